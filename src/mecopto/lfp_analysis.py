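"""Theta-band spectral analysis of the LFP.

Power is computed with a complex Morlet wavelet transform on the 1 kHz
signal; the channel with the highest mean 6-10 Hz power is selected for
a session; the per-frame theta peak frequency and mean power are then
regressed on running speed, and slopes can be compared between two
sessions through an interaction-term regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import decimate

from .synthdata import LfpSignal, Trajectory

__all__ = [
    "ThetaSeries",
    "wavelet_spectrogram",
    "theta_series",
    "select_theta_channel",
    "theta_speed_regression",
    "compare_slopes",
    "downsample_lfp",
    "blank_around_pulses",
]

THETA_BAND = (6.0, 10.0)
MORLET_RATIO = 7.0  # center frequency / spectral bandwidth of the wavelet


@dataclass
class ThetaSeries:
    """Per-trajectory-frame theta descriptors."""

    t: np.ndarray
    peak_freq_hz: np.ndarray
    mean_power: np.ndarray


def blank_around_pulses(
    lfp: LfpSignal, onsets_s: np.ndarray, half_width_ms: float = 5.0
) -> LfpSignal:
    """Sensitivity-analysis helper: linearly interpolate the trace across
    +-``half_width_ms`` around each pulse onset, removing population-spike
    artifacts.  The default analyses do NOT blank; this exists to check
    how much artifacts move the theta estimates."""
    samples = lfp.samples.copy()
    n = len(samples)
    w = int(round(half_width_ms / 1000.0 * lfp.fs))
    for onset in np.asarray(onsets_s, dtype=float):
        i = int(round(onset * lfp.fs))
        lo, hi = max(i - w, 0), min(i + w, n - 1)
        if hi <= lo:
            continue
        samples[lo : hi + 1] = np.linspace(samples[lo], samples[hi], hi - lo + 1)
    return LfpSignal(fs=lfp.fs, samples=samples, channel_id=lfp.channel_id)


def downsample_lfp(lfp: LfpSignal, target_fs: float = 1000.0) -> LfpSignal:
    """Anti-aliased decimation to ``target_fs`` (no-op if already there)."""
    factor = int(round(lfp.fs / target_fs))
    if factor <= 1:
        return lfp
    return LfpSignal(
        fs=lfp.fs / factor,
        samples=decimate(lfp.samples, factor, zero_phase=True),
        channel_id=lfp.channel_id,
    )


def _morlet_name() -> str:
    # pywt cmorB-C: B is the bandwidth parameter (variance of the Gaussian
    # envelope in time), C the center frequency.  With C = 1, spectral SD
    # is 1/(pi*sqrt(2B)); ratio 7 => B = (7 / pi)^2 / 2.
    b = (MORLET_RATIO / np.pi) ** 2 / 2.0
    return f"cmor{b:.4f}-1.0"


def wavelet_spectrogram(
    lfp: LfpSignal,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Morlet power of the LFP: returns ``(t, freqs, power)`` with power
    shaped (n_freqs, n_samples).

    The default frequency axis spans 2-20 Hz with 0.25 Hz steps outside
    the theta band and 0.1 Hz inside 6-10 Hz.
    """
    n = len(lfp.samples)
    if n < 2 * lfp.fs:
        raise ValueError("signal shorter than 2 s")
    if freqs is None:
        coarse_lo = np.arange(2.0, 6.0, 0.25)
        fine = np.arange(6.0, 10.0 + 1e-9, 0.1)
        coarse_hi = np.arange(10.25, 20.0 + 1e-9, 0.25)
        freqs = np.concatenate([coarse_lo, fine, coarse_hi])
    freqs = np.asarray(freqs, dtype=float)
    scales = pywt.frequency2scale(_morlet_name(), freqs / lfp.fs)
    coefs, _ = pywt.cwt(lfp.samples, scales, _morlet_name(), method="fft")
    power = np.abs(coefs) ** 2
    t = np.arange(n) / lfp.fs
    return t, freqs, power


def theta_series(
    lfp: LfpSignal,
    trajectory: Trajectory,
    band: tuple[float, float] = THETA_BAND,
) -> ThetaSeries:
    """Theta peak frequency and mean power aligned to trajectory frames.

    Power is averaged within each tracking frame; the peak frequency is
    the in-band argmax refined by parabolic interpolation of log power.
    """
    lfp = downsample_lfp(lfp)
    lo, hi = band
    freqs = np.arange(lo - 0.5, hi + 0.5 + 1e-9, 0.1)
    t, fgrid, power = wavelet_spectrogram(lfp, freqs=freqs)

    # average power into trajectory frames
    frame_idx = np.searchsorted(trajectory.t, t, side="right") - 1
    frame_idx = np.clip(frame_idx, 0, len(trajectory.t) - 1)
    n_frames = len(trajectory.t)
    frame_power = np.zeros((len(fgrid), n_frames))
    counts = np.bincount(frame_idx, minlength=n_frames).astype(float)
    counts[counts == 0] = np.nan
    for k in range(len(fgrid)):
        frame_power[k] = np.bincount(
            frame_idx, weights=power[k], minlength=n_frames
        ) / counts

    in_band = (fgrid >= lo) & (fgrid <= hi)
    band_power = frame_power[in_band]
    band_freqs = fgrid[in_band]
    k = np.nanargmax(band_power, axis=0)
    peak = band_freqs[k]
    # parabolic refinement on log power where the peak is interior
    logp = np.log(np.maximum(band_power, 1e-300))
    interior = (k > 0) & (k < len(band_freqs) - 1)
    ki = k[interior]
    cols = np.nonzero(interior)[0]
    y0 = logp[ki - 1, cols]
    y1 = logp[ki, cols]
    y2 = logp[ki + 1, cols]
    denom = y0 - 2 * y1 + y2
    shift = np.where(denom < 0, 0.5 * (y0 - y2) / denom, 0.0)
    df = band_freqs[1] - band_freqs[0]
    peak = peak.astype(float)
    peak[cols] += np.clip(shift, -0.5, 0.5) * df
    return ThetaSeries(
        t=trajectory.t.copy(),
        peak_freq_hz=peak,
        mean_power=np.nanmean(band_power, axis=0),
    )


def select_theta_channel(
    lfps: list[LfpSignal], band: tuple[float, float] = THETA_BAND
) -> int:
    """Channel id with the highest mean 6-10 Hz power; ties to lowest id."""
    if not lfps:
        raise ValueError("no LFP channels")
    best_id, best_power = None, -np.inf
    for sig in sorted(lfps, key=lambda s: s.channel_id):
        ds = downsample_lfp(sig)
        freqs = np.arange(band[0], band[1] + 1e-9, 0.25)
        _, _, power = wavelet_spectrogram(ds, freqs=freqs)
        mp = float(power.mean())
        if mp > best_power:
            best_id, best_power = sig.channel_id, mp
    return best_id


def theta_speed_regression(
    series: ThetaSeries,
    trajectory: Trajectory,
    min_samples: int = 100,
) -> dict:
    """OLS of theta peak frequency and mean power on running speed.

    Returns ``{"freq": {slope, intercept, r}, "power": {...}}`` with
    slopes in Hz per cm/s and power units per cm/s.
    """
    from scipy.stats import linregress

    speed = trajectory.speed()
    n = min(len(speed), len(series.peak_freq_hz))
    if n < min_samples:
        raise ValueError("too few aligned samples for a regression")
    out = {}
    for key, y in (("freq", series.peak_freq_hz[:n]), ("power", series.mean_power[:n])):
        ok = np.isfinite(y) & np.isfinite(speed[:n])
        res = linregress(speed[:n][ok], y[ok])
        out[key] = {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r": float(res.rvalue),
        }
    return out


def compare_slopes(
    series_a: ThetaSeries,
    trajectory_a: Trajectory,
    series_b: ThetaSeries,
    trajectory_b: Trajectory,
    what: str = "freq",
) -> dict:
    """Two-session slope comparison via a speed x session interaction term.

    Fits ``y ~ speed + session + speed:session`` over the pooled samples
    and reports the interaction coefficient (the slope difference) with
    its p-value.  The theta series is strongly autocorrelated at the
    30 Hz frame clock, so inference uses Newey-West (HAC) standard
    errors with a 2 s lag window rather than the naive OLS covariance.
    """
    import statsmodels.api as sm

    def xy(series, traj):
        y = series.peak_freq_hz if what == "freq" else series.mean_power
        speed = traj.speed()
        n = min(len(speed), len(y))
        ok = np.isfinite(y[:n]) & np.isfinite(speed[:n])
        return speed[:n][ok], y[:n][ok]

    sa, ya = xy(series_a, trajectory_a)
    sb, yb = xy(series_b, trajectory_b)
    speed = np.concatenate([sa, sb])
    y = np.concatenate([ya, yb])
    session = np.concatenate([np.zeros(len(sa)), np.ones(len(sb))])
    X = sm.add_constant(np.column_stack([speed, session, speed * session]))
    maxlags = int(2.0 * trajectory_a.fs)
    fit = sm.OLS(y, X).fit(cov_type="HAC", cov_kwds={"maxlags": maxlags})
    return {
        "slope_diff": float(fit.params[3]),
        "p_value": float(fit.pvalues[3]),
        "slope_a": float(fit.params[1]),
        "slope_b": float(fit.params[1] + fit.params[3]),
    }
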