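"""Session-level tuning scores.

Grid score from the six-fold rotational symmetry of the spatial
autocorrelogram; head-direction score as the mean resultant length of
the angular tuning curve; speed score as the Pearson correlation between
instantaneous firing rate and Kalman-filtered running speed; theta
modulation as the resultant length of spike phases on the 6-10 Hz
filtered LFP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, rotate as nd_rotate
from scipy.signal import butter, fftconvolve, filtfilt, hilbert

from .ratemap import compute_ratemap
from .synthdata import LfpSignal, Trajectory

__all__ = [
    "TuningScores",
    "spatial_autocorrelation",
    "grid_score",
    "hd_score",
    "hd_tuning_curve",
    "speed_score",
    "kalman_speed",
    "instantaneous_rate",
    "theta_modulation",
    "spike_theta_phases",
    "resultant",
]


@dataclass
class TuningScores:
    grid_score: float = np.nan
    hd_score: float = np.nan
    speed_score: float = np.nan
    theta_strength: float = np.nan
    theta_phase_deg: float = np.nan


def resultant(angles_rad: np.ndarray, weights: np.ndarray | None = None) -> tuple[float, float]:
    """Mean resultant length and circular mean (radians) of a sample."""
    angles_rad = np.asarray(angles_rad, dtype=float)
    if len(angles_rad) == 0:
        return float("nan"), float("nan")
    if weights is None:
        weights = np.ones_like(angles_rad)
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        return float("nan"), float("nan")
    z = np.sum(w * np.exp(1j * angles_rad)) / total
    return float(np.abs(z)), float(np.angle(z))


# ---------------------------------------------------------------------------
# spatial autocorrelation & grid score
# ---------------------------------------------------------------------------

def _masked_autocorr(values: np.ndarray, min_overlap: int = 20) -> np.ndarray:
    """Pearson correlation of a NaN-masked map with itself at every 2-D lag.

    Computed with FFT cross-correlations of the map, its square, and its
    validity mask, so each lag uses exactly the jointly valid bins.
    """
    m = np.isfinite(values)
    a = np.where(m, values, 0.0)
    a2 = a * a
    mf = m.astype(float)

    def xcorr(p, q):
        return fftconvolve(p, q[::-1, ::-1], mode="full")

    n = xcorr(mf, mf)
    sx = xcorr(a, mf)
    sy = xcorr(mf, a)
    sxx = xcorr(a2, mf)
    syy = xcorr(mf, a2)
    sxy = xcorr(a, a)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_r = np.round(n)
        cov = sxy - sx * sy / n_r
        vx = sxx - sx * sx / n_r
        vy = syy - sy * sy / n_r
        r = cov / np.sqrt(vx * vy)
    r[(n_r < min_overlap) | ~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


def spatial_autocorrelation(
    spikes: np.ndarray, trajectory: Trajectory, bin_size_cm: float = 1.5
) -> np.ndarray:
    """Spatial autocorrelogram of the rate map at ``bin_size_cm`` bins."""
    rm = compute_ratemap(spikes, trajectory, bin_size_cm=bin_size_cm)
    return _masked_autocorr(rm.values)


def _ring_profile(ac: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = (np.array(ac.shape) - 1) // 2
    ii, jj = np.meshgrid(np.arange(ac.shape[0]), np.arange(ac.shape[1]), indexing="ij")
    dist = np.hypot(ii - c[0], jj - c[1])
    return dist, c


def _annulus_radii(ac: np.ndarray) -> tuple[float, float, int] | None:
    """Inner/outer annulus radii (bins) bracketing the inner ring of peaks.

    Inner: first 1-bin ring whose mean correlation drops below 0.2.
    Outer: 1.25 x the mean center distance of the six (or fewer) nearest
    local maxima outside the central peak.  None if no peaks are found.
    """
    from skimage.feature import peak_local_max

    dist, c = _ring_profile(ac)
    rmax = int(dist.max())
    inner = None
    for r in range(1, rmax):
        ring = ac[(dist >= r) & (dist < r + 1)]
        ring = ring[np.isfinite(ring)]
        if len(ring) and ring.mean() < 0.2:
            inner = float(r)
            break
    if inner is None:
        return None
    filled = np.where(np.isfinite(ac), ac, -1.0)
    peaks = peak_local_max(filled, min_distance=2, threshold_abs=0.0, exclude_border=False)
    if len(peaks) == 0:
        return None
    d = np.hypot(peaks[:, 0] - c[0], peaks[:, 1] - c[1])
    outside = d > inner
    d = d[outside]
    if len(d) < 3:
        return None
    d6 = np.sort(d)[:6]
    outer = 1.25 * float(d6.mean())
    return inner, outer, len(d6)


def grid_score(ac: np.ndarray) -> float:
    """Gridness: mean annulus correlation at 60/120/180 deg rotations minus
    the mean at 30/90/150 deg; NaN when no ring of peaks surrounds the
    center."""
    radii = _annulus_radii(ac)
    if radii is None:
        return float("nan")
    inner, outer, _ = radii
    dist, _c = _ring_profile(ac)
    annulus = (dist > inner) & (dist <= outer)
    valid = np.isfinite(ac)
    filled = np.where(valid, ac, 0.0)

    corrs = {}
    for angle in (30, 60, 90, 120, 150, 180):
        rot = nd_rotate(filled, angle, reshape=False, order=1, cval=0.0)
        rot_valid = (
            nd_rotate(valid.astype(float), angle, reshape=False, order=1, cval=0.0)
            > 0.99
        )
        sel = annulus & valid & rot_valid
        if sel.sum() < 20:
            return float("nan")
        x, y = filled[sel], rot[sel]
        sdx, sdy = x.std(), y.std()
        if sdx == 0 or sdy == 0:
            corrs[angle] = 0.0
        else:
            corrs[angle] = float(np.corrcoef(x, y)[0, 1])
    return float(
        np.mean([corrs[60], corrs[120], corrs[180]])
        - np.mean([corrs[30], corrs[90], corrs[150]])
    )


# ---------------------------------------------------------------------------
# head direction
# ---------------------------------------------------------------------------

def hd_tuning_curve(
    spikes: np.ndarray, trajectory: Trajectory, bin_deg: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Angular firing-rate curve: spike count per HD bin over dwell time.

    Returns (bin centers in degrees, rate in Hz with NaN at unvisited
    angles).
    """
    n_bins = int(round(360.0 / bin_deg))
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    dt = 1.0 / trajectory.fs
    occ, _ = np.histogram(trajectory.hd % 360.0, bins=edges)
    occ = occ * dt
    if len(spikes):
        idx = np.searchsorted(trajectory.t, spikes)
        idx = np.clip(idx, 1, len(trajectory.t) - 1)
        left = (spikes - trajectory.t[idx - 1]) < (trajectory.t[idx] - spikes)
        idx = np.where(left, idx - 1, idx)
        counts, _ = np.histogram(trajectory.hd[idx] % 360.0, bins=edges)
    else:
        counts = np.zeros(n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = counts / occ
    rate[occ == 0] = np.nan
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, rate


def hd_score(
    spikes: np.ndarray, trajectory: Trajectory, bin_deg: float = 1.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """(bin centers, tuning curve, mean resultant length of the curve)."""
    centers, rate = hd_tuning_curve(spikes, trajectory, bin_deg)
    ok = np.isfinite(rate)
    if not ok.any() or rate[ok].sum() == 0:
        return centers, rate, float("nan")
    score, _ = resultant(np.radians(centers[ok]), rate[ok])
    return centers, rate, score


def hd_score_of_headings(spike_hd_deg: np.ndarray, bin_deg: float = 1.0) -> float:
    """HD score of a bag of spike headings under uniform occupancy
    (used for peri-stimulus windows where dwell correction cancels)."""
    if len(spike_hd_deg) == 0:
        return float("nan")
    n_bins = int(round(360.0 / bin_deg))
    counts, edges = np.histogram(
        np.asarray(spike_hd_deg) % 360.0, bins=np.linspace(0, 360, n_bins + 1)
    )
    centers = (edges[:-1] + edges[1:]) / 2.0
    score, _ = resultant(np.radians(centers), counts.astype(float))
    return score


# ---------------------------------------------------------------------------
# speed
# ---------------------------------------------------------------------------

def kalman_speed(
    trajectory: Trajectory,
    meas_noise_cm: float = 1.0,
    accel_noise_cm_s2: float = 10.0,
) -> np.ndarray:
    """Running speed from a constant-velocity Kalman filter on position.

    State per axis is (position, velocity) with discrete white-noise
    acceleration of SD ``accel_noise_cm_s2`` and measurement noise SD
    ``meas_noise_cm``; the two axes are filtered independently and the
    speed is the norm of the filtered velocities.
    """
    dt = 1.0 / trajectory.fs
    F = np.array([[1.0, dt], [0.0, 1.0]])
    q = accel_noise_cm_s2**2
    Q = q * np.array(
        [[dt**4 / 4.0, dt**3 / 2.0], [dt**3 / 2.0, dt**2]]
    )
    H = np.array([[1.0, 0.0]])
    R = meas_noise_cm**2

    def filt(z: np.ndarray) -> np.ndarray:
        n = len(z)
        xs = np.empty(n)
        state = np.array([z[0], 0.0])
        P = np.diag([R, 100.0])
        for i in range(n):
            state = F @ state
            P = F @ P @ F.T + Q
            innov = z[i] - H @ state
            S = H @ P @ H.T + R
            K = (P @ H.T) / S
            state = state + (K.ravel() * innov)
            P = P - K @ (H @ P)
            xs[i] = state[1]
        return xs

    vx = filt(trajectory.x)
    vy = filt(trajectory.y)
    return np.hypot(vx, vy)


def instantaneous_rate(
    spikes: np.ndarray,
    trajectory: Trajectory,
    smooth_width_ms: float = 250.0,
) -> np.ndarray:
    """Firing rate in one bin per tracking frame (~33 ms), smoothed with a
    Gaussian whose +-2 SD span equals ``smooth_width_ms``."""
    dt = 1.0 / trajectory.fs
    edges = np.append(trajectory.t, trajectory.t[-1] + dt)
    counts, _ = np.histogram(spikes, bins=edges)
    sigma_frames = (smooth_width_ms / 4000.0) / dt
    return gaussian_filter1d(counts.astype(float) / dt, sigma_frames)


def speed_score(
    spikes: np.ndarray,
    trajectory: Trajectory,
    min_duration_s: float = 10.0,
    speed_filter_cm_s: float | None = None,
) -> float:
    """Pearson correlation between instantaneous rate and running speed.

    ``speed_filter_cm_s``, when given, excludes frames slower than the
    cutoff (immobility) from the correlation.
    """
    if trajectory.duration < min_duration_s:
        raise ValueError("session too short for a speed score")
    speed = kalman_speed(trajectory)
    rate = instantaneous_rate(spikes, trajectory)
    sel = np.ones(len(speed), dtype=bool)
    if speed_filter_cm_s is not None:
        sel = speed >= speed_filter_cm_s
    if sel.sum() < 3 or rate[sel].std() == 0 or speed[sel].std() == 0:
        return float("nan")
    return float(np.corrcoef(rate[sel], speed[sel])[0, 1])


# ---------------------------------------------------------------------------
# theta phase locking
# ---------------------------------------------------------------------------

def _theta_phase_series(lfp: LfpSignal, band: tuple[float, float] = (6.0, 10.0)):
    nyq = lfp.fs / 2.0
    b, a = butter(3, [band[0] / nyq, band[1] / nyq], btype="band")
    filtered = filtfilt(b, a, lfp.samples)
    phase = np.unwrap(np.angle(hilbert(filtered)))
    t = np.arange(len(lfp.samples)) / lfp.fs
    return t, phase


def spike_theta_phases(
    spikes: np.ndarray, lfp: LfpSignal, band: tuple[float, float] = (6.0, 10.0)
) -> np.ndarray:
    """Theta phase (radians) of each spike, linearly interpolated on the
    unwrapped Hilbert phase of the band-passed LFP."""
    t, phase = _theta_phase_series(lfp, band)
    ph = np.interp(np.asarray(spikes, float), t, phase)
    return np.mod(ph + math.pi, 2.0 * math.pi) - math.pi


def theta_modulation(
    spikes: np.ndarray, lfp: LfpSignal, band: tuple[float, float] = (6.0, 10.0)
) -> tuple[float, float]:
    """(strength, preferred phase in degrees) of spike phase locking."""
    if len(spikes) == 0:
        return float("nan"), float("nan")
    phases = spike_theta_phases(spikes, lfp, band)
    strength, mean_phase = resultant(phases)
    return strength, math.degrees(mean_phase)
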