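"""Synthetic open-field session generator.

Builds complete recording-session bundles -- a foraging trajectory, spike
trains of idealized functional cell types (grid, head-direction, speed,
conjunctive, untuned, interneuron), periodic light-pulse trains, and a
speed-modulated theta LFP -- with a ground-truth manifest, so that every
downstream analysis stage can be exercised and calibrated without access
to real recordings.

All cell models are inhomogeneous Poisson processes whose intensity is a
function of the animal's instantaneous position, head direction and
running speed.  Spikes are drawn by exact thinning against the maximum
intensity along the path, so generated trains are exact samples from the
stated rate model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "OptoProfile",
    "GroundTruthCell",
    "StimTrain",
    "LfpSignal",
    "SessionConfig",
    "simulate_trajectory",
    "rate_function",
    "generate_spikes",
    "generate_stim_train",
    "apply_opto_response",
    "apply_opto_with_displacement",
    "opto_gain",
    "generate_lfp",
    "generate_session",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-stamped position and head-direction samples.

    ``t`` is in seconds and strictly increasing (nominally 30 Hz); ``x``
    and ``y`` are in cm inside ``[0, box_size_cm]``; ``hd`` is the head
    direction in degrees in ``[0, 360)``.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hd: np.ndarray
    box_size_cm: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.hd = np.asarray(self.hd, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.hd) == n):
            raise ValueError("t, x, y, hd must have equal length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if np.any((self.x < 0) | (self.x > self.box_size_cm)) or np.any(
            (self.y < 0) | (self.y > self.box_size_cm)
        ):
            raise ValueError("positions must lie inside the box")

    @property
    def duration(self) -> float:
        """Session duration in seconds (last sample plus one frame)."""
        if len(self.t) < 2:
            return float(self.t[-1]) if len(self.t) else 0.0
        return float(self.t[-1] + (self.t[-1] - self.t[0]) / (len(self.t) - 1))

    @property
    def fs(self) -> float:
        return (len(self.t) - 1) / (self.t[-1] - self.t[0])

    def speed(self) -> np.ndarray:
        """Instantaneous running speed (cm/s) by central differences."""
        dt = np.gradient(self.t)
        vx = np.gradient(self.x) / dt
        vy = np.gradient(self.y) / dt
        return np.hypot(vx, vy)


@dataclass
class OptoProfile:
    """Parametric light-pulse response of one unit.

    A transient rectangular excitation bump of height ``exc_gain`` (in
    multiples of the baseline rate) whose onset sits ``exc_latency_ms``
    after each pulse, with per-trial Gaussian timing jitter of SD
    ``exc_jitter_ms``; followed by suppression to ``1 - inh_depth`` of
    baseline starting at ``inh_onset_ms`` with linear recovery over
    ``inh_recovery_ms``.
    """

    exc_gain: float = 0.0
    exc_latency_ms: float = 5.0
    exc_jitter_ms: float = 0.0
    exc_width_ms: float = 2.0
    inh_depth: float = 0.0
    inh_onset_ms: float = 10.0
    inh_recovery_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.exc_gain < 0:
            raise ValueError("exc_gain must be >= 0")
        if not 0.0 <= self.inh_depth <= 1.0:
            raise ValueError("inh_depth must lie in [0, 1]")
        if self.exc_latency_ms < 0 or self.inh_onset_ms < 0:
            raise ValueError("latencies must be >= 0")


_KINDS = ("grid", "hd", "speed", "conjunctive", "untuned", "interneuron")


@dataclass
class GroundTruthCell:
    """Generative parameters for one simulated unit."""

    cell_id: str
    kind: str
    peak_rate_hz: float = 10.0
    # grid tuning
    grid_spacing_cm: float = 40.0
    grid_orientation_deg: float = 0.0
    grid_phase_cm: tuple[float, float] = (0.0, 0.0)
    grid_threshold: float = 0.3
    # head-direction tuning
    hd_pref_deg: float = 0.0
    hd_kappa: float = 4.0
    # speed tuning
    speed_slope_hz_per_cm_s: float = 0.3
    speed_intercept_hz: float = 1.0
    opto: OptoProfile = field(default_factory=OptoProfile)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if self.grid_spacing_cm <= 0:
            raise ValueError("grid spacing must be > 0")
        if self.hd_kappa < 0:
            raise ValueError("hd_kappa must be >= 0")


@dataclass
class StimTrain:
    """Periodic light-pulse onsets (seconds)."""

    onsets: np.ndarray
    pulse_width_ms: float
    frequency_hz: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if len(self.onsets) >= 2 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")
        if self.pulse_width_ms >= 1000.0 / self.frequency_hz:
            raise ValueError("pulse width must be shorter than the period")


@dataclass
class LfpSignal:
    """A single-channel local-field-potential trace (microvolts)."""

    fs: float
    samples: np.ndarray
    channel_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must be finite")


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def simulate_trajectory(
    duration_s: float,
    box_size_cm: float = 75.0,
    fs_hz: float = 30.0,
    speed_mean_cm_s: float = 15.0,
    hd_noise_deg: float = 10.0,
    tau_s: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> Trajectory:
    """Simulate open-field foraging as a mean-reverting velocity walk.

    Velocity follows an Ornstein-Uhlenbeck process per component (time
    constant ``tau_s``), whose stationary 2-D speed is Rayleigh with mean
    ``speed_mean_cm_s``; walls reflect both position and velocity.  Head
    direction is the instantaneous movement heading plus wrapped Gaussian
    noise of SD ``hd_noise_deg``.
    """
    if duration_s <= 0 or fs_hz <= 0 or speed_mean_cm_s <= 0:
        raise ValueError("duration, sampling rate and mean speed must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    dt = 1.0 / fs_hz
    # per-component SD giving Rayleigh mean = speed_mean
    sigma_v = speed_mean_cm_s / math.sqrt(math.pi / 2.0)
    theta = 1.0 / tau_s
    drive = sigma_v * math.sqrt(2.0 * theta * dt)

    x = np.empty(n)
    y = np.empty(n)
    vx = rng.normal(0.0, sigma_v)
    vy = rng.normal(0.0, sigma_v)
    px = rng.uniform(0.25, 0.75) * box_size_cm
    py = rng.uniform(0.25, 0.75) * box_size_cm
    noise = rng.normal(0.0, 1.0, size=(n, 2))
    for i in range(n):
        vx += -theta * vx * dt + drive * noise[i, 0]
        vy += -theta * vy * dt + drive * noise[i, 1]
        px += vx * dt
        py += vy * dt
        if px < 0:
            px, vx = -px, -vx
        elif px > box_size_cm:
            px, vx = 2 * box_size_cm - px, -vx
        if py < 0:
            py, vy = -py, -vy
        elif py > box_size_cm:
            py, vy = 2 * box_size_cm - py, -vy
        x[i] = px
        y[i] = py

    t = np.arange(n) * dt
    heading = np.degrees(np.arctan2(np.gradient(y), np.gradient(x)))
    hd = (heading + rng.normal(0.0, hd_noise_deg, size=n)) % 360.0
    return Trajectory(t=t, x=x, y=y, hd=hd, box_size_cm=box_size_cm)


# ---------------------------------------------------------------------------
# rate models
# ---------------------------------------------------------------------------

def _grid_factor(cell: GroundTruthCell, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Hexagonal firing field in [0, 1]: thresholded sum of three plane
    waves at 60 deg separations; equals 1 exactly at lattice nodes."""
    k = 4.0 * math.pi / (math.sqrt(3.0) * cell.grid_spacing_cm)
    base = math.radians(cell.grid_orientation_deg)
    dx = np.asarray(x, float) - cell.grid_phase_cm[0]
    dy = np.asarray(y, float) - cell.grid_phase_cm[1]
    g = np.zeros_like(dx, dtype=float)
    for j in range(3):
        ang = base + j * math.pi / 3.0 + math.pi / 6.0
        g += np.cos(k * (dx * math.cos(ang) + dy * math.sin(ang)))
    u = (g + 1.5) / 4.5  # in [0, 1]
    th = cell.grid_threshold
    return np.clip((u - th) / (1.0 - th), 0.0, None)


def _hd_factor(cell: GroundTruthCell, hd_deg: np.ndarray) -> np.ndarray:
    """von Mises tuning normalized to peak 1 (kappa=0 -> constant 1)."""
    d = np.radians(np.asarray(hd_deg, float) - cell.hd_pref_deg)
    return np.exp(cell.hd_kappa * (np.cos(d) - 1.0))


def rate_function(
    cell: GroundTruthCell,
) -> Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray], np.ndarray]:
    """Return the intensity function lambda(x, y, hd, speed) in Hz."""
    kind = cell.kind
    if kind == "grid":
        return lambda x, y, hd, speed: cell.peak_rate_hz * _grid_factor(cell, x, y)
    if kind == "hd":
        return lambda x, y, hd, speed: cell.peak_rate_hz * _hd_factor(cell, hd)
    if kind == "speed":
        return lambda x, y, hd, speed: np.clip(
            cell.speed_intercept_hz
            + cell.speed_slope_hz_per_cm_s * np.asarray(speed, float),
            0.0,
            None,
        )
    if kind == "conjunctive":
        return lambda x, y, hd, speed: (
            cell.peak_rate_hz * _grid_factor(cell, x, y) * _hd_factor(cell, hd)
        )
    if kind in ("untuned", "interneuron"):
        return lambda x, y, hd, speed: np.full(
            np.broadcast(np.asarray(x), np.asarray(hd)).shape,
            cell.peak_rate_hz,
            dtype=float,
        )
    raise ValueError(f"unknown cell kind {kind!r}")


def _rate_along(
    rate_fn: Callable, trajectory: Trajectory
) -> np.ndarray:
    speed = trajectory.speed()
    rate = np.asarray(
        rate_fn(trajectory.x, trajectory.y, trajectory.hd, speed), dtype=float
    )
    if rate.shape != trajectory.t.shape:
        rate = np.broadcast_to(rate, trajectory.t.shape).astype(float)
    if np.any(~np.isfinite(rate)) or np.any(rate < 0):
        raise ValueError("rate function must be finite and >= 0 on the path")
    return rate


def generate_spikes(
    rate_fn: Callable | np.ndarray,
    trajectory: Trajectory,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw an inhomogeneous Poisson spike train along the trajectory.

    ``rate_fn`` is either an intensity callable (see :func:`rate_function`)
    or a precomputed per-frame rate array.  Exact thinning: candidates are
    drawn homogeneously at the maximum path rate and kept with probability
    rate(t)/max, the rate being linearly interpolated between frames.
    Returns sorted spike times in seconds.
    """
    rng = np.random.default_rng(seed)
    rate = (
        np.asarray(rate_fn, dtype=float)
        if isinstance(rate_fn, np.ndarray)
        else _rate_along(rate_fn, trajectory)
    )
    if np.any(rate < 0):
        raise ValueError("negative rate encountered")
    rmax = float(rate.max(initial=0.0))
    t0, t1 = float(trajectory.t[0]), trajectory.duration
    if rmax == 0.0:
        return np.empty(0)
    n_cand = rng.poisson(rmax * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    lam = np.interp(cand, trajectory.t, rate)
    keep = rng.uniform(0.0, rmax, size=n_cand) < lam
    return cand[keep]


# ---------------------------------------------------------------------------
# stimulation
# ---------------------------------------------------------------------------

def generate_stim_train(
    frequency_hz: float, pulse_width_ms: float, duration_s: float
) -> StimTrain:
    """Periodic pulse train: onsets at k/frequency for the whole session."""
    if frequency_hz <= 0 or duration_s <= 0:
        raise ValueError("frequency and duration must be > 0")
    if pulse_width_ms >= 1000.0 / frequency_hz:
        raise ValueError("pulse width must be shorter than the period")
    n = int(math.floor(duration_s * frequency_hz))
    onsets = np.arange(n) / frequency_hz
    return StimTrain(onsets=onsets, pulse_width_ms=pulse_width_ms, frequency_hz=frequency_hz)


def opto_gain(
    tau_ms: np.ndarray, profile: OptoProfile, jitter_ms: float | np.ndarray = 0.0
) -> np.ndarray:
    """Multiplicative rate gain at time ``tau_ms`` after a pulse onset.

    Excitation: gain ``1 + exc_gain`` on [latency + jitter, latency +
    jitter + width].  Inhibition: drop to ``1 - inh_depth`` at
    ``inh_onset_ms`` with linear recovery to 1 over ``inh_recovery_ms``.
    Outside a pulse window the gain is 1.  Always >= 0.
    """
    tau = np.asarray(tau_ms, dtype=float)
    g = np.ones_like(tau)
    if profile.inh_depth > 0:
        rel = (tau - profile.inh_onset_ms) / max(profile.inh_recovery_ms, 1e-9)
        in_inh = (tau >= profile.inh_onset_ms) & (rel < 1.0)
        g = np.where(
            in_inh, 1.0 - profile.inh_depth * (1.0 - np.clip(rel, 0.0, 1.0)), g
        )
    if profile.exc_gain > 0:
        start = profile.exc_latency_ms + np.asarray(jitter_ms, dtype=float)
        in_exc = (tau >= start) & (tau < start + profile.exc_width_ms)
        g = np.where(in_exc, g + profile.exc_gain, g)
    return g


def apply_opto_response(
    rate_fn: Callable | np.ndarray,
    stim: StimTrain,
    profile: OptoProfile,
    trajectory: Trajectory,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Generate spikes whose rate is the baseline rate times a per-pulse
    time-locked gain kernel (see :func:`opto_gain`).

    The product intensity is sampled exactly: candidate spikes are drawn
    homogeneously at ``max_baseline * (1 + exc_gain)`` and thinned against
    the exact intensity, with the baseline linearly interpolated between
    trajectory frames and the gain evaluated in continuous time relative
    to the preceding pulse onset (per-trial jittered bump position).
    """
    rng = np.random.default_rng(seed)
    base = (
        np.asarray(rate_fn, dtype=float)
        if isinstance(rate_fn, np.ndarray)
        else _rate_along(rate_fn, trajectory)
    )
    rmax = float(base.max(initial=0.0)) * (1.0 + max(profile.exc_gain, 0.0))
    t0, t1 = float(trajectory.t[0]), trajectory.duration
    if rmax == 0.0:
        return np.empty(0)
    jitters = (
        rng.normal(0.0, profile.exc_jitter_ms, size=len(stim.onsets))
        if profile.exc_jitter_ms > 0
        else np.zeros(len(stim.onsets))
    )
    n_cand = rng.poisson(rmax * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    lam = np.interp(cand, trajectory.t, base)
    idx = np.searchsorted(stim.onsets, cand, side="right") - 1
    has_pulse = idx >= 0
    tau_ms = np.full(n_cand, np.inf)
    tau_ms[has_pulse] = (cand[has_pulse] - stim.onsets[idx[has_pulse]]) * 1000.0
    jit = np.where(has_pulse, jitters[np.clip(idx, 0, None)], 0.0)
    gain = np.ones(n_cand)
    m = np.isfinite(tau_ms)
    gain[m] = opto_gain(tau_ms[m], profile, jit[m])
    lam = lam * gain
    if np.any(lam < 0):
        raise ValueError("opto kernel produced a negative rate")
    keep = rng.uniform(0.0, rmax, size=n_cand) < lam
    return cand[keep]


def apply_opto_with_displacement(
    rate_fn: Callable,
    stim: StimTrain,
    profile: OptoProfile,
    trajectory: Trajectory,
    displacement_sd_cm: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Opto response whose surviving spikes are spatially inaccurate.

    Like :func:`apply_opto_response`, but candidates falling inside the
    inhibition window of a pulse (``inh_onset`` to ``inh_onset +
    inh_recovery``) are generated from the rate function evaluated at a
    per-pulse displaced position (2-D Gaussian offset of SD
    ``displacement_sd_cm`` per axis): the cell keeps firing at its usual
    field rate statistics but at the wrong place, degrading spatial
    accuracy only during the transient window.
    """
    rng = np.random.default_rng(seed)
    base = _rate_along(rate_fn, trajectory)
    rmax = float(base.max(initial=0.0)) * (1.0 + max(profile.exc_gain, 0.0))
    t0, t1 = float(trajectory.t[0]), trajectory.duration
    if rmax == 0.0:
        return np.empty(0)
    offsets = rng.normal(0.0, displacement_sd_cm, size=(len(stim.onsets), 2))
    jitters = (
        rng.normal(0.0, profile.exc_jitter_ms, size=len(stim.onsets))
        if profile.exc_jitter_ms > 0
        else np.zeros(len(stim.onsets))
    )
    n_cand = rng.poisson(rmax * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    idx = np.searchsorted(stim.onsets, cand, side="right") - 1
    tau_ms = np.where(
        idx >= 0, (cand - stim.onsets[np.clip(idx, 0, None)]) * 1000.0, np.inf
    )
    jit = np.where(idx >= 0, jitters[np.clip(idx, 0, None)], 0.0)
    gain = opto_gain(np.where(np.isfinite(tau_ms), tau_ms, 1e9), profile, jit)

    x = np.interp(cand, trajectory.t, trajectory.x)
    y = np.interp(cand, trajectory.t, trajectory.y)
    hd = np.interp(cand, trajectory.t, np.unwrap(np.radians(trajectory.hd)))
    hd = np.degrees(hd) % 360.0
    speed = np.interp(cand, trajectory.t, trajectory.speed())
    in_window = (tau_ms >= profile.inh_onset_ms) & (
        tau_ms < profile.inh_onset_ms + profile.inh_recovery_ms
    )
    dx = np.where(in_window, offsets[np.clip(idx, 0, None), 0], 0.0)
    dy = np.where(in_window, offsets[np.clip(idx, 0, None), 1], 0.0)
    lam = np.asarray(rate_fn(x + dx, y + dy, hd, speed), dtype=float) * gain
    lam = np.minimum(lam, rmax)
    keep = rng.uniform(0.0, rmax, size=n_cand) < lam
    return cand[keep]


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def generate_lfp(
    trajectory: Trajectory,
    theta_f0_hz: float = 8.0,
    freq_slope_hz_per_cm_s: float = 0.0,
    amp0_uv: float = 50.0,
    amp_slope_uv_per_cm_s: float = 0.0,
    stim: StimTrain | None = None,
    artifact_amp_uv: float = 0.0,
    noise_sd_uv: float = 5.0,
    fs_hz: float = 1000.0,
    channel_id: int = 0,
    seed: int | np.random.Generator = 0,
) -> LfpSignal:
    """Speed-modulated theta oscillation with optional pulse artifacts.

    Phase-continuous: instantaneous frequency ``theta_f0 + slope*speed(t)``
    is integrated; amplitude is ``amp0 + amp_slope*speed(t)``.  When
    ``artifact_amp_uv > 0`` a brief damped transient (3 ms decay) is added
    at each stimulus onset, mimicking population spikes that distort the
    raw trace.  Noise is drawn before artifacts, so ``artifact_amp_uv=0``
    reproduces the no-stim signal bit-for-bit under the same seed.
    """
    if fs_hz < 100:
        raise ValueError("sampling rate too low to represent theta")
    rng = np.random.default_rng(seed)
    n = int(round(trajectory.duration * fs_hz))
    t = np.arange(n) / fs_hz
    speed = np.interp(t, trajectory.t, trajectory.speed())
    finst = theta_f0_hz + freq_slope_hz_per_cm_s * speed
    phase = 2.0 * math.pi * np.cumsum(finst) / fs_hz
    amp = amp0_uv + amp_slope_uv_per_cm_s * speed
    sig = amp * np.sin(phase)
    if noise_sd_uv > 0:
        sig = sig + rng.normal(0.0, noise_sd_uv, size=n)
    if stim is not None and artifact_amp_uv > 0:
        kernel_t = np.arange(int(0.008 * fs_hz)) / fs_hz
        kernel = artifact_amp_uv * np.exp(-kernel_t / 0.003)
        for onset in stim.onsets:
            i = int(round(onset * fs_hz))
            if i >= n:
                break
            j = min(n, i + len(kernel))
            sig[i:j] += kernel[: j - i]
    return LfpSignal(fs=fs_hz, samples=sig, channel_id=channel_id)


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """Day-level simulation configuration: three sessions (baseline,
    stimulation, baseline) sharing one population of cells."""

    cells: Sequence[GroundTruthCell]
    duration_s: float = 600.0
    box_size_cm: float = 75.0
    fs_hz: float = 30.0
    speed_mean_cm_s: float = 15.0
    stim_frequency_hz: float = 8.0
    stim_pulse_width_ms: float = 10.0
    lfp_fs_hz: float = 1000.0
    theta_f0_hz: float = 8.0
    theta_freq_slope: float = 0.0
    theta_amp_slope: float = 0.0
    lfp_artifact_amp_uv: float = 0.0
    n_lfp_channels: int = 1

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("config must list at least one cell")
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("cell ids must be unique")


def generate_session(config: SessionConfig, seed: int = 0):
    """Generate a three-session day and its ground-truth manifest.

    Returns ``(bundles, manifest)`` where ``bundles`` is a list of three
    :class:`mecopto.session_io.SessionBundle` with roles baseline1,
    stimulation, baseline2, and ``manifest`` is a JSON-serializable dict of
    every generative parameter.  Only the stimulation session carries a
    stim train, and only there is each cell's opto profile applied.
    """
    from .session_io import SessionBundle, SpikeTrain  # local import, no cycle at load

    root = np.random.SeedSequence(seed)
    roles = ("baseline1", "stimulation", "baseline2")
    bundles = []
    for s_idx, role in enumerate(roles):
        ss = root.spawn(1)[0]
        streams = ss.spawn(2 + len(config.cells) + config.n_lfp_channels)
        traj = simulate_trajectory(
            config.duration_s,
            config.box_size_cm,
            config.fs_hz,
            config.speed_mean_cm_s,
            seed=np.random.default_rng(streams[0]),
        )
        stim = (
            generate_stim_train(
                config.stim_frequency_hz, config.stim_pulse_width_ms, config.duration_s
            )
            if role == "stimulation"
            else None
        )
        units = []
        for c_idx, cell in enumerate(config.cells):
            fn = rate_function(cell)
            cell_rng = np.random.default_rng(streams[2 + c_idx])
            if stim is not None:
                times = apply_opto_response(fn, stim, cell.opto, traj, seed=cell_rng)
            else:
                times = generate_spikes(fn, traj, seed=cell_rng)
            mean_rate = len(times) / config.duration_s
            pv = 1.1 if cell.kind == "interneuron" else 2.0
            units.append(
                SpikeTrain(
                    cell_id=cell.cell_id,
                    times=times,
                    mean_rate=mean_rate,
                    peak_valley_ratio=pv,
                )
            )
        lfps = [
            generate_lfp(
                traj,
                theta_f0_hz=config.theta_f0_hz,
                freq_slope_hz_per_cm_s=config.theta_freq_slope,
                amp_slope_uv_per_cm_s=config.theta_amp_slope,
                stim=stim,
                artifact_amp_uv=config.lfp_artifact_amp_uv,
                fs_hz=config.lfp_fs_hz,
                channel_id=ch,
                seed=np.random.default_rng(streams[2 + len(config.cells) + ch]),
            )
            for ch in range(config.n_lfp_channels)
        ]
        bundles.append(
            SessionBundle(
                session_id=f"sim-{seed}-{s_idx}",
                role=role,
                trajectory=traj,
                units=units,
                stim=stim,
                lfp=lfps,
                metadata={
                    "box_size_cm": config.box_size_cm,
                    "duration_s": config.duration_s,
                    "stim_frequency_hz": config.stim_frequency_hz
                    if role == "stimulation"
                    else None,
                },
            )
        )
    manifest = {
        "seed": seed,
        "config": {
            k: v
            for k, v in asdict(config).items()
            if k != "cells"
        },
        "cells": [asdict(c) for c in config.cells],
    }
    return bundles, manifest
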