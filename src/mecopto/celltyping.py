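"""Shuffle-null construction and functional cell-type classification.

The null for every tuning score is a rigid circular time shift of the
whole spike train (uniform in [20, 580] s, wrapped at the session end),
repeated per cell and per session; a cell carries a functional label
when its true score exceeds the empirical 95th-percentile shuffle cutoff
in at least two of the day's three sessions.  Head-direction cells are
split into narrow (score > 0.5) and broad; putative interneurons are
gated by mean rate and waveform peak-valley ratio and profiled by an
autocorrelogram burst index.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .session_io import DayRecord, SessionBundle
from .tuning import grid_score, spatial_autocorrelation

__all__ = [
    "ShuffleResult",
    "CellTypeConfig",
    "CellTypeLabel",
    "InterneuronProfile",
    "shuffle_spike_train",
    "shuffle_cutoff",
    "classify_cell_types",
    "classify_interneuron",
    "burst_index",
    "session_score",
]

SHIFT_MIN_S = 20.0
SHIFT_MAX_S = 580.0


@dataclass
class ShuffleResult:
    n_shuffles: int
    scores: np.ndarray
    cutoff_95: float
    cutoff_99: float

    @classmethod
    def from_scores(cls, scores: np.ndarray) -> "ShuffleResult":
        scores = np.asarray(scores, dtype=float)
        ok = scores[np.isfinite(scores)]
        if len(ok) < max(1, len(scores) // 2):
            raise ValueError("score undefined on more than half of the shuffles")
        return cls(
            n_shuffles=len(scores),
            scores=scores,
            cutoff_95=float(np.percentile(ok, 95)),
            cutoff_99=float(np.percentile(ok, 99)),
        )

    def cutoff(self, percentile: float) -> float:
        if percentile == 95:
            return self.cutoff_95
        if percentile == 99:
            return self.cutoff_99
        ok = self.scores[np.isfinite(self.scores)]
        return float(np.percentile(ok, percentile))


@dataclass
class CellTypeConfig:
    n_shuffles: int = 1000
    percentile: float = 95.0
    min_sessions: int = 2
    hd_split_score: float = 0.5
    theta_strength_min: float = 0.1
    scores: tuple[str, ...] = ("grid", "hd", "speed", "theta")
    interneuron_excludes_principal_labels: bool = False


@dataclass
class CellTypeLabel:
    cell_id: str
    labels: set = field(default_factory=set)
    session_scores: dict = field(default_factory=dict)  # score -> [s1, s2, s3]
    session_cutoffs: dict = field(default_factory=dict)
    sessions_passed: dict = field(default_factory=dict)


@dataclass
class InterneuronProfile:
    mean_rate_hz: float
    peak_valley_ratio: float
    burst_index: float = np.nan


# ---------------------------------------------------------------------------
# shuffling
# ---------------------------------------------------------------------------

def shuffle_spike_train(
    spikes: np.ndarray,
    session_duration: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Rigid circular time shift of all spikes, wrapped at the session end.

    The shift is uniform in [20, 580] s; for sessions shorter than 600 s
    the upper bound becomes duration - 20 s (keeping the shifted train at
    least 20 s away from a trivial alignment at either end).
    """
    rng = np.random.default_rng(seed)
    hi = min(SHIFT_MAX_S, session_duration - SHIFT_MIN_S)
    if hi <= SHIFT_MIN_S:
        hi = session_duration  # degenerate very-short session
    shift = rng.uniform(SHIFT_MIN_S, hi)
    if len(spikes) == 0:
        return np.asarray(spikes, dtype=float).copy()
    return np.sort(np.mod(np.asarray(spikes, float) + shift, session_duration))


def shuffle_cutoff(
    score_fn: Callable[[np.ndarray], float],
    spikes: np.ndarray,
    session_duration: float,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ShuffleResult:
    """Empirical null of ``score_fn`` over rigid-shift shuffles."""
    rng = np.random.default_rng(seed)
    scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        scores[i] = score_fn(shuffle_spike_train(spikes, session_duration, rng))
    return ShuffleResult.from_scores(scores)


# ---------------------------------------------------------------------------
# session scoring
# ---------------------------------------------------------------------------

def make_score_fn(name: str, session: SessionBundle) -> Callable[[np.ndarray], float]:
    """A fast ``spikes -> score`` closure for one session.

    Everything that does not depend on the spike train (Kalman speed,
    angular occupancy, theta phase series) is computed once, so the
    closure can be evaluated hundreds of times inside a shuffle loop.
    """
    traj = session.trajectory
    if name == "grid":
        return lambda sp: grid_score(spatial_autocorrelation(sp, traj))

    if name == "hd":
        from .tuning import resultant

        n_bins = 360
        edges = np.linspace(0.0, 360.0, n_bins + 1)
        dt = 1.0 / traj.fs
        occ = np.histogram(traj.hd % 360.0, bins=edges)[0] * dt
        centers_rad = np.radians((edges[:-1] + edges[1:]) / 2.0)
        hd_mod = traj.hd % 360.0

        def hd_fn(sp: np.ndarray) -> float:
            if len(sp) == 0:
                return float("nan")
            idx = np.searchsorted(traj.t, sp)
            idx = np.clip(idx, 1, len(traj.t) - 1)
            left = (sp - traj.t[idx - 1]) < (traj.t[idx] - sp)
            idx = np.where(left, idx - 1, idx)
            counts = np.bincount(
                np.minimum((hd_mod[idx] / 360.0 * n_bins).astype(int), n_bins - 1),
                minlength=n_bins,
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                rate = counts / occ
            ok = occ > 0
            if not ok.any() or rate[ok].sum() == 0:
                return float("nan")
            return resultant(centers_rad[ok], rate[ok])[0]

        return hd_fn

    if name == "speed":
        from scipy.ndimage import gaussian_filter1d

        from .tuning import kalman_speed

        speed = kalman_speed(traj)
        dt = 1.0 / traj.fs
        n = len(traj.t)
        t0 = traj.t[0]
        sigma_frames = (250.0 / 4000.0) / dt
        sd_speed = speed.std()

        def speed_fn(sp: np.ndarray) -> float:
            counts = np.bincount(
                np.clip(((sp - t0) / dt).astype(int), 0, n - 1), minlength=n
            )
            rate = gaussian_filter1d(counts.astype(float) / dt, sigma_frames)
            if rate.std() == 0 or sd_speed == 0:
                return float("nan")
            return float(np.corrcoef(rate, speed)[0, 1])

        return speed_fn

    if name == "theta":
        if not session.lfp:
            return lambda sp: float("nan")
        from .tuning import _theta_phase_series, resultant

        lfp = session.lfp[0]
        t_lfp, phase = _theta_phase_series(lfp)

        def theta_fn(sp: np.ndarray) -> float:
            if len(sp) == 0:
                return float("nan")
            ph = np.interp(sp, t_lfp, phase)
            return resultant(np.mod(ph, 2 * np.pi))[0]

        return theta_fn

    raise ValueError(f"unknown score {name!r}")


def session_score(name: str, spikes: np.ndarray, session: SessionBundle) -> float:
    """One named tuning score of one unit in one session."""
    return make_score_fn(name, session)(np.asarray(spikes, dtype=float))


def classify_cell_types(
    day: DayRecord,
    config: CellTypeConfig | None = None,
    seed: int = 0,
) -> list[CellTypeLabel]:
    """Shuffle-based functional classification of every unit in a day.

    For each unit, score and shuffle-cutoff are computed per session; a
    label is assigned when the score beats the cutoff in at least
    ``min_sessions`` of the three sessions.  HD-labeled cells are split
    at score 0.5 into narrow vs broad; cells carrying both the grid and
    an HD label are additionally marked conjunctive.  Theta-modulated
    cells use a fixed strength threshold (no shuffle), matching the
    resultant-length > 0.1 in 2-of-3-sessions rule.
    """
    config = config or CellTypeConfig()
    root = np.random.SeedSequence(seed)
    score_fns = {
        (name, s_idx): make_score_fn(name, session)
        for name in config.scores
        for s_idx, session in enumerate(day.sessions)
    }
    out = []
    for cell_id in day.cell_ids:
        label = CellTypeLabel(cell_id=cell_id)
        for name in config.scores:
            svals, cuts, passed = [], [], 0
            for s_idx, session in enumerate(day.sessions):
                spikes = session.unit(cell_id).times
                fn = score_fns[(name, s_idx)]
                val = fn(spikes)
                svals.append(val)
                if name == "theta":
                    cut = config.theta_strength_min
                else:
                    child = np.random.SeedSequence(
                        entropy=root.entropy,
                        spawn_key=(
                            zlib.crc32(cell_id.encode()),
                            zlib.crc32(name.encode()),
                            s_idx,
                        ),
                    )
                    try:
                        res = shuffle_cutoff(
                            fn,
                            spikes,
                            session.duration,
                            config.n_shuffles,
                            seed=np.random.default_rng(child),
                        )
                        cut = res.cutoff(config.percentile)
                    except ValueError:
                        cut = float("nan")
                cuts.append(cut)
                if np.isfinite(val) and np.isfinite(cut) and val > cut:
                    passed += 1
            label.session_scores[name] = svals
            label.session_cutoffs[name] = cuts
            label.sessions_passed[name] = passed
            if passed >= config.min_sessions:
                if name == "hd":
                    med = np.nanmedian(svals)
                    label.labels.add(
                        "narrow_hd" if med > config.hd_split_score else "broad_hd"
                    )
                elif name == "theta":
                    label.labels.add("theta_modulated")
                else:
                    label.labels.add(name)
        if "grid" in label.labels and (
            "narrow_hd" in label.labels or "broad_hd" in label.labels
        ):
            label.labels.add("conjunctive")
        out.append(label)
    return out


# ---------------------------------------------------------------------------
# interneurons
# ---------------------------------------------------------------------------

RATE_CUTOFF_HZ = 5.0
PEAK_VALLEY_CUTOFF = 1.3


def classify_interneuron(profile: InterneuronProfile) -> str:
    """'interneuron' (fast, symmetric waveform), 'principal', or
    'excluded' for the two ambiguous quadrants of the (rate, ratio) plane."""
    fast = profile.mean_rate_hz >= RATE_CUTOFF_HZ
    symmetric = profile.peak_valley_ratio <= PEAK_VALLEY_CUTOFF
    if fast and symmetric:
        return "interneuron"
    if (not fast) and (not symmetric):
        return "principal"
    return "excluded"


def spike_autocorrelogram(
    spikes: np.ndarray, max_lag_ms: float = 50.0, bin_ms: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Positive-lag spike-time autocorrelogram (symmetric lags pooled).

    Returns (bin centers in ms, pair counts per bin).
    """
    t = np.asarray(spikes, dtype=float)
    max_lag = max_lag_ms / 1000.0
    edges = np.arange(0.0, max_lag_ms + bin_ms, bin_ms)
    counts = np.zeros(len(edges) - 1)
    hi = np.searchsorted(t, t + max_lag, side="right")
    for i in range(len(t)):
        if hi[i] > i + 1:
            lags_ms = (t[i + 1 : hi[i]] - t[i]) * 1000.0
            c, _ = np.histogram(lags_ms, bins=edges)
            counts += c
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, counts


def burst_index(spikes: np.ndarray, min_spikes: int = 100) -> float:
    """Burstiness in [-1, 1] from the 1 ms autocorrelogram: the 0-10 ms
    peak against the 40-50 ms mean, normalized by the larger of the two.
    Positive for bursty cells, ~0 for Poisson-like, negative for regular
    or refractory firing."""
    if len(spikes) < min_spikes:
        return float("nan")
    centers, counts = spike_autocorrelogram(spikes)
    early = counts[(centers > 0) & (centers < 10)].max(initial=0.0)
    late = counts[(centers > 40) & (centers < 50)].mean()
    denom = max(early, late)
    if denom == 0:
        return float("nan")
    return float((early - late) / denom)


def interneuron_profiles(
    sessions: Sequence[SessionBundle],
) -> dict[str, InterneuronProfile]:
    """Per-unit mean rate, waveform ratio, and burst index over a day."""
    out: dict[str, InterneuronProfile] = {}
    for cell_id in [u.cell_id for u in sessions[0].units]:
        rates, all_spikes, pv = [], [], []
        offset = 0.0
        for s in sessions:
            u = s.unit(cell_id)
            rates.append(len(u.times) / s.duration)
            pv.append(u.peak_valley_ratio)
            all_spikes.append(u.times + offset)
            offset += s.duration

        out[cell_id] = InterneuronProfile(
            mean_rate_hz=float(np.mean(rates)),
            peak_valley_ratio=float(np.mean(pv)),
            burst_index=burst_index(np.concatenate(all_spikes)),
        )
    return out
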