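"""Tuning and accuracy metrics on peri-stimulus spike windows.

The transient effects of the light pulses are measured by restricting a
cell's spikes to short windows locked to each pulse: the per-cell
inhibition window (I), a fixed early-excitation window (E, 0-10 ms), a
matched pre-light control (Pre), and post-recovery windows.  Because a
tuning statistic computed from few spikes is biased, every Pre control
is downsampled without replacement to exactly the I (or E) spike count
and averaged over 50 random draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .optoresponse import InhibitionWindow, Psth
from .ratemap import FieldSet, spike_positions
from .synthdata import LfpSignal, StimTrain, Trajectory
from .tuning import hd_score_of_headings, resultant, spike_theta_phases

__all__ = [
    "WindowSpec",
    "WindowedMetric",
    "extract_window_spikes",
    "windowed_speed_score",
    "windowed_hd_score",
    "out_of_field_fraction",
    "distance_to_nodes",
    "rate_modulation_ratio",
    "windowed_theta_modulation",
]

N_ITER_DEFAULT = 50


@dataclass
class WindowSpec:
    """A peri-stimulus window, in ms relative to pulse onset."""

    kind: str  # {"I", "E", "Pre", "Pre15", "Post_fixed", "Post_recovered"}
    start_ms: float
    end_ms: float

    @classmethod
    def fixed(cls, kind: str, inh: InhibitionWindow | None = None) -> "WindowSpec":
        table = {
            "E": (0.0, 10.0),
            "Pre": (-30.0, 0.0),
            "Pre15": (-15.0, 0.0),
            "Post_fixed": (10.0, 25.0),
        }
        if kind in table:
            return cls(kind, *table[kind])
        if kind == "I":
            if inh is None:
                raise ValueError("I window needs an InhibitionWindow")
            return cls("I", inh.t_start_ms, inh.t_end_ms)
        if kind == "Post_recovered":
            if inh is None:
                raise ValueError("Post_recovered window needs an InhibitionWindow")
            return cls("Post_recovered", inh.t_end_ms, 40.0)
        raise ValueError(f"unknown window kind {kind!r}")

    @property
    def center_ms(self) -> float:
        return (self.start_ms + self.end_ms) / 2.0


@dataclass
class WindowedMetric:
    metric: str
    value_test: float
    value_control: float
    n_spikes_test: int
    n_iter: int
    extra: dict | None = None


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

def extract_window_spikes(
    spikes: np.ndarray, stim: StimTrain, spec: WindowSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Spike times falling in the window of any trial.

    Returns ``(times, trial_index)`` with times in seconds (absolute
    session time) sorted ascending.
    """
    spikes = np.asarray(spikes, dtype=float)
    times, trials = [], []
    for k, onset in enumerate(stim.onsets):
        lo = np.searchsorted(spikes, onset + spec.start_ms / 1000.0)
        hi = np.searchsorted(spikes, onset + spec.end_ms / 1000.0)
        if hi > lo:
            times.append(spikes[lo:hi])
            trials.append(np.full(hi - lo, k))
    if not times:
        return np.empty(0), np.empty(0, dtype=int)
    return np.concatenate(times), np.concatenate(trials)


def _downsample(
    values: np.ndarray, n_target: int, rng: np.random.Generator
) -> np.ndarray:
    idx = rng.choice(len(values), size=n_target, replace=False)
    return idx


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _speed_at(trajectory: Trajectory, speed_series: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Speed at the video frame closest to each time."""
    idx = np.searchsorted(trajectory.t, t)
    idx = np.clip(idx, 1, len(trajectory.t) - 1)
    left = (t - trajectory.t[idx - 1]) < (trajectory.t[idx] - t)
    idx = np.where(left, idx - 1, idx)
    return speed_series[idx]


def windowed_speed_score(
    spikes: np.ndarray,
    stim: StimTrain,
    trajectory: Trajectory,
    speed_series: np.ndarray,
    inh: InhibitionWindow,
    n_iter: int = N_ITER_DEFAULT,
    seed: int | np.random.Generator = 0,
    min_trials_with_spikes: int = 20,
) -> WindowedMetric:
    """Speed tuning inside the inhibition window vs matched Pre control.

    Test value: Pearson correlation across trials between the I-window
    spike count and the speed at the frame nearest the I-window center.
    Control: pre-light (-30 to 0 ms) spikes downsampled to the total I
    count, counted per trial, correlated with speed at -15 ms; averaged
    over ``n_iter`` draws.
    """
    rng = np.random.default_rng(seed)
    i_spec = WindowSpec.fixed("I", inh)
    pre_spec = WindowSpec.fixed("Pre")
    _, i_trials = extract_window_spikes(spikes, stim, i_spec)
    pre_times, pre_trials = extract_window_spikes(spikes, stim, pre_spec)

    n_trials = len(stim.onsets)
    i_counts = np.bincount(i_trials, minlength=n_trials).astype(float)
    n_i = int(i_counts.sum())
    if (i_counts > 0).sum() < min_trials_with_spikes:
        raise ValueError("too few trials with I-window spikes")
    if n_i > len(pre_times):
        raise ValueError("fewer Pre spikes than I spikes; cannot match counts")

    speed_i = _speed_at(
        trajectory, speed_series, stim.onsets + i_spec.center_ms / 1000.0
    )
    speed_pre = _speed_at(trajectory, speed_series, stim.onsets - 0.015)

    value_i = float(np.corrcoef(i_counts, speed_i)[0, 1])
    vals = np.empty(n_iter)
    for it in range(n_iter):
        keep = _downsample(pre_times, n_i, rng)
        c = np.bincount(pre_trials[keep], minlength=n_trials).astype(float)
        vals[it] = np.corrcoef(c, speed_pre)[0, 1]
    return WindowedMetric(
        metric="speed_score",
        value_test=value_i,
        value_control=float(np.nanmean(vals)),
        n_spikes_test=n_i,
        n_iter=n_iter,
    )


def _spike_headings(trajectory: Trajectory, t: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(trajectory.t, t)
    idx = np.clip(idx, 1, len(trajectory.t) - 1)
    left = (t - trajectory.t[idx - 1]) < (trajectory.t[idx] - t)
    idx = np.where(left, idx - 1, idx)
    return trajectory.hd[idx]


def windowed_hd_score(
    spikes: np.ndarray,
    stim: StimTrain,
    trajectory: Trajectory,
    mode: str = "fixed",
    inh: InhibitionWindow | None = None,
    n_iter: int = N_ITER_DEFAULT,
    seed: int | np.random.Generator = 0,
    pre_cutoff: float | None = None,
) -> WindowedMetric:
    """Head-direction tuning in peri-stimulus windows.

    ``mode='fixed'`` (narrow HD cells): HD score of all spikes in
    (+10, +25) ms vs all spikes in (-15, 0) ms, no downsampling.
    ``mode='inhibition'`` (broad HD cells): HD score in the per-cell I
    window vs pre-light (-30, 0 ms) spikes downsampled to the I count
    over ``n_iter`` draws.  When ``pre_cutoff`` is given (the cell's
    shuffled HD cutoff), cells whose Pre score does not beat it are
    rejected, so that downsampling bias cannot masquerade as tuning.
    """
    rng = np.random.default_rng(seed)
    if mode == "fixed":
        test_spec = WindowSpec.fixed("Post_fixed")
        ctrl_spec = WindowSpec.fixed("Pre15")
    elif mode == "inhibition":
        test_spec = WindowSpec.fixed("I", inh)
        ctrl_spec = WindowSpec.fixed("Pre")
    else:
        raise ValueError("mode must be 'fixed' or 'inhibition'")

    test_times, _ = extract_window_spikes(spikes, stim, test_spec)
    ctrl_times, _ = extract_window_spikes(spikes, stim, ctrl_spec)
    if len(test_times) == 0 or len(ctrl_times) == 0:
        raise ValueError("empty peri-stimulus window")
    test_hd = _spike_headings(trajectory, test_times)
    value_test = hd_score_of_headings(test_hd)

    if mode == "fixed":
        value_ctrl = hd_score_of_headings(_spike_headings(trajectory, ctrl_times))
        n_iter_used = 1
    else:
        n_t = len(test_times)
        if n_t > len(ctrl_times):
            raise ValueError("fewer Pre spikes than I spikes; cannot match counts")
        ctrl_hd = _spike_headings(trajectory, ctrl_times)
        vals = np.empty(n_iter)
        for it in range(n_iter):
            keep = _downsample(ctrl_times, n_t, rng)
            vals[it] = hd_score_of_headings(ctrl_hd[keep])
        value_ctrl = float(np.nanmean(vals))
        n_iter_used = n_iter
        if pre_cutoff is not None and not value_ctrl > pre_cutoff:
            raise ValueError(
                "cell excluded: Pre HD tuning does not exceed its shuffled cutoff"
            )
    return WindowedMetric(
        metric="hd_score",
        value_test=value_test,
        value_control=value_ctrl,
        n_spikes_test=int(len(test_times)),
        n_iter=n_iter_used,
    )


def out_of_field_fraction(
    spike_times: np.ndarray,
    fieldset: FieldSet,
    trajectory: Trajectory,
    bin_size_cm: float = 3.0,
) -> float:
    """Fraction of spikes whose position falls inside no detected field."""
    if len(spike_times) == 0:
        raise ValueError("no spikes in the window")
    if len(fieldset) == 0:
        return 1.0
    sx, sy = spike_positions(np.asarray(spike_times, float), trajectory)
    n = int(np.ceil(trajectory.box_size_cm / bin_size_cm - 1e-9))
    grid = fieldset.membership_grid((n, n))
    ix = np.clip((sx / bin_size_cm).astype(int), 0, n - 1)
    iy = np.clip((sy / bin_size_cm).astype(int), 0, n - 1)
    inside = grid[ix, iy] >= 0
    return float(1.0 - inside.mean())


def distance_to_nodes(
    i_spike_times: np.ndarray,
    pre_spike_times: np.ndarray,
    fieldset: FieldSet,
    trajectory: Trajectory,
    n_iter: int = N_ITER_DEFAULT,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Mean spike-to-nearest-grid-node distance over grid spacing.

    Returns ``(norm_dist_I, norm_dist_Pre, norm_dist_random)`` where Pre
    is downsampled to the I spike count and random draws the same number
    of x-y coordinates uniformly from the animal's path, both averaged
    over ``n_iter`` draws.
    """
    if len(fieldset) < 2:
        raise ValueError("distance to nodes needs >= 2 fields")
    if len(i_spike_times) == 0:
        raise ValueError("no spikes in the I window")
    rng = np.random.default_rng(seed)
    spacing = fieldset.grid_spacing_cm
    tree = cKDTree(fieldset.centroids)

    def norm_dist(x, y):
        d, _ = tree.query(np.column_stack([x, y]))
        return float(np.mean(d)) / spacing

    ix, iy = spike_positions(np.asarray(i_spike_times, float), trajectory)
    val_i = norm_dist(ix, iy)
    n_i = len(i_spike_times)
    if n_i > len(pre_spike_times):
        raise ValueError("fewer Pre spikes than I spikes; cannot match counts")
    px, py = spike_positions(np.asarray(pre_spike_times, float), trajectory)

    pre_vals = np.empty(n_iter)
    rand_vals = np.empty(n_iter)
    n_frames = len(trajectory.t)
    for it in range(n_iter):
        keep = _downsample(pre_spike_times, n_i, rng)
        pre_vals[it] = norm_dist(px[keep], py[keep])
        f = rng.integers(0, n_frames, size=n_i)
        rand_vals[it] = norm_dist(trajectory.x[f], trajectory.y[f])
    return val_i, float(pre_vals.mean()), float(rand_vals.mean())


def rate_modulation_ratio(psth: Psth) -> float:
    """Mean rate in +10..+25 ms over mean rate in -15..0 ms (NaN if the
    pre-window rate is zero)."""
    lefts, rates = psth.rates(1.0)
    post = rates[(lefts >= 10) & (lefts < 25)]
    pre = rates[(lefts >= -15) & (lefts < 0)]
    if pre.mean() == 0:
        return float("nan")
    return float(post.mean() / pre.mean())


def windowed_theta_modulation(
    spikes: np.ndarray,
    stim: StimTrain,
    lfp: LfpSignal,
    inh: InhibitionWindow,
    n_iter: int = N_ITER_DEFAULT,
    seed: int | np.random.Generator = 0,
) -> tuple[WindowedMetric, WindowedMetric]:
    """Theta phase locking of I-window spikes vs matched Pre spikes.

    Returns (strength metric, phase metric); phases in degrees.
    """
    rng = np.random.default_rng(seed)
    i_times, _ = extract_window_spikes(spikes, stim, WindowSpec.fixed("I", inh))
    pre_times, _ = extract_window_spikes(spikes, stim, WindowSpec.fixed("Pre"))
    if len(i_times) == 0 or len(pre_times) == 0:
        raise ValueError("empty peri-stimulus window")
    n_i = len(i_times)
    if n_i > len(pre_times):
        raise ValueError("fewer Pre spikes than I spikes; cannot match counts")
    ph_i = spike_theta_phases(i_times, lfp)
    s_i, m_i = resultant(ph_i)
    ph_pre = spike_theta_phases(pre_times, lfp)
    s_vals = np.empty(n_iter)
    m_sin = np.empty(n_iter)
    m_cos = np.empty(n_iter)
    for it in range(n_iter):
        keep = _downsample(pre_times, n_i, rng)
        s, m = resultant(ph_pre[keep])
        s_vals[it] = s
        m_sin[it], m_cos[it] = np.sin(m), np.cos(m)
    mean_phase_pre = float(np.degrees(np.arctan2(m_sin.mean(), m_cos.mean())))
    strength = WindowedMetric(
        metric="theta_strength",
        value_test=s_i,
        value_control=float(s_vals.mean()),
        n_spikes_test=n_i,
        n_iter=n_iter,
    )
    phase = WindowedMetric(
        metric="theta_phase_deg",
        value_test=float(np.degrees(m_i)),
        value_control=mean_phase_pre,
        n_spikes_test=n_i,
        n_iter=n_iter,
    )
    return strength, phase
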