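"""Peri-stimulus rasters/histograms and light-response classification.

Each unit's spikes are aligned to pulse onsets in a +-40 ms window.  The
per-cell baseline is Mean_pre, the average rate in the 40 ms before each
pulse.  Excitation and inhibition are judged against *population*
empirical nulls: the distribution over cells of the pre-light maximum
normalized 1 ms-bin rate (excitation) and of the pre-light minimum
normalized 10 ms sliding-window rate (inhibition).  A cell is excited if
any post-light 1 ms bin beats the 95%-tail of the baseline maxima, and
inhibited if any post-light 10 ms window falls below the 95%-confidence
tail of the baseline minima.  Excitation latency comes from the 0.1 ms
PSTH half-peak rise, jitter from per-trial first-spike latencies, and
the inhibition window runs from the post-light rate minimum until
recovery to a stated fraction of baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthdata import StimTrain

__all__ = [
    "Psth",
    "ResponseClass",
    "InhibitionWindow",
    "build_psth",
    "population_null",
    "classify_excited",
    "classify_inhibited",
    "classify_response",
    "inhibition_window",
]

WINDOW_MS = 40.0


@dataclass
class Psth:
    """Trial-aligned raster in a +-40 ms window around pulse onsets.

    ``trial_spikes`` holds, per trial, spike times in ms relative to the
    pulse onset; histograms at any bin width are derived on demand.
    """

    trial_spikes: list
    n_trials: int
    mean_pre: float  # Hz, average rate in [-40, 0) ms
    window_ms: float = WINDOW_MS
    truncated_trials: int = 0

    def counts(self, bin_width_ms: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """(bin left edges in ms, summed spike counts per bin)."""
        edges = np.arange(-self.window_ms, self.window_ms + bin_width_ms / 2, bin_width_ms)
        pooled = (
            np.concatenate(self.trial_spikes) if self.trial_spikes else np.empty(0)
        )
        c, _ = np.histogram(pooled, bins=edges)
        return edges[:-1], c

    def rates(self, bin_width_ms: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """(bin left edges in ms, trial-averaged rate per bin in Hz)."""
        lefts, c = self.counts(bin_width_ms)
        return lefts, c / (self.n_trials * bin_width_ms / 1000.0)


@dataclass
class ResponseClass:
    excited: bool
    inhibited: bool
    exc_latency_ms: float = np.nan
    jitter_ms: float = np.nan
    inh_latency_ms: float = np.nan

    @property
    def category(self) -> str:
        if self.excited and self.inhibited:
            return "both"
        if self.excited:
            return "excited"
        if self.inhibited:
            return "inhibited"
        return "none"


@dataclass
class InhibitionWindow:
    t_start_ms: float
    t_end_ms: float
    recovery_fraction: float
    capped: bool = False


# ---------------------------------------------------------------------------

def build_psth(
    spikes: np.ndarray, stim: StimTrain, session_duration: float | None = None
) -> Psth:
    """Align spikes to pulse onsets in +-40 ms windows.

    Trials whose window crosses the session edge are dropped; when pulses
    repeat faster than 12.5 Hz each trial is truncated at the next onset
    and flagged.
    """
    if len(stim.onsets) == 0:
        raise ValueError("stim train has no onsets")
    spikes = np.asarray(spikes, dtype=float)
    w = WINDOW_MS / 1000.0
    onsets = stim.onsets
    period = np.min(np.diff(onsets)) if len(onsets) > 1 else np.inf
    truncate = period < 2 * w

    trial_spikes = []
    n_pre = 0
    truncated = 0
    for k, onset in enumerate(onsets):
        if onset - w < 0:
            continue
        end = onset + w
        if truncate and k + 1 < len(onsets):
            end = min(end, onsets[k + 1])
            if end < onset + w:
                truncated += 1
        if session_duration is not None and end > session_duration:
            continue
        lo = np.searchsorted(spikes, onset - w)
        hi = np.searchsorted(spikes, end)
        rel = (spikes[lo:hi] - onset) * 1000.0
        trial_spikes.append(rel)
        n_pre += int(np.sum(rel < 0))
    n_trials = len(trial_spikes)
    if n_trials == 0:
        raise ValueError("no complete trials in the session")
    mean_pre = n_pre / (n_trials * w)
    return Psth(
        trial_spikes=trial_spikes,
        n_trials=n_trials,
        mean_pre=mean_pre,
        truncated_trials=truncated,
    )


def _normalized_bins(psth: Psth, side: str, bin_ms: float = 1.0) -> np.ndarray:
    lefts, rates = psth.rates(bin_ms)
    sel = lefts < 0 if side == "pre" else lefts >= 0
    return rates[sel] / psth.mean_pre


def _sliding_window_means(x: np.ndarray, width: int = 10) -> np.ndarray:
    c = np.convolve(x, np.ones(width) / width, mode="valid")
    return c


def population_null(psths: list[Psth], kind: str) -> float:
    """Population threshold from the pre-light side of every cell's PSTH.

    ``kind='excitation'``: 95th percentile over cells of the maximum
    normalized pre-light 1 ms-bin rate.  ``kind='inhibition'``: the
    5%-tail (extreme-decrease side) of the per-cell minimum normalized
    rate over 10 ms sliding windows (1 ms step), a value below 1.  Cells
    with zero baseline are excluded.
    """
    stats = []
    for p in psths:
        if p.mean_pre <= 0:
            continue
        pre = _normalized_bins(p, "pre", 1.0)
        if kind == "excitation":
            stats.append(pre.max())
        elif kind == "inhibition":
            stats.append(_sliding_window_means(pre, 10).min())
        else:
            raise ValueError("kind must be 'excitation' or 'inhibition'")
    if not stats:
        raise ValueError("no cells with nonzero baseline")
    if kind == "excitation":
        return float(np.percentile(stats, 95))
    return float(np.percentile(stats, 5))


def classify_excited(
    psth: Psth, threshold: float
) -> tuple[bool, float, float]:
    """(excited?, latency in ms, jitter in ms).

    Excited when any post-light normalized 1 ms bin exceeds the
    population threshold.  Latency: first 0.1 ms bin at which the rate
    rise exceeds half the post-light peak.  Jitter: SD over trials of the
    first-spike latency, trials with no spike within 10 ms dropped.
    """
    if psth.mean_pre <= 0:
        raise ValueError("cell has zero baseline rate; unclassifiable")
    post = _normalized_bins(psth, "post", 1.0)
    excited = bool(post.max() > threshold)

    lefts, rates = psth.rates(0.1)
    post_sel = lefts >= 0
    post_rates = rates[post_sel]
    post_lefts = lefts[post_sel]
    latency = np.nan
    if post_rates.max() > 0:
        half = post_rates.max() / 2.0
        above = np.nonzero(post_rates > half)[0]
        if len(above):
            latency = float(post_lefts[above[0]])

    firsts = []
    for rel in psth.trial_spikes:
        in_win = rel[(rel > 0) & (rel <= 10.0)]
        if len(in_win):
            firsts.append(in_win[0])
    jitter = float(np.std(firsts, ddof=1)) if len(firsts) >= 2 else np.nan
    return excited, latency, jitter


def classify_inhibited(psth: Psth, threshold: float) -> tuple[bool, float]:
    """(inhibited?, latency in ms of the minimum 10 ms window's start).

    Inhibited when the mean normalized rate in any post-light 10 ms
    sliding window (1 ms step) falls below the population threshold.
    """
    if psth.mean_pre <= 0:
        raise ValueError("cell has zero baseline rate; unclassifiable")
    post = _normalized_bins(psth, "post", 1.0)
    win = _sliding_window_means(post, 10)
    k = int(np.argmin(win))
    return bool(win[k] < threshold), float(k)


def classify_response(
    psth: Psth, exc_threshold: float, inh_threshold: float
) -> ResponseClass:
    """Independent excitation and inhibition classification of one cell."""
    exc, lat, jit = classify_excited(psth, exc_threshold)
    inh, inh_lat = classify_inhibited(psth, inh_threshold)
    return ResponseClass(
        excited=exc,
        inhibited=inh,
        exc_latency_ms=lat,
        jitter_ms=jit,
        inh_latency_ms=inh_lat if inh else np.nan,
    )


def inhibition_window(
    psth: Psth, recovery_fraction: float = 0.5, smooth_bins: int = 3
) -> InhibitionWindow:
    """Per-cell inhibition window on the 1 ms PSTH.

    Starts at the post-light rate minimum (after a ``smooth_bins``-wide
    moving average, which keeps single-bin noise from planting the
    minimum), ends at the first later bin whose smoothed rate regains
    ``recovery_fraction`` of Mean_pre; capped at +40 ms with a flag when
    the cell never recovers inside the window.
    """
    if not 0.0 < recovery_fraction <= 1.0:
        raise ValueError("recovery_fraction must be in (0, 1]")
    lefts, rates = psth.rates(1.0)
    sel = lefts >= 0
    post = rates[sel]
    post_lefts = lefts[sel]
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        post = np.convolve(post, kernel, mode="same")
    k = int(np.argmin(post))
    t_start = float(post_lefts[k])
    target = recovery_fraction * psth.mean_pre
    rec = np.nonzero(post[k + 1 :] >= target)[0]
    if len(rec):
        t_end = float(post_lefts[k + 1 + rec[0]])
        capped = False
    else:
        t_end = float(WINDOW_MS)
        capped = True
    return InhibitionWindow(
        t_start_ms=t_start,
        t_end_ms=t_end,
        recovery_fraction=recovery_fraction,
        capped=capped,
    )
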