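"""Occupancy and firing-rate maps, firing-field boundaries, grid spacing.

The open field is divided into square bins (3 x 3 cm by default).  The
rate in each bin is the spike count divided by dwell time, smoothed with
a fixed 5 x 5 kernel by NaN-aware normalized convolution.  Bins far from
the tracked path (> 2.5 cm) or with under 150 ms of occupancy are masked
to NaN.  Firing fields are extracted by contouring each local peak down
to 0.3 of its rate, repeating while peaks above 2 Hz remain, and then
partitioning contested bins by simultaneous region growing from all
peaks.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import convolve
from scipy.spatial import cKDTree

from .synthdata import Trajectory

__all__ = [
    "SMOOTHING_KERNEL",
    "RateMap",
    "Field",
    "FieldSet",
    "compute_occupancy",
    "compute_ratemap",
    "smooth_map",
    "detect_fields",
    "grid_spacing_of",
]

# fixed 5x5 smoothing kernel (sums to 1)
SMOOTHING_KERNEL = np.array(
    [
        [0.0025, 0.0125, 0.0200, 0.0125, 0.0025],
        [0.0125, 0.0625, 0.1000, 0.0625, 0.0125],
        [0.0200, 0.1000, 0.1600, 0.1000, 0.0200],
        [0.0125, 0.0625, 0.1000, 0.0625, 0.0125],
        [0.0025, 0.0125, 0.0200, 0.0125, 0.0025],
    ]
)

PEAK_RATE_MIN_HZ = 2.0  # fields must peak above this
FIELD_CONTOUR_FRACTION = 0.3  # contour level relative to the field peak
MIN_OCCUPANCY_S = 0.150
MAX_PATH_DISTANCE_CM = 2.5


@dataclass
class RateMap:
    """Binned, smoothed firing-rate map with NaN mask.

    ``values[i, j]`` covers x in [i*b, (i+1)*b) and y in [j*b, (j+1)*b)
    cm (half-open); entries are Hz or NaN where masked.
    """

    bin_size_cm: float
    values: np.ndarray
    occupancy_s: np.ndarray
    raw_values: np.ndarray | None = None

    @property
    def nan_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        b = self.bin_size_cm
        xc = (np.arange(self.shape[0]) + 0.5) * b
        yc = (np.arange(self.shape[1]) + 0.5) * b
        return xc, yc


@dataclass
class Field:
    bins: set
    centroid_cm: tuple[float, float]
    peak_rate_hz: float
    peak_bin: tuple[int, int]
    boundary: np.ndarray | None = None  # (k, 2) polygon in cm, may be None


@dataclass
class FieldSet:
    fields: list[Field] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fields)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([f.centroid_cm for f in self.fields]).reshape(-1, 2)

    @property
    def grid_spacing_cm(self) -> float:
        return grid_spacing_of(self)

    def membership_grid(self, shape: tuple[int, int]) -> np.ndarray:
        """Integer grid: field index per bin, -1 outside all fields."""
        grid = np.full(shape, -1, dtype=int)
        for k, f in enumerate(self.fields):
            for i, j in f.bins:
                grid[i, j] = k
        return grid


# ---------------------------------------------------------------------------
# occupancy & rate
# ---------------------------------------------------------------------------

def _bin_index(coords: np.ndarray, bin_size: float, n_bins: int) -> np.ndarray:
    idx = np.floor(np.asarray(coords) / bin_size).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _grid_shape(box_size: float, bin_size: float) -> int:
    return int(math.ceil(box_size / bin_size - 1e-9))


def compute_occupancy(trajectory: Trajectory, bin_size_cm: float = 3.0) -> np.ndarray:
    """Per-bin dwell time in seconds: frame count times the frame interval."""
    if len(trajectory.t) == 0:
        raise ValueError("empty trajectory")
    n = _grid_shape(trajectory.box_size_cm, bin_size_cm)
    dt = 1.0 / trajectory.fs if len(trajectory.t) > 1 else 0.0
    ix = _bin_index(trajectory.x, bin_size_cm, n)
    iy = _bin_index(trajectory.y, bin_size_cm, n)
    occ = np.zeros((n, n))
    np.add.at(occ, (ix, iy), dt)
    return occ


def spike_positions(
    spikes: np.ndarray, trajectory: Trajectory
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each spike the position of the nearest-in-time frame."""
    idx = np.searchsorted(trajectory.t, spikes)
    idx = np.clip(idx, 1, len(trajectory.t) - 1)
    left_closer = (spikes - trajectory.t[idx - 1]) < (trajectory.t[idx] - spikes)
    idx = np.where(left_closer, idx - 1, idx)
    return trajectory.x[idx], trajectory.y[idx]


def smooth_map(values: np.ndarray, nan_mask: np.ndarray | None = None) -> np.ndarray:
    """NaN-aware normalized convolution with the fixed 5x5 kernel.

    At each bin the output is the kernel-weighted average over valid
    neighbors, with weights renormalized to sum to 1 over valid bins;
    neighborhoods with no valid bin stay NaN.  A constant map (with or
    without scattered NaNs) is left unchanged on its valid bins.
    """
    values = np.asarray(values, dtype=float)
    if nan_mask is None:
        nan_mask = np.isnan(values)
    valid = (~nan_mask).astype(float)
    filled = np.where(nan_mask, 0.0, values)
    num = convolve(filled, SMOOTHING_KERNEL, mode="constant", cval=0.0)
    den = convolve(valid, SMOOTHING_KERNEL, mode="constant", cval=0.0)
    out = np.full_like(values, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    out[nan_mask] = np.nan
    return out


def compute_ratemap(
    spikes: np.ndarray,
    trajectory: Trajectory,
    bin_size_cm: float = 3.0,
    smooth: bool = True,
) -> RateMap:
    """Spikes-per-dwell-time rate map, smoothed and NaN-masked.

    Raw rate = spike count / occupancy per bin; bins never visited are NaN
    before smoothing.  After smoothing, bins whose center lies more than
    2.5 cm from every tracked sample or with under 150 ms of occupancy are
    set to NaN.
    """
    spikes = np.asarray(spikes, dtype=float)
    if len(spikes) and (
        spikes[0] < trajectory.t[0] - 1.0 or spikes[-1] > trajectory.duration + 1.0
    ):
        raise ValueError("spike times outside the trajectory time range")
    occ = compute_occupancy(trajectory, bin_size_cm)
    n = occ.shape[0]
    counts = np.zeros_like(occ)
    if len(spikes):
        sx, sy = spike_positions(spikes, trajectory)
        np.add.at(
            counts,
            (_bin_index(sx, bin_size_cm, n), _bin_index(sy, bin_size_cm, n)),
            1.0,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = counts / occ
    raw[occ == 0] = np.nan

    values = smooth_map(raw) if smooth else raw.copy()

    # final mask: low occupancy, or bin center far from the tracked path
    xc, yc = np.meshgrid(
        (np.arange(n) + 0.5) * bin_size_cm,
        (np.arange(n) + 0.5) * bin_size_cm,
        indexing="ij",
    )
    tree = cKDTree(np.column_stack([trajectory.x, trajectory.y]))
    dist, _ = tree.query(np.column_stack([xc.ravel(), yc.ravel()]))
    far = dist.reshape(n, n) > MAX_PATH_DISTANCE_CM
    values[far | (occ < MIN_OCCUPANCY_S)] = np.nan
    return RateMap(
        bin_size_cm=bin_size_cm, values=values, occupancy_s=occ, raw_values=raw
    )


# ---------------------------------------------------------------------------
# fields
# ---------------------------------------------------------------------------

def _grow_region(
    values: np.ndarray, peak: tuple[int, int], level: float, available: np.ndarray
) -> set:
    """Connected bins (4-neighborhood) around ``peak`` with value >= level."""
    n0, n1 = values.shape
    seen = {peak}
    stack = [peak]
    out = set()
    while stack:
        i, j = stack.pop()
        v = values[i, j]
        if not available[i, j] or not np.isfinite(v) or v < level:
            continue
        out.add((i, j))
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            q = (i + di, j + dj)
            if 0 <= q[0] < n0 and 0 <= q[1] < n1 and q not in seen:
                seen.add(q)
                stack.append(q)
    return out


def _field_boundary(values: np.ndarray, level: float, bin_size: float, peak) -> np.ndarray | None:
    """Sub-bin boundary polygon via marching squares at the contour level."""
    try:
        from skimage import measure
    except ImportError:  # pragma: no cover
        return None
    filled = np.where(np.isfinite(values), values, 0.0)
    contours = measure.find_contours(filled, level)
    px, py = (peak[0] + 0.5) * bin_size, (peak[1] + 0.5) * bin_size
    best, best_d = None, np.inf
    for c in contours:
        poly = (c + 0.5) * bin_size
        d = np.min(np.hypot(poly[:, 0] - px, poly[:, 1] - py))
        if d < best_d:
            best, best_d = poly, d
    return best


def detect_fields(ratemap: RateMap) -> FieldSet:
    """Extract firing fields from a smoothed rate map.

    Phase 1: repeatedly take the highest unassigned bin; if its rate is
    above 2 Hz, grow the connected region above 0.3 x that peak and claim
    it.  Phase 2: re-partition simultaneously -- a multi-source best-first
    growth from all peaks where a bin joins the first field that reaches
    it (subject to that field's own 0.3-peak level), ties going to the
    field with the higher peak.
    """
    values = ratemap.values
    if not np.any(np.isfinite(values)):
        return FieldSet([])
    available = np.isfinite(values)

    # candidate peaks are local maxima of the smoothed map; a bare "highest
    # remaining bin" rule would seed new fields on the shoulders of already
    # extracted ones (the bins just outside a 0.3-contour), which are not
    # firing fields
    filled = np.where(available, values, -np.inf)
    from scipy.ndimage import maximum_filter

    is_max = (filled == maximum_filter(filled, size=3)) & available
    cand = sorted(
        ((float(values[p]), (int(p[0]), int(p[1]))) for p in zip(*np.nonzero(is_max))),
        reverse=True,
    )

    peaks: list[tuple[int, int]] = []
    claimed = np.zeros_like(available)
    for peak_rate, peak in cand:
        if peak_rate <= PEAK_RATE_MIN_HZ:
            break
        if claimed[peak]:
            continue
        region = _grow_region(
            values, peak, FIELD_CONTOUR_FRACTION * peak_rate, available & ~claimed
        )
        region.add(peak)
        for i, j in region:
            claimed[i, j] = True
        peaks.append(peak)

    if not peaks:
        return FieldSet([])

    # phase 2: simultaneous growth; priority = number of growth steps from
    # the seed (breadth-first rings), ties broken toward the higher peak
    peak_rates = [float(values[p]) for p in peaks]
    order = np.argsort(peak_rates)[::-1]
    owner = np.full(values.shape, -1, dtype=int)
    heap: list[tuple[int, int, int, int]] = []
    for rank, k in enumerate(order):
        i, j = peaks[k]
        heapq.heappush(heap, (0, rank, i, j))
    levels = {int(k): FIELD_CONTOUR_FRACTION * peak_rates[k] for k in range(len(peaks))}
    rank_to_field = {rank: int(k) for rank, k in enumerate(order)}
    n0, n1 = values.shape
    while heap:
        dist, rank, i, j = heapq.heappop(heap)
        if owner[i, j] != -1:
            continue
        k = rank_to_field[rank]
        if not available[i, j] or values[i, j] < levels[k]:
            continue
        owner[i, j] = k
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            qi, qj = i + di, j + dj
            if 0 <= qi < n0 and 0 <= qj < n1 and owner[qi, qj] == -1:
                heapq.heappush(heap, (dist + 1, rank, qi, qj))
    # seeds always own themselves
    for k, p in enumerate(peaks):
        owner[p] = k

    b = ratemap.bin_size_cm
    fields = []
    for k, p in enumerate(peaks):
        bins = {tuple(map(int, ij)) for ij in zip(*np.nonzero(owner == k))}
        if not bins:
            continue
        arr = np.array(sorted(bins), dtype=float)
        centroid = tuple((arr.mean(axis=0) + 0.5) * b)
        fields.append(
            Field(
                bins=bins,
                centroid_cm=(float(centroid[0]), float(centroid[1])),
                peak_rate_hz=peak_rates[k],
                peak_bin=p,
                boundary=_field_boundary(values, levels[k], b, p),
            )
        )
    return FieldSet(fields)


def average_maps(maps: Sequence[RateMap]) -> RateMap:
    """Bin-wise average of session rate maps (the reference map).

    NaNs present in a minority of sessions are ignored; bins NaN in at
    least half of the sessions stay NaN.
    """
    if not maps:
        raise ValueError("no maps to average")
    stack = np.stack([m.values for m in maps])
    n_valid = np.isfinite(stack).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(
            n_valid > 0, np.nansum(np.nan_to_num(stack, nan=0.0), axis=0), np.nan
        ) / np.maximum(n_valid, 1)
    avg[n_valid < (len(maps) + 1) // 2] = np.nan
    occ = np.stack([m.occupancy_s for m in maps]).sum(axis=0)
    return RateMap(bin_size_cm=maps[0].bin_size_cm, values=avg, occupancy_s=occ)


def grid_spacing_of(fieldset: FieldSet) -> float:
    """Grid spacing: mean nearest-neighbor distance between field centroids."""
    if len(fieldset) < 2:
        raise ValueError("grid spacing needs >= 2 fields")
    c = fieldset.centroids
    d = np.hypot(c[:, None, 0] - c[None, :, 0], c[:, None, 1] - c[None, :, 1])
    np.fill_diagonal(d, np.inf)
    return float(np.mean(d.min(axis=1)))
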