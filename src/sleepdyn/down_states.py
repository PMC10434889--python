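"""DOWN/OFF-state detection and its relation to population recurrences.

Two detection rules are provided, matching the two recorded regions:

* ``neocortex-off`` — an OFF period is a maximal gap in the merged
  population spike train lasting between 50 and 1250 ms (near-total
  silence).
* ``hippocampus-fraction`` — a time bin is DOWN when strictly fewer than
  10% of the recorded neurons fired in it (hippocampal neurons keep a
  minimal firing level during DOWN states).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import IntervalSet, PopulationTrajectory, SpikeTrainSet, restrict_trajectory


@dataclass
class DownStateSeries:
    """Per-bin binary DOWN indicator aligned to a PopulationTrajectory."""

    is_down: np.ndarray
    bin_starts: np.ndarray
    bin_width: float
    rule: str = "neocortex-off"

    def __post_init__(self):
        self.is_down = np.asarray(self.is_down, dtype=np.uint8)
        self.bin_starts = np.asarray(self.bin_starts, dtype=float)
        if self.is_down.shape != self.bin_starts.shape:
            raise ValueError("is_down and bin_starts must align")
        if not np.isin(self.is_down, (0, 1)).all():
            raise ValueError("is_down must be binary")

    @property
    def n_bins(self) -> int:
        return self.is_down.size


def detect_off_periods(
    spikes: SpikeTrainSet,
    min_dur: float = 0.050,
    max_dur: float = 1.250,
) -> IntervalSet:
    """OFF periods: maximal inter-spike gaps of the merged population spike
    train with duration in ``[min_dur, max_dur]``.

    Gaps touching the recording edges are not scored (silence there is
    undefined).
    """
    merged = spikes.merged()
    if merged.size == 0:
        raise ValueError("empty spike set: population silence undefined")
    gaps = np.diff(merged)
    keep = (gaps >= min_dur) & (gaps <= max_dur)
    intervals = [(merged[i], merged[i + 1]) for i in np.flatnonzero(keep)]
    return IntervalSet(intervals, label="OFF")


def detect_on_periods(
    spikes: SpikeTrainSet,
    off: IntervalSet,
    min_spikes: int = 10,
    min_dur: float = 0.200,
    max_dur: float = 4.000,
) -> IntervalSet:
    """ON periods: segments between consecutive OFF periods containing at
    least ``min_spikes`` merged spikes and lasting ``min_dur``–``max_dur``.
    """
    merged = spikes.merged()
    out = []
    for (_, a), (b, _) in zip(off.intervals, off.intervals[1:]):
        dur = b - a
        if not (min_dur <= dur <= max_dur):
            continue
        n = int(np.searchsorted(merged, b, side="left")
                - np.searchsorted(merged, a, side="left"))
        if n >= min_spikes:
            out.append((a, b))
    return IntervalSet(out, label="ON")


def detect_fraction_down(
    traj: PopulationTrajectory,
    fraction: float = 0.10,
) -> DownStateSeries:
    """Hippocampal rule: a bin is DOWN iff strictly fewer than ``fraction``
    of the neurons fired in it."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    if traj.n_neurons < 10:
        warnings.warn("fewer than 10 neurons: fraction-based DOWN detection is coarse")
    active = (traj.counts >= 1).sum(axis=1)
    is_down = (active / traj.n_neurons) < fraction
    return DownStateSeries(
        is_down=is_down.astype(np.uint8),
        bin_starts=traj.bin_starts,
        bin_width=traj.bin_width,
        rule="hippocampus-fraction",
    )


def intervals_to_series(
    off: IntervalSet,
    traj: PopulationTrajectory,
    min_coverage: float = 0.5,
) -> DownStateSeries:
    """Rasterize OFF intervals onto trajectory bins.

    A bin is marked DOWN iff at least ``min_coverage`` of its width is
    covered by OFF time (default: majority rule).
    """
    bw = traj.bin_width
    cover = np.zeros(traj.n_bins)
    lo = traj.bin_starts
    hi = lo + bw
    for a, b in off.intervals:
        overlap = np.minimum(hi, b) - np.maximum(lo, a)
        cover += np.clip(overlap, 0.0, None)
    is_down = cover >= min_coverage * bw
    return DownStateSeries(
        is_down=is_down.astype(np.uint8),
        bin_starts=traj.bin_starts,
        bin_width=bw,
        rule="neocortex-off",
    )


def series_to_intervals(series: DownStateSeries) -> IntervalSet:
    """Contiguous DOWN bins back to time intervals (bin-quantized)."""
    x = np.concatenate(([0], series.is_down, [0])).astype(np.int8)
    d = np.diff(x)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    out = [
        (series.bin_starts[s], series.bin_starts[e - 1] + series.bin_width)
        for s, e in zip(starts, ends)
    ]
    return IntervalSet(out, label="DOWN")


def correlate_down_recurrence(
    down: DownStateSeries,
    profile: np.ndarray,
) -> tuple[float, float]:
    """Point-biserial correlation between the binary DOWN series and the
    per-bin recurrence count profile.

    Returns (r, p).  Undefined (raises) when the DOWN series has a single
    class or the profile is constant.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != down.is_down.shape:
        raise ValueError("series lengths differ")
    x = down.is_down.astype(float)
    if x.min() == x.max():
        raise ValueError("DOWN series has a single class: correlation undefined")
    if profile.min() == profile.max():
        raise ValueError("constant recurrence profile: correlation undefined")
    r, p = stats.pointbiserialr(x, profile)
    return float(r), float(p)


def exclude_down_bins(
    traj: PopulationTrajectory,
    down: DownStateSeries,
) -> PopulationTrajectory:
    """UP-only trajectory: remove DOWN bins and concatenate the remainder.

    The result is time-compressed; windows computed on it may span removed
    time.
    """
    if down.n_bins != traj.n_bins:
        raise ValueError("DOWN series not aligned with trajectory")
    keep = down.is_down == 0
    if not keep.any():
        raise ValueError("all bins are DOWN: nothing left to analyse")
    return restrict_trajectory(traj, keep)


def interval_jaccard(a: IntervalSet, b: IntervalSet, resolution: float = 0.001) -> float:
    """Time-based Jaccard overlap between two interval sets.

    Rasterizes both sets on a common grid at ``resolution`` seconds and
    returns |intersection| / |union| of the covered time.
    """
    if len(a) == 0 and len(b) == 0:
        return 1.0
    if len(a) == 0 or len(b) == 0:
        return 0.0
    lo = min(a.intervals[0][0], b.intervals[0][0])
    hi = max(a.intervals[-1][1], b.intervals[-1][1])
    n = int(np.ceil((hi - lo) / resolution))
    grid = lo + resolution * (np.arange(n) + 0.5)

    def mask(ivs):
        m = np.zeros(n, dtype=bool)
        for s, e in ivs.intervals:
            m |= (grid >= s) & (grid < e)
        return m

    ma, mb = mask(a), mask(b)
    union = np.count_nonzero(ma | mb)
    return float(np.count_nonzero(ma & mb) / union) if union else 1.0


def interval_precision_recall(
    detected: IntervalSet,
    truth: IntervalSet,
    resolution: float = 0.001,
) -> tuple[float, float]:
    """Time-based precision and recall of detected vs planted intervals."""
    lo = min(i[0] for s in (detected, truth) if len(s) for i in s.intervals[:1])
    hi = max(i[1] for s in (detected, truth) if len(s) for i in s.intervals[-1:])
    n = int(np.ceil((hi - lo) / resolution))
    grid = lo + resolution * (np.arange(n) + 0.5)

    def mask(ivs):
        m = np.zeros(n, dtype=bool)
        for s, e in ivs.intervals:
            m |= (grid >= s) & (grid < e)
        return m

    md, mt = mask(detected), mask(truth)
    inter = np.count_nonzero(md & mt)
    precision = inter / max(np.count_nonzero(md), 1)
    recall = inter / max(np.count_nonzero(mt), 1)
    return float(precision), float(recall)
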