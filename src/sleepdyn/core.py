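"""Canonical data containers and plumbing for spike-train sessions.

Spike trains are kept in seconds as per-neuron sorted float arrays.  All
binning uses half-open bins ``[start, start + width)``; a trailing partial
bin is dropped so every retained bin covers exactly ``bin_width`` seconds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

STATES = ("Wake", "SWS", "REM")
INTERVAL_LABELS = ("OFF", "DOWN", "UP", "ON")


class SpikeTableError(ValueError):
    """Raised when a spike/hypnogram table cannot be parsed."""


@dataclass
class SpikeTrainSet:
    """Spike times for a simultaneously recorded neuronal population.

    Parameters
    ----------
    neuron_ids : list of str
        Unique neuron identifiers.
    spike_times : dict mapping id -> float array
        Strictly sorted spike times in seconds, within ``[t_start, t_end]``.
    region : str
        Anatomical label, e.g. ``"neocortex"`` or ``"hippocampus"``.
    excitatory : dict mapping id -> bool
        Putative excitatory flag per neuron (used by the synthetic LFP).
    t_start, t_end : float
        Recording bounds in seconds.
    """

    neuron_ids: list
    spike_times: dict
    region: str = "neocortex"
    excitatory: dict = field(default_factory=dict)
    t_start: float = 0.0
    t_end: float = 0.0

    def __post_init__(self):
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise ValueError("neuron_ids must be unique")
        for nid in self.neuron_ids:
            t = np.asarray(self.spike_times.get(nid, ()), dtype=float)
            if t.size and np.any(np.diff(t) <= 0):
                raise ValueError(f"spike times of {nid!r} not strictly sorted")
            self.spike_times[nid] = t
            self.excitatory.setdefault(nid, True)
        times = self.merged()
        if times.size:
            if self.t_end <= self.t_start:
                self.t_start = float(min(self.t_start, times[0]))
                self.t_end = float(times[-1])
            if times[0] < self.t_start or times[-1] > self.t_end:
                raise ValueError("spike times outside [t_start, t_end]")

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(self.spike_times[n]) for n in self.neuron_ids))

    def merged(self) -> np.ndarray:
        """All spike times pooled across the population, sorted."""
        if not self.neuron_ids:
            return np.empty(0)
        return np.sort(np.concatenate([self.spike_times[n] for n in self.neuron_ids]))

    def subset(self, neuron_ids: Sequence) -> "SpikeTrainSet":
        ids = list(neuron_ids)
        return SpikeTrainSet(
            neuron_ids=ids,
            spike_times={n: self.spike_times[n].copy() for n in ids},
            region=self.region,
            excitatory={n: self.excitatory[n] for n in ids},
            t_start=self.t_start,
            t_end=self.t_end,
        )


@dataclass
class Hypnogram:
    """Sleep-wake state schedule: sorted, non-overlapping (start, end, state)."""

    intervals: list

    def __post_init__(self):
        iv = sorted((float(a), float(b), s) for a, b, s in self.intervals)
        for (a, b, s) in iv:
            if b <= a:
                raise ValueError(f"hypnogram interval with end <= start: {(a, b, s)}")
        for (_, b0, _), (a1, _, _) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValueError("hypnogram intervals overlap")
        self.intervals = iv

    def epochs(self, state: str) -> list:
        return [(a, b) for a, b, s in self.intervals if s == state]

    def states(self) -> set:
        return {s for _, _, s in self.intervals}

    def total_duration(self, state: str) -> float:
        return float(sum(b - a for a, b in self.epochs(state)))


@dataclass
class IntervalSet:
    """Labelled time intervals (OFF/DOWN/UP/ON) on the session clock."""

    intervals: list
    label: str = "OFF"

    def __post_init__(self):
        iv = sorted((float(a), float(b)) for a, b in self.intervals)
        for a, b in iv:
            if b <= a:
                raise ValueError(f"interval with end <= start: {(a, b)}")
        for (_, b0), (a1, _) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValueError("intervals overlap")
        self.intervals = iv

    def __len__(self):
        return len(self.intervals)

    def total_duration(self) -> float:
        return float(sum(b - a for a, b in self.intervals))

    def contains(self, t: float) -> bool:
        """Membership with half-open [start, end) intervals."""
        return any(a <= t < b for a, b in self.intervals)


@dataclass
class PopulationTrajectory:
    """Binned firing counts: the N-dimensional phase-space trajectory.

    ``counts`` is T x N; row i holds the spike counts of every neuron in the
    half-open bin ``[bin_starts[i], bin_starts[i] + bin_width)``.
    """

    counts: np.ndarray
    bin_width: float
    bin_starts: np.ndarray
    neuron_ids: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.bin_starts = np.asarray(self.bin_starts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be T x N")
        if np.any(self.counts < 0):
            raise ValueError("negative firing counts")
        if self.counts.shape[0] != self.bin_starts.shape[0]:
            raise ValueError("bin_starts length must match T")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]

    def summed(self) -> np.ndarray:
        """Population activity: counts summed across neurons per bin."""
        return self.counts.sum(axis=1)


# ---------------------------------------------------------------------------
# File I/O (TSV dialects: one spike per row; BED-like interval tables)
# ---------------------------------------------------------------------------

def load_spikes(path, t_start: float | None = None, t_end: float | None = None) -> SpikeTrainSet:
    """Read a spike table (TSV with header ``neuron_id\\ttime_s``).

    A JSON sidecar ``<path>.meta.json`` may carry ``region``, ``excitatory``
    (id -> bool), ``t_start`` and ``t_end``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"neuron_id": str, "time_s": float})
    except (ValueError, pd.errors.ParserError) as exc:
        raise SpikeTableError(f"{path}: malformed spike table: {exc}") from exc
    if list(df.columns) != ["neuron_id", "time_s"]:
        raise SpikeTableError(
            f"{path}: expected header 'neuron_id\\ttime_s', got {list(df.columns)}"
        )
    if df["time_s"].isna().any() or df["neuron_id"].isna().any():
        line = int(df.isna().any(axis=1).idxmax()) + 2  # 1-based + header
        raise SpikeTableError(f"{path}: malformed row at line {line}")
    if (df["time_s"] < 0).any():
        line = int((df["time_s"] < 0).idxmax()) + 2
        raise SpikeTableError(f"{path}: negative spike time at line {line}")

    meta = {}
    meta_path = path.with_name(path.name + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    if t_start is None:
        t_start = meta.get("t_start")
    if t_end is None:
        t_end = meta.get("t_end")

    ids = sorted(df["neuron_id"].unique())
    times = {n: np.sort(df.loc[df["neuron_id"] == n, "time_s"].to_numpy()) for n in ids}
    for n, t in times.items():
        times[n] = np.unique(t)  # drop exact duplicates defensively
    all_t = np.concatenate(list(times.values())) if ids else np.empty(0)
    lo = float(all_t.min()) if all_t.size else 0.0
    hi = float(all_t.max()) if all_t.size else 0.0
    exc = meta.get("excitatory", {})
    return SpikeTrainSet(
        neuron_ids=ids,
        spike_times=times,
        region=meta.get("region", "neocortex"),
        excitatory={n: bool(exc.get(n, True)) for n in ids},
        t_start=lo if t_start is None else float(t_start),
        t_end=hi if t_end is None else float(t_end),
    )


def save_spikes(spikes: SpikeTrainSet, path) -> None:
    path = Path(path)
    rows = []
    for n in spikes.neuron_ids:
        for t in spikes.spike_times[n]:
            rows.append((n, t))
    rows.sort(key=lambda r: (r[1], r[0]))
    with open(path, "w") as fh:
        fh.write("neuron_id\ttime_s\n")
        for n, t in rows:
            fh.write(f"{n}\t{t:.9f}\n")
    meta = {
        "region": spikes.region,
        "excitatory": {n: bool(spikes.excitatory[n]) for n in spikes.neuron_ids},
        "t_start": spikes.t_start,
        "t_end": spikes.t_end,
    }
    path.with_name(path.name + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_hypnogram(path) -> Hypnogram:
    df = pd.read_csv(path, sep="\t", dtype={"state": str})
    if list(df.columns) != ["start_s", "end_s", "state"]:
        raise SpikeTableError(f"{path}: expected header 'start_s\\tend_s\\tstate'")
    return Hypnogram([(r.start_s, r.end_s, r.state) for r in df.itertuples()])


def save_hypnogram(hyp: Hypnogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("start_s\tend_s\tstate\n")
        for a, b, s in hyp.intervals:
            fh.write(f"{a:.9f}\t{b:.9f}\t{s}\n")


def load_intervals(path) -> IntervalSet:
    df = pd.read_csv(path, sep="\t")
    label = str(df["label"].iloc[0]) if len(df) else "OFF"
    return IntervalSet([(r.start_s, r.end_s) for r in df.itertuples()], label=label)


def save_intervals(ivs: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("start_s\tend_s\tlabel\n")
        for a, b in ivs.intervals:
            fh.write(f"{a:.9f}\t{b:.9f}\t{ivs.label}\n")


# ---------------------------------------------------------------------------
# State restriction and binning
# ---------------------------------------------------------------------------

def restrict_to_state(spikes: SpikeTrainSet, hyp: Hypnogram, state: str) -> SpikeTrainSet:
    """Keep only spikes inside the hypnogram's ``state`` epochs (half-open)."""
    epochs = hyp.epochs(state)
    if not epochs:
        warnings.warn(f"state {state!r} absent from hypnogram; returning empty set")
    starts = np.array([a for a, _ in epochs])
    ends = np.array([b for _, b in epochs])
    out = {}
    for n in spikes.neuron_ids:
        t = spikes.spike_times[n]
        if not epochs or t.size == 0:
            out[n] = np.empty(0)
            continue
        idx = np.searchsorted(starts, t, side="right") - 1
        keep = (idx >= 0) & (t < ends[np.clip(idx, 0, len(ends) - 1)])
        out[n] = t[keep]
    return SpikeTrainSet(
        neuron_ids=list(spikes.neuron_ids),
        spike_times=out,
        region=spikes.region,
        excitatory=dict(spikes.excitatory),
        t_start=spikes.t_start,
        t_end=spikes.t_end,
    )


def bin_population(
    spikes: SpikeTrainSet,
    bin_width: float = 0.05,
    window: tuple | None = None,
) -> PopulationTrajectory:
    """Bin every neuron's spikes into non-overlapping count windows.

    ``counts[i, k]`` is the number of spikes of neuron k in
    ``[start + i*bin_width, start + (i+1)*bin_width)``; a trailing partial
    bin is discarded.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    start, end = window if window is not None else (spikes.t_start, spikes.t_end)
    n_bins = int(np.floor((end - start) / bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    edges = start + bin_width * np.arange(n_bins + 1)
    counts = np.zeros((n_bins, spikes.n_neurons), dtype=np.int64)
    for k, n in enumerate(spikes.neuron_ids):
        t = spikes.spike_times[n]
        t = t[(t >= start) & (t < edges[-1])]
        if t.size:
            counts[:, k] = np.histogram(t, bins=edges)[0]
    return PopulationTrajectory(
        counts=counts,
        bin_width=float(bin_width),
        bin_starts=edges[:-1],
        neuron_ids=list(spikes.neuron_ids),
    )


def state_bin_mask(traj: PopulationTrajectory, hyp: Hypnogram, state: str) -> np.ndarray:
    """Boolean mask of bins assigned to ``state``.

    A bin belongs to a state iff its *start* lies inside one of the state's
    intervals (bins need not align with state boundaries).
    """
    epochs = hyp.epochs(state)
    mask = np.zeros(traj.n_bins, dtype=bool)
    for a, b in epochs:
        mask |= (traj.bin_starts >= a) & (traj.bin_starts < b)
    return mask


def restrict_trajectory(traj: PopulationTrajectory, mask: np.ndarray) -> PopulationTrajectory:
    """Keep the masked bins, concatenated (time-compressed)."""
    mask = np.asarray(mask, dtype=bool)
    return PopulationTrajectory(
        counts=traj.counts[mask],
        bin_width=traj.bin_width,
        bin_starts=traj.bin_starts[mask],
        neuron_ids=list(traj.neuron_ids),
    )
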