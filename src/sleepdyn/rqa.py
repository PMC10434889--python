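"""Recurrence plots and recurrence quantification of population trajectories.

A recurrence plot of a binned population trajectory marks every pair of time
bins whose N-dimensional count vectors lie within a tolerance ``epsilon`` of
each other.  Five scalar metrics summarise its structure:

RR   recurrence rate, the density of recurrent points;
DET  fraction of off-identity recurrent points on diagonal lines >= l_min;
LAM  fraction of recurrent points on vertical lines >= v_min;
TT   trapping time, the mean length of vertical lines >= v_min;
DIV  divergence, 1 / L_max with the identity line excluded.

The identity line (LOI) is excluded from the diagonal statistics (a Theiler
window of 1); vertical structures through the LOI are genuine trapping and
are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import Hypnogram, PopulationTrajectory, SpikeTrainSet, bin_population

_NORMS = {"euclidean": "euclidean", "chebyshev": "chebyshev"}
RQA_KEYS = ("RR", "DET", "LAM", "TT", "DIV")


@dataclass
class RecurrencePlot:
    """Binary symmetric T x T recurrence matrix with its tolerance."""

    R: np.ndarray
    epsilon: float
    norm: str = "euclidean"
    window_id: int | None = None

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=np.uint8)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise ValueError("R must be square")
        if not np.array_equal(self.R, self.R.T):
            raise ValueError("R must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.R.shape[0]


@dataclass
class RQAMetrics:
    rr: float
    det: float
    lam: float
    tt: float
    div: float
    l_max: int
    l_min: int = 2
    v_min: int = 2
    diagonal_hist: dict = field(default_factory=dict)
    vertical_hist: dict = field(default_factory=dict)
    window_id: int | None = None

    def as_dict(self) -> dict:
        return {"RR": self.rr, "DET": self.det, "LAM": self.lam,
                "TT": self.tt, "DIV": self.div}


def wake_epsilon(
    spikes: SpikeTrainSet,
    hyp: Hypnogram,
    bin_width: float = 0.05,
    n_sd: float = 1.0,
) -> float:
    """Recurrence tolerance: ``n_sd`` standard deviations of the summed
    firing counts across all wakefulness bins of the session.

    Each Wake epoch is binned separately (bins never straddle state
    boundaries) and the neuron-summed counts are pooled before taking the
    population (ddof=0) standard deviation.
    """
    epochs = hyp.epochs("Wake")
    if not epochs:
        raise ValueError("hypnogram has no Wake epochs; epsilon undefined")
    summed = []
    for a, b in epochs:
        if b - a < bin_width:
            continue
        traj = bin_population(spikes, bin_width=bin_width, window=(a, b))
        summed.append(traj.summed())
    if not summed:
        raise ValueError("no Wake epoch holds a full bin; epsilon undefined")
    pooled = np.concatenate(summed)
    return float(n_sd * pooled.std(ddof=0))


def summed_count_epsilon(traj: PopulationTrajectory, n_sd: float = 1.0) -> float:
    """Tolerance from a trajectory directly: n_sd * SD of the summed counts.

    Used for model output, where the non-silenced baseline run plays the
    role of wakefulness.
    """
    return float(n_sd * traj.summed().std(ddof=0))


def recurrence_matrix(
    traj: PopulationTrajectory,
    epsilon: float,
    norm: str = "euclidean",
    window_id: int | None = None,
) -> RecurrencePlot:
    """R(i, j) = 1 iff the distance between count vectors i and j <= epsilon.

    The comparison is inclusive, so ``epsilon = 0`` marks exact repeats of a
    firing pattern.
    """
    if traj.n_bins < 2:
        raise ValueError("need at least 2 bins for a recurrence plot")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if norm not in _NORMS:
        raise ValueError(f"unknown norm {norm!r}")
    x = np.asarray(traj.counts, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite firing counts")
    d = squareform(pdist(x, metric=_NORMS[norm]))
    return RecurrencePlot(R=(d <= epsilon).astype(np.uint8),
                          epsilon=float(epsilon), norm=norm, window_id=window_id)


def _run_lengths(x: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of ones in a 1-d 0/1 array."""
    padded = np.concatenate(([0], x.astype(np.int8), [0]))
    d = np.diff(padded)
    return np.flatnonzero(d == -1) - np.flatnonzero(d == 1)


def _diagonal_lines(R: np.ndarray) -> np.ndarray:
    """Run lengths over all off-identity diagonals (both triangles)."""
    T = R.shape[0]
    out = []
    for off in range(1, T):
        runs = _run_lengths(np.diagonal(R, offset=off))
        if runs.size:
            out.append(np.concatenate([runs, runs]))  # symmetric: lower mirror
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def _vertical_lines(R: np.ndarray) -> np.ndarray:
    """Run lengths of ones down every column (identity included)."""
    out = [_run_lengths(R[:, j]) for j in range(R.shape[1])]
    out = [r for r in out if r.size]
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def rqa_metrics(rp: RecurrencePlot, l_min: int = 2, v_min: int = 2) -> RQAMetrics:
    """Compute RR, DET, LAM, TT and DIV from a recurrence plot."""
    if l_min < 2 or v_min < 2:
        raise ValueError("l_min and v_min must be >= 2")
    R = rp.R
    T = R.shape[0]
    if T == 0:
        raise ValueError("empty recurrence matrix")

    rr = float(R.sum()) / (T * T)

    diag = _diagonal_lines(R)
    diag_points = float(diag.sum())
    det_points = float(diag[diag >= l_min].sum())
    det = det_points / diag_points if diag_points > 0 else 0.0
    l_max = int(diag.max()) if diag.size else 1
    l_max = max(l_max, 1)
    div = 1.0 / l_max

    vert = _vertical_lines(R)
    vert_points = float(vert.sum())
    qual = vert[vert >= v_min]
    lam = float(qual.sum()) / vert_points if vert_points > 0 else 0.0
    tt = float(qual.mean()) if qual.size else 0.0

    dhist = dict(zip(*np.unique(diag, return_counts=True))) if diag.size else {}
    vhist = dict(zip(*np.unique(vert, return_counts=True))) if vert.size else {}
    return RQAMetrics(
        rr=rr, det=det, lam=lam, tt=tt, div=div, l_max=l_max,
        l_min=l_min, v_min=v_min,
        diagonal_hist={int(k): int(v) for k, v in dhist.items()},
        vertical_hist={int(k): int(v) for k, v in vhist.items()},
        window_id=rp.window_id,
    )


def recurrence_time_profile(rp: RecurrencePlot) -> np.ndarray:
    """Number of recurrences per time bin: the column sums of R."""
    return rp.R.sum(axis=0).astype(np.int64)


def windowed_rqa(
    traj: PopulationTrajectory,
    epsilon: float,
    window_len: float = 10.0,
    l_min: int = 2,
    v_min: int = 2,
    norm: str = "euclidean",
) -> list[RQAMetrics]:
    """Split the trajectory into non-overlapping windows (default 10 s, so
    T = 200 at 50 ms bins) and compute the metrics per window.  An
    incomplete trailing window is dropped.
    """
    bins_per_window = int(round(window_len / traj.bin_width))
    if bins_per_window < 2:
        raise ValueError("window must span at least 2 bins")
    n_windows = traj.n_bins // bins_per_window
    if n_windows == 0:
        warnings.warn("trajectory shorter than one window; no metrics computed")
        return []
    out = []
    for w in range(n_windows):
        sl = slice(w * bins_per_window, (w + 1) * bins_per_window)
        sub = PopulationTrajectory(
            counts=traj.counts[sl],
            bin_width=traj.bin_width,
            bin_starts=traj.bin_starts[sl],
            neuron_ids=list(traj.neuron_ids),
        )
        rp = recurrence_matrix(sub, epsilon, norm=norm, window_id=w)
        out.append(rqa_metrics(rp, l_min=l_min, v_min=v_min))
    return out


def mean_metrics(metrics: list[RQAMetrics]) -> dict:
    """Average each RQA metric across windows."""
    if not metrics:
        raise ValueError("no metrics to average")
    keys = ["RR", "DET", "LAM", "TT", "DIV"]
    return {k: float(np.mean([m.as_dict()[k] for m in metrics])) for k in keys}
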