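"""Neuronal avalanches: detection, power-law fits and crackling-noise scaling.

The merged population spike train is binned (by default at its mean
inter-spike interval); an avalanche is a maximal run of non-empty bins
delimited by empty bins.  Size is the total spike count, duration the run
length.  Size and duration distributions are fitted with a discrete
maximum-likelihood power law; at criticality the exponents obey the
crackling-noise relation (tau_t - 1)/(tau - 1) = 1/(sigma nu z), where the
right-hand side is the scaling exponent of mean size against duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .core import SpikeTrainSet


@dataclass
class AvalancheCatalog:
    sizes: np.ndarray
    durations_bins: np.ndarray
    bin_width: float
    state: str | None = None

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        self.durations_bins = np.asarray(self.durations_bins, dtype=np.int64)
        if self.sizes.shape != self.durations_bins.shape:
            raise ValueError("sizes and durations must align")
        if self.sizes.size and (self.sizes.min() < 1 or self.durations_bins.min() < 1):
            raise ValueError("avalanche sizes and durations must be >= 1")

    @property
    def n(self) -> int:
        return self.sizes.size

    @property
    def durations_s(self) -> np.ndarray:
        return self.durations_bins * self.bin_width


@dataclass
class PowerLawFit:
    exponent: float
    xmin: int
    n_tail: int
    ks: float
    method: str = "discrete-mle"
    ci: tuple | None = None


@dataclass
class ScalingFit:
    exponent: float  # 1 / (sigma nu z)
    intercept: float
    n_durations: int
    ci: tuple | None = None


def detect_avalanches(
    spikes: SpikeTrainSet,
    bin_width: float | str = "mean-isi",
    state: str | None = None,
) -> AvalancheCatalog:
    """Segment the merged population spike train into avalanches.

    ``bin_width="mean-isi"`` uses the average inter-spike interval of the
    merged train.  Runs of non-empty bins touching the recording edges are
    discarded (they are not delimited by an empty bin on both sides).
    """
    merged = spikes.merged()
    if bin_width == "mean-isi":
        if merged.size < 2:
            raise ValueError("mean ISI undefined with fewer than 2 spikes")
        bw = float(np.diff(merged).mean())
    else:
        bw = float(bin_width)
        if bw <= 0:
            raise ValueError("bin_width must be positive")
    t0, t1 = spikes.t_start, spikes.t_end
    n_bins = int(np.floor((t1 - t0) / bw))
    if n_bins < 1 or merged.size == 0:
        return AvalancheCatalog(np.empty(0), np.empty(0), bw, state)
    edges = t0 + bw * np.arange(n_bins + 1)
    counts = np.histogram(merged[(merged >= t0) & (merged < edges[-1])], bins=edges)[0]

    occupied = np.concatenate(([0], (counts > 0).astype(np.int8), [0]))
    d = np.diff(occupied)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    sizes, durs = [], []
    for s, e in zip(starts, ends):
        if s == 0 or e == n_bins:  # touches the recording edge
            continue
        sizes.append(int(counts[s:e].sum()))
        durs.append(int(e - s))
    return AvalancheCatalog(np.array(sizes), np.array(durs), bw, state)


# ---------------------------------------------------------------------------
# Discrete power-law fitting (maximum likelihood, KS-optimal xmin)
# ---------------------------------------------------------------------------

def _mle_exponent(tail: np.ndarray, xmin: int) -> float:
    """Maximize the discrete power-law likelihood P(x) = x^-a / zeta(a, xmin)."""
    slogx = float(np.log(tail).sum())
    n = tail.size

    def nll(a):
        return a * slogx + n * np.log(special.zeta(a, xmin))

    res = optimize.minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded",
                                   options={"xatol": 1e-6})
    return float(res.x)


def _ks_distance(tail: np.ndarray, a: float, xmin: int) -> float:
    xs = np.unique(tail)
    z = special.zeta(a, xmin)
    model_cdf = 1.0 - special.zeta(a, xs + 1) / z
    emp_cdf = np.searchsorted(np.sort(tail), xs, side="right") / tail.size
    return float(np.max(np.abs(emp_cdf - model_cdf)))


def fit_discrete_power_law(
    values,
    xmin: int | str = "auto",
    min_tail: int = 50,
    max_candidates: int = 60,
) -> PowerLawFit:
    """Discrete maximum-likelihood power-law fit.

    With ``xmin="auto"`` the cutoff is chosen to minimize the
    Kolmogorov-Smirnov distance between the tail data and the fitted
    distribution, scanning the unique data values that leave at least
    ``min_tail`` tail observations.
    """
    x = np.asarray(values, dtype=np.int64)
    if x.size and x.min() < 1:
        raise ValueError("values must be positive integers")
    if np.unique(x).size < 2:
        raise ValueError("degenerate input: all values equal")
    if xmin == "auto":
        uniq = np.unique(x)
        cands = [int(u) for u in uniq if np.count_nonzero(x >= u) >= min_tail]
        if not cands:
            raise ValueError(f"fewer than {min_tail} tail observations")
        if len(cands) > max_candidates:
            idx = np.unique(np.linspace(0, len(cands) - 1, max_candidates).astype(int))
            cands = [cands[i] for i in idx]
        best = None
        for xm in cands:
            tail = x[x >= xm]
            a = _mle_exponent(tail, xm)
            ks = _ks_distance(tail, a, xm)
            if best is None or ks < best[0]:
                best = (ks, a, xm, tail.size)
        ks, a, xm, n_tail = best
    else:
        xm = int(xmin)
        tail = x[x >= xm]
        if tail.size < min_tail:
            raise ValueError(f"fewer than {min_tail} tail observations")
        a = _mle_exponent(tail, xm)
        ks = _ks_distance(tail, a, xm)
        n_tail = tail.size
    return PowerLawFit(exponent=a, xmin=xm, n_tail=n_tail, ks=ks)


def bootstrap_exponent_ci(
    values,
    xmin: int,
    n_boot: int = 500,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the tail exponent at a fixed xmin."""
    x = np.asarray(values, dtype=np.int64)
    tail = x[x >= xmin]
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _mle_exponent(rng.choice(tail, size=tail.size, replace=True), xmin)
    alpha = (1.0 - level) / 2
    return (float(np.quantile(boots, alpha)), float(np.quantile(boots, 1 - alpha)))


def size_duration_scaling(
    cat: AvalancheCatalog,
    n_boot: int = 0,
    level: float = 0.95,
    seed: int | None = None,
) -> ScalingFit:
    """OLS slope of log10(mean size) against log10(duration): 1/(sigma nu z)."""

    def slope_of(sizes, durs):
        uniq = np.unique(durs)
        if uniq.size < 3:
            return None
        means = np.array([sizes[durs == d].mean() for d in uniq])
        coef = np.polyfit(np.log10(uniq.astype(float)), np.log10(means), 1)
        return coef

    coef = slope_of(cat.sizes, cat.durations_bins)
    if coef is None:
        raise ValueError("need at least 3 distinct avalanche durations")
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, cat.n, size=cat.n)
            c = slope_of(cat.sizes[idx], cat.durations_bins[idx])
            if c is not None:
                boots.append(c[0])
        alpha = (1.0 - level) / 2
        ci = (float(np.quantile(boots, alpha)), float(np.quantile(boots, 1 - alpha)))
    return ScalingFit(exponent=float(coef[0]), intercept=float(coef[1]),
                      n_durations=int(np.unique(cat.durations_bins).size), ci=ci)


def crackling_ratio(size_fit: PowerLawFit, dur_fit: PowerLawFit) -> float:
    """(tau_t - 1) / (tau - 1), the crackling-noise prediction for 1/(sigma nu z)."""
    tau = size_fit.exponent
    tau_t = dur_fit.exponent
    if tau <= 1.0:
        raise ValueError("size exponent <= 1: ratio degenerate")
    return float((tau_t - 1.0) / (tau - 1.0))
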