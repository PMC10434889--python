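"""Ground-truth-labelled synthetic sessions emulating the study recordings.

A session carries ~50 simultaneously recorded neurons with lognormal firing
rates (median 2 Hz).  Wake and REM epochs are asynchronous-irregular
(independent Poisson) firing; SWS epochs alternate UP periods (Poisson at
elevated rates) with DOWN periods drawn uniformly from 50-1250 ms, UP
durations from 200-4000 ms.  During DOWN, firing is zero (neocortex-like)
or restricted to a small fraction of neurons at reduced rate
(hippocampus-like).  UP rates are rescaled so the SWS state-mean rate
matches Wake, making state differences structural rather than rate
artifacts.  The exact DOWN intervals are returned as ground truth for
detector validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .core import Hypnogram, IntervalSet, SpikeTrainSet


def default_schedule(wake: float = 300.0, sws: float = 300.0, rem: float = 300.0) -> Hypnogram:
    """One epoch per state: Wake, then SWS, then REM."""
    return Hypnogram([
        (0.0, wake, "Wake"),
        (wake, wake + sws, "SWS"),
        (wake + sws, wake + sws + rem, "REM"),
    ])


@dataclass
class SessionSpec:
    """Parameters of a synthetic recording session.

    down_firing_fraction : fraction of neurons that keep firing during DOWN
        periods (0 for neocortex-like near-total silence, 0.1 for
        hippocampus-like residual firing).
    """

    n_neurons: int = 50
    rate_median: float = 2.0     # Hz, median of the lognormal rate distribution
    rate_sigma: float = 1.0      # lognormal shape parameter (log-dynamic brain)
    schedule: Hypnogram | None = None
    down_dur_range: tuple = (0.050, 1.250)
    up_dur_range: tuple = (0.200, 4.000)
    down_firing_fraction: float = 0.0
    down_rate_scale: float = 0.1  # DOWN-active neurons fire at this x their rate
    inhibitory_fraction: float = 0.2   # fast-spiking interneuron-like units
    inhibitory_rate_scale: float = 4.0  # their rate multiplier
    duration_dist: str = "uniform"  # or "lognormal"
    up_rate_mode: str = "wake-matched"  # or "state-mean-matched"
    region: str = "neocortex"
    seed: int = 0

    def __post_init__(self):
        if self.rate_median <= 0:
            raise ValueError("rates must be positive")
        if not (0.0 <= self.down_firing_fraction < 1.0):
            raise ValueError("down_firing_fraction must be in [0, 1)")
        if self.schedule is None:
            self.schedule = default_schedule()


def _draw_duration(rng: np.random.Generator, rng_bounds: tuple, dist: str) -> float:
    lo, hi = rng_bounds
    if dist == "uniform":
        return float(rng.uniform(lo, hi))
    # lognormal truncated to the stated bounds
    mu = np.log(np.sqrt(lo * hi))
    sigma = np.log(hi / lo) / 4.0
    while True:
        d = float(rng.lognormal(mu, sigma))
        if lo <= d <= hi:
            return d


def _poisson_times(rng: np.random.Generator, rate: float, a: float, b: float) -> np.ndarray:
    if rate <= 0 or b <= a:
        return np.empty(0)
    n = rng.poisson(rate * (b - a))
    return np.sort(rng.uniform(a, b, size=n))


def _segment_sws(rng, epochs, spec: SessionSpec):
    """Alternate UP/DOWN segments inside each SWS epoch, starting with UP."""
    ups, downs = [], []
    for a, b in epochs:
        t = a
        is_up = True
        while t < b:
            bounds = spec.up_dur_range if is_up else spec.down_dur_range
            d = _draw_duration(rng, bounds, spec.duration_dist)
            end = min(t + d, b)
            if end > t:
                (ups if is_up else downs).append((t, end))
            t = end
            is_up = not is_up
    return ups, downs


def gen_session(spec: SessionSpec):
    """Generate a session: (SpikeTrainSet, Hypnogram, ground-truth DOWN IntervalSet).

    Identical spec + seed gives byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    hyp = spec.schedule
    if "SWS" not in hyp.states():
        import warnings

        warnings.warn("schedule contains no SWS: DOWN parameters unused")
    n = spec.n_neurons
    rates = spec.rate_median * np.exp(rng.normal(0.0, spec.rate_sigma, size=n))
    # a fast-spiking, putatively inhibitory subset, as in the recorded
    # populations; these units silence during DOWN like the rest but are
    # excluded from the synthetic LFP
    n_inh = int(round(spec.inhibitory_fraction * n))
    is_inh = np.zeros(n, dtype=bool)
    if n_inh:
        is_inh[rng.choice(n, size=n_inh, replace=False)] = True
        rates[is_inh] *= spec.inhibitory_rate_scale

    ups, downs = _segment_sws(rng, hyp.epochs("SWS"), spec)
    if spec.up_rate_mode == "wake-matched":
        # UP-state firing matches wakefulness, as in vivo; the SWS state
        # mean rate is then lower by the UP occupancy fraction
        up_factor = 1.0
    else:  # state-mean-matched
        total_sws = hyp.total_duration("SWS")
        total_up = sum(b - a for a, b in ups)
        up_factor = (total_sws / total_up) if total_up > 0 else 1.0

    n_down_active = int(round(spec.down_firing_fraction * n))
    down_active = rng.choice(n, size=n_down_active, replace=False) if n_down_active else np.empty(0, dtype=int)

    ids = [f"n{k:03d}" for k in range(n)]
    times: dict = {nid: [] for nid in ids}
    for a, b, state in hyp.intervals:
        if state in ("Wake", "REM"):
            for k, nid in enumerate(ids):
                times[nid].append(_poisson_times(rng, rates[k], a, b))
    for a, b in ups:
        for k, nid in enumerate(ids):
            times[nid].append(_poisson_times(rng, rates[k] * up_factor, a, b))
    for a, b in downs:
        for k in down_active:
            times[ids[k]].append(
                _poisson_times(rng, rates[k] * spec.down_rate_scale, a, b)
            )

    spike_times = {}
    for nid in ids:
        t = np.sort(np.concatenate(times[nid])) if times[nid] else np.empty(0)
        spike_times[nid] = np.unique(t)
    t_end = hyp.intervals[-1][1]
    spikes = SpikeTrainSet(
        neuron_ids=ids,
        spike_times=spike_times,
        region=spec.region,
        excitatory={nid: bool(~is_inh[k]) for k, nid in enumerate(ids)},
        t_start=hyp.intervals[0][0],
        t_end=t_end,
    )
    truth = IntervalSet(downs, label="DOWN") if downs else IntervalSet([], label="DOWN")
    return spikes, hyp, truth


def gen_cohort(n_sessions: int, base_spec: SessionSpec, seed: int = 0):
    """Independent sessions sharing parameters but not seeds."""
    out = []
    for s in range(n_sessions):
        spec = SessionSpec(
            n_neurons=base_spec.n_neurons,
            rate_median=base_spec.rate_median,
            rate_sigma=base_spec.rate_sigma,
            schedule=base_spec.schedule,
            down_dur_range=base_spec.down_dur_range,
            up_dur_range=base_spec.up_dur_range,
            down_firing_fraction=base_spec.down_firing_fraction,
            down_rate_scale=base_spec.down_rate_scale,
            duration_dist=base_spec.duration_dist,
            up_rate_mode=base_spec.up_rate_mode,
            inhibitory_fraction=base_spec.inhibitory_fraction,
            inhibitory_rate_scale=base_spec.inhibitory_rate_scale,
            region=base_spec.region,
            seed=seed + 1000 * (s + 1),
        )
        out.append(gen_session(spec))
    return out


def sample_discrete_power_law(
    exponent: float,
    xmin: int,
    n: int,
    seed: int | None = None,
) -> np.ndarray:
    """Draw n iid values from P(x) proportional to x^-exponent, x >= xmin.

    Exact inverse-CDF sampling: the bulk via a precomputed CDF table, the
    far tail by bisection on the Hurwitz-zeta CCDF.
    """
    if exponent <= 1.0:
        raise ValueError("exponent must exceed 1 (distribution not normalizable)")
    if n < 1:
        raise ValueError("n must be >= 1")
    xmin = int(xmin)
    rng = np.random.default_rng(seed)
    z = special.zeta(exponent, xmin)
    cutoff = 100_000
    ks = np.arange(xmin, cutoff + 1)
    pmf = ks.astype(float) ** (-exponent) / z
    cdf = np.cumsum(pmf)
    u = rng.random(n)
    out = np.empty(n, dtype=np.int64)
    bulk = u < cdf[-1]
    out[bulk] = ks[np.searchsorted(cdf, u[bulk], side="left")]
    for i in np.flatnonzero(~bulk):
        # smallest x with CDF(x) >= u  <=>  zeta(a, x+1) <= (1-u) z
        target = (1.0 - u[i]) * z
        lo = cutoff
        hi = cutoff * 2
        while special.zeta(exponent, hi + 1) > target:
            lo, hi = hi, hi * 2
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if special.zeta(exponent, mid + 1) <= target:
                hi = mid
            else:
                lo = mid
        out[i] = hi
    return out
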