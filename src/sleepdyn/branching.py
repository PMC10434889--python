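"""Critical branching network with optional periodic noise silencing.

Fifty units on an Erdos-Renyi graph (link probability 0.03) evolve in 1 ms
steps through resting -> firing -> refractory (one step) -> resting.  A
resting unit fires when (a) a neighbour that fired in the previous step
excites it, each attempt succeeding independently with probability
P_prop = sigma / <k> (<k> the realized mean degree), or (b) its intrinsic
Poisson drive spikes, which happens with probability 1 - exp(-lambda) per
step.  sigma = 1 is the critical point separating quiescent (sigma < 1)
from self-sustained (sigma > 1) phases.

An SWS-like state is produced by periodically suppressing the *noise
drive* (propagation is untouched) of a fixed random subset of units for
``silence_duration`` out of every ``silence_period`` seconds, emulating
DOWN states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import PopulationTrajectory, SpikeTrainSet, bin_population
from .rqa import RQA_KEYS, mean_metrics, summed_count_epsilon, windowed_rqa


@dataclass
class BranchingConfig:
    n_units: int = 50
    attach_p: float = 0.03
    sigma: float = 1.0
    lambda_noise: float = 0.014  # per 1 ms step
    dt: float = 0.001
    n_steps: int = 1_000_000
    silenced_fraction: float = 0.0
    silence_duration: float = 0.250
    silence_period: float = 0.500
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0 or self.lambda_noise < 0:
            raise ValueError("sigma and lambda_noise must be >= 0")
        if not (0.0 <= self.silenced_fraction <= 1.0):
            raise ValueError("silenced_fraction must lie in [0, 1]")
        if self.silence_duration > self.silence_period:
            raise ValueError("silence_duration cannot exceed silence_period")


@dataclass
class NetworkTopology:
    adjacency: np.ndarray
    mean_degree: float

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if not np.array_equal(A, A.T) or np.any(np.diag(A)):
            raise ValueError("adjacency must be symmetric with no self-links")
        self.adjacency = A.astype(np.int8)


def build_network(n_units: int, attach_p: float, seed: int = 0) -> NetworkTopology:
    """Undirected Erdos-Renyi graph: each pair linked with ``attach_p``."""
    if n_units < 2:
        raise ValueError("need at least 2 units")
    if not (0.0 <= attach_p <= 1.0):
        raise ValueError("attach_p must lie in [0, 1]")
    g = nx.gnp_random_graph(n_units, attach_p, seed=seed)
    A = nx.to_numpy_array(g, dtype=np.int8)
    k = float(A.sum(axis=1).mean())
    if k == 0:
        warnings.warn("zero-edge network: spike propagation impossible")
    return NetworkTopology(adjacency=A, mean_degree=k)


def _silence_mask(cfg: BranchingConfig, steps: np.ndarray) -> np.ndarray:
    """True at steps where the silencing window is active."""
    phase = (steps * cfg.dt) % cfg.silence_period
    return phase < cfg.silence_duration


def simulate(
    cfg: BranchingConfig,
    topo: NetworkTopology | None = None,
    initial_active: np.ndarray | None = None,
    stop_when_silent: bool = False,
) -> SpikeTrainSet:
    """Run the branching dynamics and return the raster as a SpikeTrainSet.

    ``initial_active`` seeds spikes at step 0 (used to probe the phase
    transition with the noise turned off).  With ``stop_when_silent`` and
    lambda = 0 the run ends as soon as activity dies (it can never
    restart).
    """
    if topo is None:
        topo = build_network(cfg.n_units, cfg.attach_p, seed=cfg.seed)
    n = cfg.n_units
    A = topo.adjacency
    rng = np.random.default_rng(cfg.seed)

    k_mean = topo.mean_degree
    if k_mean > 0:
        p_prop = cfg.sigma / k_mean
        if p_prop > 1.0:
            warnings.warn("sigma exceeds mean degree; clamping P_prop to 1")
            p_prop = 1.0
    else:
        p_prop = 0.0
    # P(at least one of m neighbour attempts succeeds)
    p_any = 1.0 - (1.0 - p_prop) ** np.arange(n + 1)
    p_noise = 1.0 - np.exp(-cfg.lambda_noise)

    n_silenced = int(round(cfg.silenced_fraction * n))
    silenced = rng.choice(n, size=n_silenced, replace=False) if n_silenced else None

    fired_prev = np.zeros(n, dtype=bool)
    if initial_active is not None:
        fired_prev[np.asarray(initial_active, dtype=int)] = True
    spike_steps: list = []
    spike_units: list = []
    if initial_active is not None:
        idx = np.flatnonzero(fired_prev)
        spike_steps.append(np.zeros(idx.size, dtype=np.int64))
        spike_units.append(idx)

    chunk = 100_000
    t = 1
    while t < cfg.n_steps:
        m_steps = min(chunk, cfg.n_steps - t)
        steps = np.arange(t, t + m_steps)
        noise = rng.random((m_steps, n)) < p_noise
        if silenced is not None and silenced.size:
            sil = _silence_mask(cfg, steps)
            noise[np.ix_(sil, silenced)] = False
        fires_chunk = np.zeros((m_steps, n), dtype=bool)
        dead = False
        for j in range(m_steps):
            if fired_prev.any():
                m = A @ fired_prev
                fires = ~fired_prev & (noise[j] | (rng.random(n) < p_any[m]))
            else:
                fires = noise[j]
            fires_chunk[j] = fires
            fired_prev = fires
            if stop_when_silent and cfg.lambda_noise == 0 and not fires.any():
                dead = True
                break
        rows, cols = np.nonzero(fires_chunk)
        if rows.size:
            spike_steps.append(rows + t)
            spike_units.append(cols)
        t += m_steps
        if dead:
            break

    ids = [f"u{k:03d}" for k in range(n)]
    if spike_steps:
        all_steps = np.concatenate(spike_steps)
        all_units = np.concatenate(spike_units)
    else:
        all_steps = np.empty(0, dtype=np.int64)
        all_units = np.empty(0, dtype=np.int64)
    times = {}
    for k in range(n):
        times[ids[k]] = np.sort(all_steps[all_units == k]) * cfg.dt
    return SpikeTrainSet(
        neuron_ids=ids,
        spike_times=times,
        region="model",
        excitatory={i: True for i in ids},
        t_start=0.0,
        t_end=cfg.n_steps * cfg.dt,
    )


def seeded_cascades(
    sigma: float,
    n_trials: int = 2000,
    cap: int = 5000,
    n_units: int = 50,
    attach_p: float = 0.03,
    seed: int = 0,
    trials_per_topology: int = 100,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Avalanche sizes and durations of single-seed cascades (no noise).

    This realizes the small-noise limit where avalanches are isolated: one
    spike is planted in a random connected unit and the cascade runs until
    it dies.  Cascades still alive after ``cap`` steps are censored and
    discarded (their count is returned).  Fresh topologies are drawn every
    ``trials_per_topology`` trials.
    """
    rng = np.random.default_rng(seed)
    sizes, durs = [], []
    censored = 0
    done = 0
    while done < n_trials:
        b = min(trials_per_topology, n_trials - done)
        topo = build_network(n_units, attach_p, seed=int(rng.integers(2**31)))
        A = topo.adjacency.astype(np.float64)
        if topo.mean_degree == 0:
            done += b
            continue
        p_prop = min(sigma / topo.mean_degree, 1.0)
        p_any = 1.0 - (1.0 - p_prop) ** np.arange(n_units + 1)
        cand = np.flatnonzero(topo.adjacency.sum(axis=1) > 0)
        fired = np.zeros((b, n_units), dtype=bool)
        fired[np.arange(b), rng.choice(cand, size=b)] = True
        size = np.ones(b, dtype=np.int64)
        dur = np.ones(b, dtype=np.int64)
        alive = np.ones(b, dtype=bool)
        for _ in range(cap):
            m = (fired @ A).astype(np.int64)
            fired = ~fired & (rng.random((b, n_units)) < p_any[m])
            s = fired.sum(axis=1)
            active = s > 0
            size += s
            dur += active
            alive &= True
            if not active.any():
                alive[:] = False
                break
            fired[~active] = False
            alive = active
        finished = ~alive
        sizes.extend(size[finished].tolist())
        durs.extend(dur[finished].tolist())
        censored += int(alive.sum())
        done += b
    return np.asarray(sizes, dtype=np.int64), np.asarray(durs, dtype=np.int64), censored


def last_spike_step(spikes: SpikeTrainSet, dt: float = 0.001) -> int:
    """Step index of the last spike in a run (-1 for a silent raster)."""
    merged = spikes.merged()
    if merged.size == 0:
        return -1
    return int(round(merged[-1] / dt))


def model_trajectory(spikes: SpikeTrainSet, bin_width: float = 0.05) -> PopulationTrajectory:
    return bin_population(spikes, bin_width=bin_width)


def model_rqa(
    cfg: BranchingConfig,
    n_realizations: int = 10,
    bin_width: float = 0.05,
    window_len: float = 10.0,
    l_min: int = 2,
    v_min: int = 2,
    epsilon_sd: float = 1.0,
) -> dict:
    """Mean windowed RQA of the model across seeded realizations.

    Each realization draws a fresh topology and noise stream; epsilon is
    one SD of that run's summed 50 ms counts (the model analogue of the
    wakefulness-derived tolerance).
    """
    per_real = []
    for r in range(n_realizations):
        c = BranchingConfig(**{**cfg.__dict__, "seed": cfg.seed + 7919 * r})
        spikes = simulate(c)
        traj = model_trajectory(spikes, bin_width=bin_width)
        eps = summed_count_epsilon(traj, n_sd=epsilon_sd)
        ms = windowed_rqa(traj, eps, window_len=window_len, l_min=l_min, v_min=v_min)
        per_real.append(mean_metrics(ms))
    return {k: float(np.mean([m[k] for m in per_real])) for k in RQA_KEYS}


def delta_rqa_curve(
    cfg: BranchingConfig,
    fractions,
    n_rep: int = 5,
    bin_width: float = 0.05,
    window_len: float = 10.0,
    reference: dict | None = None,
) -> list[dict]:
    """Difference (silenced - baseline) of each RQA metric per silenced fraction.

    For every repetition the baseline (fraction 0) and silenced runs share
    the same seed, hence the same topology and noise stream; epsilon comes
    from the baseline run.  Returns one record per fraction with mean and
    SD of each Delta metric; if ``reference`` supplies experimental
    differences, the crossing fraction per metric is appended.
    """
    fractions = list(fractions)
    if not fractions:
        raise ValueError("empty fraction list")
    deltas = {f: {k: [] for k in RQA_KEYS} for f in fractions}
    for rep in range(n_rep):
        seed = cfg.seed + 104729 * rep
        base_cfg = BranchingConfig(**{**cfg.__dict__, "silenced_fraction": 0.0, "seed": seed})
        base = simulate(base_cfg)
        base_traj = model_trajectory(base, bin_width=bin_width)
        eps = summed_count_epsilon(base_traj)
        base_m = mean_metrics(windowed_rqa(base_traj, eps, window_len=window_len))
        for f in fractions:
            if f == 0.0:
                sil_m = base_m
            else:
                sil_cfg = BranchingConfig(
                    **{**cfg.__dict__, "silenced_fraction": float(f), "seed": seed}
                )
                sil = simulate(sil_cfg)
                sil_traj = model_trajectory(sil, bin_width=bin_width)
                sil_m = mean_metrics(windowed_rqa(sil_traj, eps, window_len=window_len))
            for k in RQA_KEYS:
                deltas[f][k].append(sil_m[k] - base_m[k])
    out = []
    for f in fractions:
        rec = {"fraction": float(f)}
        for k in RQA_KEYS:
            vals = np.asarray(deltas[f][k])
            rec[f"d{k}"] = float(vals.mean())
            rec[f"d{k}_sd"] = float(vals.std(ddof=0))
        out.append(rec)
    if reference is not None:
        for k in RQA_KEYS:
            if k not in reference:
                continue
            target = reference[k]
            crossing = None
            for r0, r1 in zip(out, out[1:]):
                a, b = r0[f"d{k}"] - target, r1[f"d{k}"] - target
                if a == 0 or a * b < 0:
                    span = r1[f"d{k}"] - r0[f"d{k}"]
                    frac = 0.0 if span == 0 else (target - r0[f"d{k}"]) / span
                    crossing = r0["fraction"] + frac * (r1["fraction"] - r0["fraction"])
                    break
            for rec in out:
                rec[f"crossing_{k}"] = crossing
    return out
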