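"""End-to-end analyses: per-state RQA comparisons, complexity pipelines,
robustness sweeps, and neuron-count dependence.

A "session" is a (SpikeTrainSet, Hypnogram) pair.  State comparisons pool
windowed RQA metrics per session and state, run a Friedman omnibus across
the paired per-session means, and follow up with pairwise signed-rank
tests under Benjamini-Hochberg correction, reporting Cohen's d alongside.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .complexity import signal_complexity
from .core import (
    Hypnogram,
    PopulationTrajectory,
    SpikeTrainSet,
    bin_population,
    restrict_to_state,
    restrict_trajectory,
)
from .down_states import (
    detect_fraction_down,
    detect_off_periods,
    detect_on_periods,
    exclude_down_bins,
    intervals_to_series,
)
from .fields import build_slfp, welch_psd
from .rqa import RQA_KEYS, mean_metrics, wake_epsilon, windowed_rqa
from .stats import friedman_test, paired_posthoc

STATE_ORDER = ("Wake", "SWS", "REM")


def _state_trajectory(
    spikes: SpikeTrainSet,
    hyp: Hypnogram,
    state: str,
    bin_width: float,
    up_only: bool = False,
    down_rule: str | None = None,
) -> PopulationTrajectory:
    """Bin each state epoch separately (bins never straddle states) and
    concatenate.  With ``up_only`` the DOWN bins are removed first."""
    epochs = hyp.epochs(state)
    if not epochs:
        raise ValueError(f"no {state} epochs")
    rule = down_rule or (
        "hippocampus-fraction" if spikes.region == "hippocampus" else "neocortex-off"
    )
    parts = []
    for a, b in epochs:
        if b - a < bin_width:
            continue
        traj = bin_population(spikes, bin_width=bin_width, window=(a, b))
        if up_only:
            if rule == "neocortex-off":
                sub = restrict_to_state(spikes, Hypnogram([(a, b, state)]), state)
                off = detect_off_periods(sub)
                on = detect_on_periods(sub, off)
                if len(on) == 0:
                    continue
                # keep only bins fully inside detected ON (population-firing)
                # periods; silent stretches outside the OFF bounds are
                # excluded too, not just the OFF periods themselves
                covered = intervals_to_series(on, traj, min_coverage=1.0 - 1e-9)
                keep = covered.is_down == 1
                if not keep.any():
                    continue
                traj = restrict_trajectory(traj, keep)
            else:
                series = detect_fraction_down(traj)
                if series.is_down.all():
                    continue
                traj = exclude_down_bins(traj, series)
        parts.append(traj)
    if not parts:
        raise ValueError(f"no usable {state} bins")
    counts = np.vstack([p.counts for p in parts])
    starts = np.concatenate([p.bin_starts for p in parts])
    return PopulationTrajectory(counts=counts, bin_width=bin_width,
                                bin_starts=starts, neuron_ids=list(spikes.neuron_ids))


def session_state_metrics(
    spikes: SpikeTrainSet,
    hyp: Hypnogram,
    state: str,
    epsilon: float,
    bin_width: float = 0.05,
    window_len: float = 10.0,
    up_only: bool = False,
    down_rule: str | None = None,
) -> dict:
    """Mean windowed RQA metrics of one session in one state."""
    traj = _state_trajectory(spikes, hyp, state, bin_width, up_only, down_rule)
    metrics = windowed_rqa(traj, epsilon, window_len=window_len)
    if not metrics:
        raise ValueError(f"{state}: fewer bins than one window")
    return mean_metrics(metrics)


@dataclass
class ComparisonReport:
    table: pd.DataFrame
    friedman: dict
    posthoc: dict
    provenance: dict = field(default_factory=dict)

    def significant_pairs(self, metric: str, alpha: float = 0.05) -> list:
        return [r["pair"] for r in self.posthoc[metric] if r["p_adj"] < alpha]


def run_state_comparison(
    sessions: list,
    states=STATE_ORDER,
    bin_width: float = 0.05,
    window_len: float = 10.0,
    up_only: bool = False,
    down_rule: str | None = None,
    epsilon_sd: float = 1.0,
) -> ComparisonReport:
    """Per-state windowed RQA pooled across sessions, with Friedman omnibus
    and BH-corrected pairwise post-hoc tests.

    Sessions missing a requested state are excluded with a warning; at
    least 3 complete sessions are required for the paired design.
    """
    rows = []
    kept = 0
    for i, (spikes, hyp) in enumerate(sessions):
        if any(not hyp.epochs(s) for s in states):
            warnings.warn(f"session {i} lacks a requested state; excluded")
            continue
        eps = wake_epsilon(spikes, hyp, bin_width=bin_width, n_sd=epsilon_sd)
        rec = {"session": i}
        for s in states:
            m = session_state_metrics(
                spikes, hyp, s, eps, bin_width=bin_width, window_len=window_len,
                up_only=up_only and s == "SWS", down_rule=down_rule,
            )
            for k, v in m.items():
                rec[f"{s}_{k}"] = v
        rows.append(rec)
        kept += 1
    if kept < 3:
        raise ValueError("need at least 3 sessions with all requested states")
    table = pd.DataFrame(rows).set_index("session")

    friedman, posthoc = {}, {}
    for k in RQA_KEYS:
        samples = {s: table[f"{s}_{k}"].to_numpy() for s in states}
        friedman[k] = friedman_test(samples)
        posthoc[k] = paired_posthoc(samples)

    cfg = {
        "states": list(states), "bin_width": bin_width, "window_len": window_len,
        "up_only": up_only, "down_rule": down_rule, "epsilon_sd": epsilon_sd,
        "n_sessions": kept,
    }
    provenance = {
        "config": cfg,
        "config_hash": hashlib.md5(json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
    }
    return ComparisonReport(table=table, friedman=friedman, posthoc=posthoc,
                            provenance=provenance)


def session_field_complexity(
    spikes: SpikeTrainSet,
    hyp: Hypnogram,
    state: str,
    bin_width: float = 0.008,
    tau: float = 0.024,
    exclude_down: bool = False,
    down_rule: str | None = None,
    max_duration: float = 240.0,
) -> dict:
    """sLFP of one state plus its spectrum and complexity measures.

    With ``exclude_down`` the DOWN bins (at the sLFP bin width) are removed
    from the trajectory before the convolution, so the field reflects UP
    activity only.  At most ``max_duration`` seconds of signal enter the
    complexity measures (the pairwise sample-entropy count is quadratic).
    """
    traj = _state_trajectory(spikes, hyp, state, bin_width,
                             up_only=exclude_down, down_rule=down_rule)
    if max_duration is not None:
        max_bins = int(max_duration / bin_width)
        traj = restrict_trajectory(traj, np.arange(traj.n_bins) < max_bins)
    # rebuild a spike-free path: convolve counts directly
    from .fields import FieldSignal, exponential_kernel

    kernel = exponential_kernel(bin_width, tau)
    T = traj.n_bins
    out = np.zeros(T)
    exc = [k for k, n in enumerate(traj.neuron_ids) if spikes.excitatory.get(n, True)]
    if not exc:
        raise ValueError("no excitatory neurons")
    for k in exc:
        out += np.convolve(traj.counts[:, k].astype(float), kernel)[:T]
    out /= len(exc)
    sig = FieldSignal(samples=out, fs=1.0 / bin_width, kind="sLFP")
    spec = welch_psd(sig)
    comp = signal_complexity(sig.samples)
    return {
        "signal": sig,
        "spectrum": spec,
        "delta_fraction": spec.band_fraction(0.0, 4.0),
        "pe": comp.pe,
        "se": comp.se,
        "lz": comp.lz,
    }


def robustness_sweep(
    spikes: SpikeTrainSet,
    hyp: Hypnogram,
    eps_sds=(0.0, 1.0, 2.0, 3.0, 4.0),
    bin_widths=(0.02, 0.05, 0.1, 0.2),
    states=STATE_ORDER,
    window_len: float = 10.0,
) -> pd.DataFrame:
    """RQA metric means on a (tolerance, bin-width) grid, per state.

    Tolerances are expressed in units of the wakefulness SD of the summed
    counts at each bin width (0-4 SD); bin widths span 20-200 ms.
    """
    rows = []
    for bw in bin_widths:
        sd1 = wake_epsilon(spikes, hyp, bin_width=bw, n_sd=1.0)
        for ns in eps_sds:
            eps = ns * sd1
            for s in states:
                if not hyp.epochs(s):
                    continue
                m = session_state_metrics(spikes, hyp, s, eps, bin_width=bw,
                                          window_len=window_len)
                rows.append({"state": s, "bin_width": bw, "eps_sd": ns,
                             "epsilon": eps, **m})
    return pd.DataFrame(rows)


def neuron_count_dependence(
    spikes: SpikeTrainSet,
    hyp: Hypnogram,
    sizes,
    n_rep: int = 5,
    seed: int = 0,
    bin_width: float = 0.05,
    window_len: float = 10.0,
) -> dict:
    """Absolute between-state RQA differences as a function of neuron count.

    For each subsample size, ``n_rep`` random neuron subsets are analysed;
    |SWS - Wake| and |SWS - REM| differences per metric are regressed on
    the subsample size (ordinary least squares slope and p-value).
    """
    rng = np.random.default_rng(seed)
    n = spikes.n_neurons
    records = []
    for size in sizes:
        if size > n:
            raise ValueError(f"subsample size {size} exceeds population {n}")
        for rep in range(n_rep):
            ids = list(rng.choice(spikes.neuron_ids, size=size, replace=False))
            sub = spikes.subset(ids)
            eps = wake_epsilon(sub, hyp, bin_width=bin_width)
            per_state = {
                s: session_state_metrics(sub, hyp, s, eps, bin_width=bin_width,
                                         window_len=window_len)
                for s in STATE_ORDER
            }
            rec = {"size": size, "rep": rep}
            for k in RQA_KEYS:
                rec[f"dSW_{k}"] = abs(per_state["SWS"][k] - per_state["Wake"][k])
                rec[f"dSR_{k}"] = abs(per_state["SWS"][k] - per_state["REM"][k])
            records.append(rec)
    df = pd.DataFrame(records)
    fits = {}
    for col in [c for c in df.columns if c.startswith("d")]:
        res = sstats.linregress(df["size"], df[col])
        fits[col] = {"slope": float(res.slope), "p": float(res.pvalue)}
    return {"table": df, "fits": fits}
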