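"""Small statistics helpers: effect sizes, bootstrap CIs, paired comparisons.

Cohen's d and the percentile bootstrap are implemented in-repo because
their exact conventions matter; omnibus and post-hoc tests wrap standard
routines (scipy Friedman, Wilcoxon signed-rank, Benjamini-Hochberg FDR).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests


def cohens_d(a, b) -> float:
    """Standardised mean difference (mean(a) - mean(b)) / pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    return float((a.mean() - b.mean()) / pooled)


def bootstrap_ci(
    values,
    statistic=np.mean,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of ``statistic``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = statistic(x[rng.integers(0, x.size, size=x.size)])
    alpha = (1.0 - level) / 2
    return (float(np.quantile(boots, alpha)), float(np.quantile(boots, 1 - alpha)))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg FDR-adjusted p-values (monotone in the raw order)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def friedman_test(samples: dict) -> tuple[float, float]:
    """Friedman omnibus across paired conditions; samples: name -> values."""
    arrays = [np.asarray(v, dtype=float) for v in samples.values()]
    stat, p = sstats.friedmanchisquare(*arrays)
    return float(stat), float(p)


def paired_posthoc(samples: dict) -> list[dict]:
    """All pairwise Wilcoxon signed-rank tests with BH correction.

    Returns one record per pair with the raw and adjusted p-value and
    Cohen's d.
    """
    names = list(samples.keys())
    recs = []
    for x, y in combinations(names, 2):
        a = np.asarray(samples[x], dtype=float)
        b = np.asarray(samples[y], dtype=float)
        if np.allclose(a, b):
            p = 1.0
        else:
            p = float(sstats.wilcoxon(a, b).pvalue)
        try:
            d = cohens_d(a, b)
        except ValueError:
            d = float("nan")
        recs.append({"pair": (x, y), "p_raw": p, "cohens_d": d})
    adj = bh_adjust([r["p_raw"] for r in recs])
    for r, q in zip(recs, adj):
        r["p_adj"] = float(q)
    return recs
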