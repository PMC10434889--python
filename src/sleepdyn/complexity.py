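"""Temporal-complexity measures for field signals and spike trains.

Permutation entropy (ordinal-pattern Shannon entropy, natural log), sample
entropy (negative log conditional match ratio under the Chebyshev
distance), and Lempel-Ziv-76 complexity (normalized exhaustive phrase
count of the mean-binarized signal).

All three are invariant to affine rescaling of the input: PE and LZ depend
only on order/binarization relative to the mean, and the SE tolerance
scales with the signal's standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class ComplexityResult:
    pe: float
    se: float
    lz: float
    params: dict


def _ordinal_pattern(window: np.ndarray) -> tuple:
    # stable argsort: ties ranked by order of appearance
    return tuple(np.argsort(window, kind="stable"))


def permutation_entropy(
    x,
    order: int = 3,
    delay: int = 5,
    mode: str = "sliding",
    base: float = math.e,
) -> float:
    """Shannon entropy of ordinal patterns of ``order`` points spaced
    ``delay`` samples apart.

    ``mode="sliding"`` (default) uses every admissible window;
    ``mode="nonoverlap"`` advances by the window span instead.  Ties are
    ranked by order of appearance.
    """
    x = np.asarray(x, dtype=float)
    span = (order - 1) * delay + 1
    if x.size < span + 1:
        raise ValueError("series too short for the requested order/delay")
    step = 1 if mode == "sliding" else span
    counts: dict = {}
    for i in range(0, x.size - span + 1, step):
        pat = _ordinal_pattern(x[i:i + span:delay])
        counts[pat] = counts.get(pat, 0) + 1
    p = np.array(list(counts.values()), dtype=float)
    p /= p.sum()
    return float(-(p * np.log(p)).sum() / math.log(base))


def sample_entropy(
    x,
    m: int = 3,
    r_frac: float = 0.1,
    downsample: int = 5,
) -> float:
    """SE = -log(A / B): A (B) counts template pairs of length m+1 (m)
    closer than r = ``r_frac`` * SD under the Chebyshev distance.

    The signal is decimated by ``downsample`` first (keeping every k-th
    sample); matching is strict (< r) and self-matches are excluded.  Both
    template sets use the same start indices, so a constant signal gives
    exactly 0.  Returns NaN when no pair matches at either length.
    """
    x = np.asarray(x, dtype=float)
    if downsample > 1:
        x = x[::downsample]
    n = x.size
    if n < m + 2:
        raise ValueError("series too short after downsampling")
    r = r_frac * x.std(ddof=0)
    # templates share start indices i = 0 .. n-m-1 for both lengths, so a
    # constant signal gives A = B exactly
    emb = np.lib.stride_tricks.sliding_window_view(x, m + 1)  # (n-m, m+1)
    n_templates = emb.shape[0]
    a = b = 0
    chunk = max(1, 2_000_000 // max(n_templates, 1))
    for i0 in range(0, n_templates - 1, chunk):
        i1 = min(i0 + chunk, n_templates - 1)
        diffs = np.abs(emb[i0:i1, None, :] - emb[None, i0 + 1:, :])
        d_m = diffs[:, :, :m].max(axis=2)
        d_m1 = np.maximum(d_m, diffs[:, :, m])
        # keep ordered pairs j > i only
        rows = np.arange(i0, i1)[:, None]
        cols = np.arange(i0 + 1, n_templates)[None, :]
        mask = cols > rows
        if r > 0:
            b += int(np.count_nonzero((d_m < r) & mask))
            a += int(np.count_nonzero((d_m1 < r) & mask))
        else:
            # degenerate tolerance (constant-ish signal): exact-equality match
            b += int(np.count_nonzero((d_m == 0) & mask))
            a += int(np.count_nonzero((d_m1 == 0) & mask))
    if a == 0 or b == 0:
        return float("nan")
    return float(-math.log(a / b))


def binarize_at_mean(x) -> np.ndarray:
    """1 where the sample exceeds the signal mean, else 0.

    For a constant signal no sample is greater than the mean, so the
    output is all zeros.
    """
    x = np.asarray(x, dtype=float)
    return (x > x.mean()).astype(np.uint8)


def _lz76_core(s) -> int:
    n = s.size
    i, k, l = 0, 1, 1
    k_max = 1
    c = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


try:  # the exhaustive parse is sequential; JIT it when numba is available
    from numba import njit as _njit

    _lz76_fast = _njit(_lz76_core)
except ImportError:  # pragma: no cover
    _lz76_fast = _lz76_core


def lz76_phrase_count(s: np.ndarray) -> int:
    """Number of phrases in the exhaustive Lempel-Ziv (1976) parsing."""
    s = np.ascontiguousarray(s, dtype=np.uint8)
    if s.size == 0:
        return 0
    if s.size == 1:
        return 1
    return int(_lz76_fast(s))


def lempel_ziv_76(x, normalize: bool = True) -> float:
    """LZ-76 complexity of the mean-binarized signal.

    Returns ``c / (w / log2 w)`` where c is the exhaustive phrase count
    and w the sequence length; an iid fair-coin sequence approaches 1.
    """
    s = binarize_at_mean(x)
    w = s.size
    if w < 2:
        raise ValueError("series too short")
    c = lz76_phrase_count(s)
    if not normalize:
        return float(c)
    return float(c / (w / math.log2(w)))


def signal_complexity(
    x,
    pe_order: int = 3,
    pe_delay: int = 5,
    se_m: int = 3,
    se_r_frac: float = 0.1,
    se_downsample: int = 5,
) -> ComplexityResult:
    """All three measures with the study's defaults."""
    return ComplexityResult(
        pe=permutation_entropy(x, order=pe_order, delay=pe_delay),
        se=sample_entropy(x, m=se_m, r_frac=se_r_frac, downsample=se_downsample),
        lz=lempel_ziv_76(x),
        params={
            "pe_order": pe_order, "pe_delay": pe_delay, "se_m": se_m,
            "se_r_frac": se_r_frac, "se_downsample": se_downsample,
            "binarization": "mean",
        },
    )


def single_unit_lz(counts: np.ndarray) -> float:
    """LZ-76 of one neuron's binned spike counts (binarized at the mean)."""
    return lempel_ziv_76(np.asarray(counts, dtype=float))
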