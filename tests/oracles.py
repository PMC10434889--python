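"""Independent brute-force oracles used to validate the fast implementations."""

import math

import numpy as np


def brute_rqa(R, l_min=2, v_min=2):
    """O(T^3)-style recurrence metrics by explicit line scanning.

    Walks every off-identity diagonal (both triangles) and every column with
    plain Python loops, collecting run lengths; no shared code with the
    package implementation.
    """
    R = np.asarray(R)
    T = R.shape[0]
    diag_lines = []
    for off in range(1, T):
        for sign in (1, -1):
            run = 0
            for i in range(T - off):
                a, b = (i, i + off) if sign == 1 else (i + off, i)
                if R[a, b]:
                    run += 1
                else:
                    if run:
                        diag_lines.append(run)
                    run = 0
            if run:
                diag_lines.append(run)
    vert_lines = []
    for j in range(T):
        run = 0
        for i in range(T):
            if R[i, j]:
                run += 1
            else:
                if run:
                    vert_lines.append(run)
                run = 0
        if run:
            vert_lines.append(run)

    rr = sum(int(R[i, j]) for i in range(T) for j in range(T)) / (T * T)
    dp = sum(diag_lines)
    det = sum(l for l in diag_lines if l >= l_min) / dp if dp else 0.0
    l_max = max(diag_lines) if diag_lines else 1
    div = 1.0 / max(l_max, 1)
    vp = sum(vert_lines)
    qual = [v for v in vert_lines if v >= v_min]
    lam = sum(qual) / vp if vp else 0.0
    tt = sum(qual) / len(qual) if qual else 0.0
    return {"RR": rr, "DET": det, "LAM": lam, "TT": tt, "DIV": div}


def brute_sample_entropy(x, m=3, r_frac=0.1, downsample=1):
    """Exhaustive pair-counting SampEn (strict < r, Chebyshev, shared index set)."""
    x = np.asarray(x, dtype=float)[::downsample]
    n = len(x)
    r = r_frac * x.std()

    def count(mm):
        c = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                d = max(abs(x[i + k] - x[j + k]) for k in range(mm))
                if (d < r) if r > 0 else (d == 0):
                    c += 1
        return c

    a, b = count(m + 1), count(m)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def brute_permutation_entropy(x, order=3, delay=1):
    """Ordinal-pattern entropy by explicit pattern enumeration."""
    x = np.asarray(x, dtype=float)
    span = (order - 1) * delay + 1
    counts = {}
    for i in range(len(x) - span + 1):
        w = x[i:i + span:delay]
        pat = tuple(sorted(range(order), key=lambda k: (w[k], k)))
        counts[pat] = counts.get(pat, 0) + 1
    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values())
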