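"""Independent oracles: brute-force / closed-form re-implementations used only
by the tests to check the package's fast paths."""

from __future__ import annotations

import math

import numpy as np

NEG = -1e12


def gotoh_semi_global(read: str, ref: str) -> float:
    """Exhaustive DP for the semi-global scheme: read global, reference local;
    match +1, mismatch -1, a gap of length L costs -(3 + L)."""
    n, m = len(read), len(ref)
    OPEN, EXT = -4.0, -1.0
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in ref (read base vs -)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in read (ref base vs -)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        M[0, j] = 0.0  # leading unaligned reference is free
    for i in range(1, n + 1):
        Ix[i, 0] = OPEN + EXT * (i - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1.0 if read[i - 1] == ref[j - 1] else -1.0
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] + OPEN, Ix[i - 1, j] + EXT)
            Iy[i, j] = max(M[i, j - 1] + OPEN, Iy[i, j - 1] + EXT)
    return float(max(max(M[n, j], Ix[n, j]) for j in range(m + 1)))


def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Closed-form Wilson score interval for a binomial proportion."""
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct log-space summation."""
    if k <= 0:
        return 1.0
    lp, lq = math.log(p), math.log1p(-p)
    total = 0.0
    for x in range(k, n + 1):
        total += math.exp(math.lgamma(n + 1) - math.lgamma(x + 1)
                          - math.lgamma(n - x + 1) + x * lp + (n - x) * lq)
    return min(total, 1.0)


def nearest_barcode(i5: str, i7: str, pairs: list[tuple[str, str, str]],
                    max_mismatch: int):
    """Brute-force nearest-neighbor scan over (sample_id, i5, i7) triples.

    Returns (sample_id | None, ambiguous: bool)."""
    dists = []
    for sid, b5, b7 in pairs:
        d = sum(a != b for a, b in zip(i5, b5)) + sum(a != b for a, b in zip(i7, b7))
        dists.append((d, sid))
    dmin = min(d for d, _ in dists)
    hits = [sid for d, sid in dists if d == dmin]
    if dmin > max_mismatch:
        return None, False
    if len(hits) > 1:
        return None, True
    return hits[0], False


def selection_pool_rates(joint: np.ndarray, l0: float, l1: float, l2: float):
    """Brute-force enumeration over the 8 editing states of the splicing
    selection model; returns (pre_rates, mrna_rates) keyed by site index
    0=S/G, 1=Q/R, 2=intron+4."""
    pre = [0.0, 0.0, 0.0]
    num = [0.0, 0.0, 0.0]
    denom = 0.0
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                w = joint[a, b, c]
                sp = 1.0 / (1.0 + math.exp(-(l0 - l1 * b - l2 * c)))
                denom += w * sp
                for i, bit in enumerate((a, b, c)):
                    pre[i] += w * bit
                    num[i] += w * sp * bit
    return pre, [x / denom for x in num]


def ols_normal_equations(x, y):
    """Straight-line fit and R^2 via the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return float(beta[1]), float(beta[0]), 1.0 - ss_res / ss_tot
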