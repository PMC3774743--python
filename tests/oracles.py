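"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration, grid search or
resampling, sharing no code with the implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE p-value by full enumeration with rational arithmetic."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het

    def weight(h):
        hom_alt = (n_alt - h) // 2
        hom_ref = n - h - hom_alt
        if hom_alt < 0 or hom_ref < 0 or (n_alt - h) % 2:
            return Fraction(0)
        # multinomial count x 2^h phase factor, conditional on allele counts
        return Fraction(comb(n, h) * comb(n - h, hom_alt) * 2**h)

    weights = {h: weight(h) for h in range(0, min(n_alt, 2 * n - n_alt) + 1)}
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items() if w > 0}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


def simplex_grid_min(Q: np.ndarray, c: np.ndarray, const: float, step: float = 1e-3):
    """Exhaustive simplex grid search of alpha' Q alpha + c' alpha + const (L <= 3)."""
    L = len(c)
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    if L == 1:
        grid = np.array([[1.0]])
    elif L == 2:
        grid = np.column_stack([ticks, 1.0 - ticks])
    elif L == 3:
        a, b = np.meshgrid(ticks, ticks, indexing="ij")
        keep = a + b <= 1.0 + 1e-12
        grid = np.column_stack([a[keep], b[keep], 1.0 - a[keep] - b[keep]])
    else:
        raise ValueError("grid oracle supports L <= 3")
    vals = np.einsum("ij,jk,ik->i", grid, Q, grid) + grid @ c + const
    i = int(np.argmin(vals))
    return grid[i], float(vals[i])


def hudson_fst(p1, n1, p2, n2) -> float:
    """Hudson's FST estimator as a ratio of sums over SNPs."""
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


def permutation_slope_pvalue(x, y, n_perm: int = 10_000, seed: int = 0) -> float:
    """One-sided p for positive OLS slope by permutation of y.

    The OLS slope is proportional to the x-y covariance at fixed x, so
    permuted covariances rank permuted slopes.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float)
    obs = x @ y
    count = 0
    for _ in range(n_perm):
        count += x @ rng.permutation(y) >= obs
    return (1 + count) / (1 + n_perm)


def permutation_corr_pvalue(x, y, n_perm: int = 10_000, seed: int = 0) -> float:
    """Two-sided p for Pearson correlation by permutation of y."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float)
    obs = abs(x @ (y - y.mean()))
    count = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        count += abs(x @ (yp - yp.mean())) >= obs
    return (1 + count) / (1 + n_perm)
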