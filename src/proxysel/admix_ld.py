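"""Admixture-LD analytics and haplotype diversity.

Mixing two populations X and Y in proportion alpha : 1-alpha produces, at a
pair of SNPs j, k, expected LD

    D_Z(alpha) = alpha D_X + (1 - alpha) D_Y + alpha (1 - alpha) delta_j delta_k,

where delta is the between-source allele-frequency difference at each SNP —
a quadratic in alpha whose cross term is the admixture contribution. Its
maximum over alpha in [0, 1] bounds how much LD admixture alone can create.
The quadratic form holds on a signed LD scale, so the module operates on the
signed composite D (an r^2 variant is available where only magnitudes
matter). Haplotype diversity uses the unbiased estimator
H = n/(n-1) (1 - sum p_i^2) over haplotype frequencies p.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .freq_stats import FrequencyTable, freq_difference
from .panel_io import GenotypePanel, PanelError
from .proxy_score import LDTable, pairwise_ld


def expected_admixture_ld(D_X, D_Y, delta_j, delta_k, alpha):
    """Expected LD in the mixture at proportion alpha of source X."""
    alpha = np.asarray(alpha, float)
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * D_X + (1 - alpha) * D_Y + alpha * (1 - alpha) * delta_j * delta_k


def max_expected_admixture_ld(D_X, D_Y, delta_j, delta_k) -> tuple[float, float]:
    """Maximize the admixture-LD quadratic over alpha in [0, 1].

    With c = delta_j delta_k != 0 the stationary point is
    alpha* = (D_X - D_Y + c) / (2 c); it is the maximum only when the
    quadratic is concave (c > 0), in which case alpha* is clamped to [0, 1].
    Otherwise the maximum sits at the better boundary (alpha = 1 gives D_X,
    alpha = 0 gives D_Y). Returns (alpha_star, D_max).
    """
    c = delta_j * delta_k
    if c > 0:
        a = float(np.clip((D_X - D_Y + c) / (2 * c), 0.0, 1.0))
    else:
        a = 1.0 if D_X >= D_Y else 0.0
    return a, float(expected_admixture_ld(D_X, D_Y, delta_j, delta_k, a))


def subsample_panel(panel: GenotypePanel, n_samples: int, seed: int = 0) -> GenotypePanel:
    """Seeded subsample without replacement, for equal-size LD comparisons."""
    if n_samples > panel.n_samples:
        raise ValueError("cannot subsample beyond the panel size")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(panel.n_samples, size=n_samples, replace=False))
    return panel.subset_samples(idx)


def ld_decay_profile(
    panel: GenotypePanel,
    bin_edges_morgans,
    max_pairs: int = 200_000,
    seed: int = 0,
):
    """Mean pairwise r^2 per genetic-distance bin.

    Returns a list of dicts (bin_lo, bin_hi, mean_r2, n_pairs); empty bins
    are reported with count 0 and mean NaN. To compare cohorts of unequal
    size, subsample them to a common size first (:func:`subsample_panel`).
    """
    edges = np.asarray(bin_edges_morgans, float)
    if len(edges) < 3:
        raise ValueError("at least 2 bins (3 edges) required")
    ld = pairwise_ld(panel, max_dist_morgans=float(edges[-1]), max_pairs=max_pairs, seed=seed)
    which = np.digitize(ld.dist_morgans, edges) - 1
    out = []
    for b in range(len(edges) - 1):
        sel = which == b
        n = int(sel.sum())
        out.append(
            {
                "bin_lo": float(edges[b]),
                "bin_hi": float(edges[b + 1]),
                "mean_r2": float(ld.r2[sel].mean()) if n else float("nan"),
                "n_pairs": n,
            }
        )
    return out


def admixture_ld_correlation(
    admixed_ld: LDTable,
    source_pairs: list[tuple[FrequencyTable, FrequencyTable]],
    mode: str = "per-pair",
    use_r2: bool = False,
):
    """Correlate admixed-cohort LD with ancestral differentiation products.

    per-pair: for each source pair (X, Y), the Pearson correlation of the
    admixed LD statistic with |delta_j delta_k| and its p-value.
    additive: multiple regression of the admixed LD on all pairs'
    delta_j delta_k jointly; returns the overall F-test p-value alongside
    the per-pair table.
    """
    if mode not in ("per-pair", "additive"):
        raise ValueError("mode must be 'per-pair' or 'additive'")
    y = admixed_ld.r2 if use_r2 else admixed_ld.D
    if np.ptp(y) == 0:
        raise ValueError("admixed LD vector is constant: correlation undefined")
    if admixed_ld.n_pairs < 10:
        raise ValueError("fewer than 10 usable pairs")
    cols, rows = [], []
    for fA, fB in source_pairs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            delta = freq_difference(fA, fB)
        x = delta[admixed_ld.idx_j] * delta[admixed_ld.idx_k]
        ok = ~np.isnan(x)
        r, p = stats.pearsonr(np.abs(x[ok]), y[ok])
        rows.append({"pair": f"{fA.pop_label}-{fB.pop_label}", "r": float(r), "p": float(p)})
        cols.append(np.where(ok, x, 0.0))
    if mode == "per-pair":
        return rows
    X = np.column_stack(cols)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return rows, float(fit.f_pvalue)


def haplotype_diversity(hap_freqs, n: int) -> float:
    """Unbiased haplotype diversity H = n/(n-1) (1 - sum p_i^2)."""
    p = np.asarray(hap_freqs, float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("haplotype frequencies must sum to 1")
    if n < 2:
        raise ValueError("haplotype sample size must be >= 2")
    return float(n / (n - 1) * (1.0 - (p**2).sum()))


def window_haplotype_diversity(panel: GenotypePanel, window_snps: int = 5) -> np.ndarray:
    """Haplotype diversity per non-overlapping window of phased SNPs.

    Haplotype frequencies within each window are the observed frequencies of
    distinct allele strings across the panel's haplotypes. Returns one H per
    window; the panel-level summary is their mean.
    """
    if not panel.phased or panel.haplotypes is None:
        raise PanelError("window_haplotype_diversity requires a phased panel")
    H = panel.haplotypes
    n = H.shape[0]
    out = []
    for lo in range(0, panel.n_snps - window_snps + 1, window_snps):
        block = H[:, lo : lo + window_snps]
        _, counts = np.unique(block, axis=0, return_counts=True)
        out.append(haplotype_diversity(counts / n, n))
    return np.asarray(out)
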