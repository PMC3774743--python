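"""Simplex-constrained quadratic program for ancestry-mixture fitting.

The admixed population's allele frequencies are modelled as a convex
combination of L candidate reference panels. The objective

    F(alpha) = mean over SNPs of (p_A - sum_i alpha_i p_i)^2,

debiased for finite sample size (each squared observed frequency is an
upwardly biased estimate of the squared population frequency; subtracting
p(1-p)/(n-1) removes the bias), is quadratic in alpha and minimized over the
probability simplex {alpha >= 0, sum alpha = 1}. Expanding the square gives
F = alpha' Q alpha + c' alpha + const with Q positive semidefinite up to the
debiasing terms; combinations of one panel per pool are ranked by their
minimized F.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .freq_stats import FrequencyTable


@dataclass
class QpSpec:
    """Quadratic-form coefficients of the mixture objective, summed over SNPs.

    F(alpha) = alpha' Q alpha + c' alpha + const, on the mean-per-SNP scale.
    """

    Q: np.ndarray
    c: np.ndarray
    const: float
    labels: list[str]
    n_snps_used: int
    n_snps_dropped: int = 0

    @property
    def L(self) -> int:
        return len(self.labels)

    def objective(self, alpha: np.ndarray) -> float:
        alpha = np.asarray(alpha, float)
        return float(alpha @ self.Q @ alpha + self.c @ alpha + self.const)


@dataclass
class MixSolution:
    labels: list[str]
    alpha: np.ndarray
    F: float
    se: float | None = None
    ci95: tuple[float, float] | None = None
    n_clipped_eigenvalues: int = 0


def build_qp(
    admixed: FrequencyTable,
    refs: list[FrequencyTable],
    bias_correction: bool = True,
) -> QpSpec:
    """Expand the mean squared frequency distance into alpha' Q alpha + c' alpha + const.

    With correction, Q_ii sums p_i^2 - p_i(1-p_i)/(n_i-1) and the constant
    sums p_A^2 - p_A(1-p_A)/(n_A-1); cross terms Q_il = sum p_i p_l and
    c_i = -2 sum p_A p_i are unbiased as-is because the panels are
    independent samples. SNPs with an undefined frequency (or n < 2 when
    correcting) in any table are dropped and counted.
    """
    if not refs:
        raise ValueError("at least one reference required")
    for r in refs:
        if r.snp_ids != admixed.snp_ids:
            raise ValueError(f"reference {r.pop_label} not on the admixed SNP list")
    P = np.column_stack([r.alt_freq for r in refs])  # m x L
    N = np.column_stack([r.allele_count for r in refs])
    pA, nA = admixed.alt_freq, admixed.allele_count
    ok = ~np.isnan(pA) & ~np.isnan(P).any(axis=1)
    if bias_correction:
        ok &= (nA >= 2) & (N >= 2).all(axis=1)
    m = int(ok.sum())
    if m == 0:
        raise ValueError("all SNPs dropped: no usable frequencies")
    P, N, pA, nA = P[ok], N[ok], pA[ok], nA[ok]

    Q = P.T @ P
    c = -2.0 * (P.T @ pA)
    const = float(pA @ pA)
    if bias_correction:
        Q[np.diag_indices_from(Q)] -= (P * (1 - P) / (N - 1)).sum(axis=0)
        const -= float((pA * (1 - pA) / (nA - 1)).sum())
    scale = 1.0 / m
    return QpSpec(Q * scale, c * scale, const * scale, [r.pop_label for r in refs], m, int((~ok).sum()))


def _psd_repair(Q: np.ndarray) -> tuple[np.ndarray, int]:
    Qs = 0.5 * (Q + Q.T)
    w, V = np.linalg.eigh(Qs)
    n_clip = int((w < 0).sum())
    if n_clip:
        Qs = (V * np.maximum(w, 0.0)) @ V.T
        Qs = 0.5 * (Qs + Qs.T)
    return Qs, n_clip


def _solve_support(Q, c, support):
    """Equality-constrained minimizer of a'Qa + c'a with sum(a)=1 on a support set."""
    k = len(support)
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = 2.0 * Q[np.ix_(support, support)]
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    b = np.zeros(k + 1)
    b[:k] = -c[support]
    b[k] = 1.0
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:k]


def solve_simplex_qp(spec: QpSpec) -> MixSolution:
    """Global minimizer of the mixture objective over the probability simplex.

    The (PSD-repaired) convex QP is solved exactly by enumerating active
    sets: for every nonempty support the equality-constrained KKT system is
    solved and primal-feasible candidates are compared. Deterministic; ties
    resolve to the first support in lexicographic enumeration order. The
    objective F is reported on the ORIGINAL (unrepaired) coefficients.
    """
    if not (np.all(np.isfinite(spec.Q)) and np.all(np.isfinite(spec.c)) and np.isfinite(spec.const)):
        raise ValueError("non-finite QP coefficients")
    L = spec.L
    Q, n_clip = _psd_repair(spec.Q)
    c = spec.c
    best_alpha, best_val = None, np.inf
    for r in range(1, L + 1):
        for support in itertools.combinations(range(L), r):
            a_s = _solve_support(Q, c, list(support))
            if np.any(a_s < -1e-9) or not np.all(np.isfinite(a_s)):
                continue
            alpha = np.zeros(L)
            alpha[list(support)] = np.clip(a_s, 0.0, None)
            s = alpha.sum()
            if s <= 0:
                continue
            alpha /= s
            val = float(alpha @ Q @ alpha + c @ alpha)
            if val < best_val - 1e-15:
                best_val, best_alpha = val, alpha
    if best_alpha is None:  # cannot happen for finite input, but be safe
        best_alpha = np.full(L, 1.0 / L)
    return MixSolution(
        list(spec.labels), best_alpha, spec.objective(best_alpha), n_clipped_eigenvalues=n_clip
    )


def _block_slices(m: int, block_size: int):
    n_blocks = m // block_size + (1 if m % block_size else 0)
    return [(b * block_size, min((b + 1) * block_size, m)) for b in range(n_blocks)]


def fit_mixture(
    admixed: FrequencyTable,
    refs: list[FrequencyTable],
    block_size_snps: int = 500,
    bias_correction: bool = True,
) -> MixSolution:
    """Fit simplex-constrained proportions with a block-jackknife SE on F.

    Contiguous SNP blocks are deleted in turn, the QP coefficients rebuilt
    from the remaining SNPs (cheap: per-block partial sums subtracted from
    the totals) and alpha refit; the jackknife spread of the refit F gives
    the SE and the 95% CI F +/- 1.96 SE.
    """
    spec = build_qp(admixed, refs, bias_correction)
    sol = solve_simplex_qp(spec)
    m = spec.n_snps_used
    slices = _block_slices(m, block_size_snps)
    if len(slices) < 2:
        return sol

    # rebuild per-SNP quantities on the SNPs build_qp retained
    P = np.column_stack([r.alt_freq for r in refs])
    N = np.column_stack([r.allele_count for r in refs])
    pA, nA = admixed.alt_freq, admixed.allele_count
    ok = ~np.isnan(pA) & ~np.isnan(P).any(axis=1)
    if bias_correction:
        ok &= (nA >= 2) & (N >= 2).all(axis=1)
    P, N, pA, nA = P[ok], N[ok], pA[ok], nA[ok]

    Q_tot = spec.Q * m
    c_tot = spec.c * m
    k_tot = spec.const * m
    F_loo = np.empty(len(slices))
    for b, (lo, hi) in enumerate(slices):
        Pb, pAb = P[lo:hi], pA[lo:hi]
        Qb = Pb.T @ Pb
        cb = -2.0 * (Pb.T @ pAb)
        kb = float(pAb @ pAb)
        if bias_correction:
            Qb[np.diag_indices_from(Qb)] -= (Pb * (1 - Pb) / (N[lo:hi] - 1)).sum(axis=0)
            kb -= float((pAb * (1 - pAb) / (nA[lo:hi] - 1)).sum())
        mb = m - (hi - lo)
        spec_b = QpSpec((Q_tot - Qb) / mb, (c_tot - cb) / mb, (k_tot - kb) / mb, spec.labels, mb)
        F_loo[b] = solve_simplex_qp(spec_b).F
    B = len(slices)
    se = float(np.sqrt((B - 1) / B * ((F_loo - F_loo.mean()) ** 2).sum()))
    sol.se = se
    sol.ci95 = (sol.F - 1.96 * se, sol.F + 1.96 * se)
    return sol


def rank_combinations(
    admixed: FrequencyTable,
    pools: dict[str, list[FrequencyTable]],
    L: int | None = None,
    block_size_snps: int = 500,
    bias_correction: bool = True,
    max_combinations: int = 20_000,
) -> list[MixSolution]:
    """Fit every one-panel-per-pool combination and rank ascending by F.

    Ties in F are broken lexicographically by the combination's labels, so
    output order is reproducible.
    """
    pool_lists = list(pools.values())
    if L is not None and L != len(pool_lists):
        raise ValueError("L must equal the number of pools (one panel per pool)")
    n_comb = int(np.prod([len(p) for p in pool_lists]))
    if n_comb > max_combinations:
        raise ValueError(
            f"{n_comb} combinations exceed the cap {max_combinations}; prune the pools"
        )
    out = []
    for combo in itertools.product(*pool_lists):
        out.append(fit_mixture(admixed, list(combo), block_size_snps, bias_correction))
    out.sort(key=lambda s: (s.F, tuple(s.labels)))
    return out
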