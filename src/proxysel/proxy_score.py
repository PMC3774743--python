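"""The proxy-ancestry score: admixture LD versus ancestral differentiation.

Admixture between populations with different allele frequencies creates LD
between nearby markers in the admixed cohort. The score exploits this: for
each candidate reference population i, paired with every other reference l,
short-range LD in the admixed cohort is regressed on the product of allele
frequency differences delta_j * delta_k between i and l at the two SNPs of
each pair. A genuinely ancestral candidate produces positive association
(small one-sided p). Evidence is combined over pairings by the probit
transform t = Phi^-1(1 - p) and averaged; within each pool of candidates the
combined score is normalized against the other pool members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .freq_stats import FrequencyTable, allele_frequencies, freq_difference
from .panel_io import MISSING, GenotypePanel, PanelError

_P_FLOOR = 1e-300


class DegeneratePairingError(ValueError):
    """Regression predictor has no variance (e.g. the two references coincide)."""


@dataclass
class LDTable:
    """Pairwise short-range LD records for one cohort.

    For every within-chromosome SNP pair closer than the distance threshold:
    indices into the panel's SNP list, genetic distance (Morgans), the signed
    dosage correlation r, r^2, the Fisher-transformed statistic D and the
    per-pair complete-sample count n.
    """

    idx_j: np.ndarray
    idx_k: np.ndarray
    dist_morgans: np.ndarray
    r: np.ndarray
    r2: np.ndarray
    D: np.ndarray
    n: np.ndarray
    n_pairs_skipped: int = 0
    max_dist_morgans: float = np.nan

    @property
    def n_pairs(self) -> int:
        return len(self.idx_j)


@dataclass
class ProxyScoreResult:
    pool: str
    pop_label: str
    raw_score: float
    se: float
    pscore_z: float
    n_pairings: int


def fisher_ld(r: float | np.ndarray, n: int | np.ndarray, stabilized: bool = True):
    """Fisher-transformed LD statistic D = atanh(r) * sqrt(n - 3).

    Variance-stabilized so that D is comparable across pairs with different
    complete-sample counts; ``stabilized=False`` returns plain atanh(r).
    The sign of D follows the sign of r.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("transform undefined at |r| = 1")
    if np.any(n < 4):
        raise ValueError("fisher_ld requires n >= 4")
    z = np.arctanh(r)
    return z * np.sqrt(n - 3) if stabilized else z


def pairwise_ld(
    admixed: GenotypePanel,
    max_dist_morgans: float = 0.2,
    max_pairs: int = 200_000,
    seed: int = 0,
    stabilized: bool = True,
) -> LDTable:
    """Dosage r^2 for all within-chromosome SNP pairs closer than the threshold.

    r is the Pearson correlation of dosage vectors over samples complete for
    both SNPs. Pairs involving a zero-variance SNP are skipped and counted;
    pairs at |r| = 1 are kept with D evaluated just inside the open interval.
    If the candidate pair count exceeds ``max_pairs`` a seeded uniform
    subsample is taken.
    """
    if admixed.n_snps < 2:
        raise PanelError("pairwise_ld requires at least 2 SNPs")
    if admixed.n_samples < 3:
        raise PanelError("pairwise_ld requires at least 3 samples")
    gpos = admixed.gpos
    chroms = admixed.chroms
    # enumerate candidate pairs per chromosome via a sliding window
    starts_j, counts = [], []
    pair_j_parts, pair_k_parts = [], []
    for chrom in np.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        pos = gpos[idx]
        hi = np.searchsorted(pos, pos + max_dist_morgans, side="left")
        for a in range(len(idx)):
            if hi[a] > a + 1:
                pair_j_parts.append(np.full(hi[a] - a - 1, idx[a]))
                pair_k_parts.append(idx[a + 1 : hi[a]])
    if not pair_j_parts:
        raise PanelError("no SNP pairs within the distance threshold")
    J = np.concatenate(pair_j_parts)
    K = np.concatenate(pair_k_parts)
    if len(J) > max_pairs:
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(J), size=max_pairs, replace=False)
        sel.sort()
        J, K = J[sel], K[sel]

    X = admixed.genotypes.astype(float)
    X[admixed.genotypes == MISSING] = np.nan
    r_out = np.empty(len(J))
    n_out = np.empty(len(J), dtype=int)
    chunk = 20_000
    for lo in range(0, len(J), chunk):
        jj, kk = J[lo : lo + chunk], K[lo : lo + chunk]
        A, B = X[:, jj], X[:, kk]
        m = ~np.isnan(A) & ~np.isnan(B)
        n = m.sum(axis=0)
        Am = np.where(m, A, 0.0)
        Bm = np.where(m, B, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ma = Am.sum(0) / n
            mb = Bm.sum(0) / n
            sab = (Am * Bm).sum(0) - n * ma * mb
            saa = (Am * Am).sum(0) - n * ma * ma
            sbb = (Bm * Bm).sum(0) - n * mb * mb
            r_out[lo : lo + chunk] = sab / np.sqrt(saa * sbb)
        n_out[lo : lo + chunk] = n
    ok = np.isfinite(r_out) & (n_out >= 4)
    n_skipped = int((~ok).sum())
    J, K, r, n = J[ok], K[ok], r_out[ok], n_out[ok]
    # |r| can hit 1 exactly (duplicated columns); record the pair with a
    # saturated Fisher statistic rather than dropping it
    D = fisher_ld(np.clip(r, -1 + 1e-12, 1 - 1e-12), n, stabilized=stabilized)
    return LDTable(
        J, K, gpos[K] - gpos[J], r, r**2, D, n, n_skipped, max_dist_morgans
    )


def ld_vs_delta_regression(
    ld: LDTable, refA: FrequencyTable, refB: FrequencyTable
) -> tuple[float, float]:
    """OLS of the admixed cohort's D on delta_j * delta_k; one-sided p.

    delta is the signed frequency difference between the two candidate
    references; under admixture from (relatives of) A and B the cross term of
    admixture LD is alpha(1-alpha) delta_j delta_k, so the slope is expected
    positive and the p-value is one-sided for slope > 0.
    """
    delta = freq_difference(refA, refB)
    x = delta[ld.idx_j] * delta[ld.idx_k]
    y = ld.D
    ok = ~np.isnan(x)
    x, y = x[ok], y[ok]
    if len(x) < 10:
        raise ValueError("fewer than 10 usable pairs for regression")
    if np.ptp(x) == 0 or np.var(x) < 1e-300:
        raise DegeneratePairingError(
            f"degenerate pairing {refA.pop_label} vs {refB.pop_label}: delta product has no variance"
        )
    res = stats.linregress(x, y)
    p_two = res.pvalue
    p_one = p_two / 2 if res.slope > 0 else 1 - p_two / 2
    return float(res.slope), float(min(max(p_one, _P_FLOOR), 1.0))


def proxy_ancestry_scores(
    admixed: GenotypePanel,
    pools: dict[str, list[GenotypePanel]],
    max_dist_morgans: float = 0.2,
    max_pairs: int = 200_000,
    seed: int = 0,
    ld: LDTable | None = None,
) -> list[ProxyScoreResult]:
    """Score every candidate reference against a pool structure.

    For candidate i, every pairing (i, l) with the other references across
    all pools contributes t_il = Phi^-1(1 - p_il); the raw score S_i is the
    mean of t_il (its SE by delete-one-partner jackknife). Within each pool,
    pscore_z_i = (S_i - mean(S_others)) / sd(S_others). Results are sorted
    descending by pscore_z within pool.
    """
    for name, pool in pools.items():
        if len(pool) < 2:
            raise ValueError(
                f"pool {name!r} has a single candidate: normalization undefined"
            )
    if sum(len(p) for p in pools.values()) < 2:
        raise ValueError("need at least 2 reference populations overall")
    admixed_snps = admixed.snp_ids
    freqs: dict[str, FrequencyTable] = {}
    membership: list[tuple[str, str]] = []
    for name, pool in pools.items():
        for p in pool:
            if p.snp_ids != admixed_snps:
                raise PanelError(
                    f"panel {p.pop_label} not harmonized with the admixed panel"
                )
            if p.pop_label in freqs:
                raise ValueError(f"duplicate population label {p.pop_label}")
            freqs[p.pop_label] = allele_frequencies(p)
            membership.append((name, p.pop_label))
    labels = [lab for _, lab in membership]
    if ld is None:
        ld = pairwise_ld(admixed, max_dist_morgans, max_pairs, seed)

    t_vals: dict[str, list[float]] = {lab: [] for lab in labels}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                la, lb = labels[a], labels[b]
                try:
                    _, p = ld_vs_delta_regression(ld, freqs[la], freqs[lb])
                except DegeneratePairingError:
                    warnings.warn(f"degenerate pairing skipped: {la} vs {lb}")
                    continue
                t = float(stats.norm.isf(p))
                t_vals[la].append(t)
                t_vals[lb].append(t)

    if all(len(v) == 0 for v in t_vals.values()):
        raise DegeneratePairingError("all pairings degenerate: no differentiation among references")

    raw: dict[str, float] = {}
    se: dict[str, float] = {}
    for lab in labels:
        tv = np.asarray(t_vals[lab])
        if len(tv) == 0:
            raw[lab], se[lab] = np.nan, np.nan
            continue
        raw[lab] = float(tv.mean())
        if len(tv) > 1:
            loo = (tv.sum() - tv) / (len(tv) - 1)
            se[lab] = float(np.sqrt((len(tv) - 1) / len(tv) * ((loo - loo.mean()) ** 2).sum()))
        else:
            se[lab] = np.nan

    results = []
    for name, pool in pools.items():
        pool_labels = [p.pop_label for p in pool]
        for lab in pool_labels:
            others = np.asarray([raw[o] for o in pool_labels if o != lab])
            others = others[~np.isnan(others)]
            if len(others) >= 2 and np.std(others, ddof=1) > 0:
                z = (raw[lab] - others.mean()) / np.std(others, ddof=1)
            else:
                z = np.nan
            results.append(
                ProxyScoreResult(name, lab, raw[lab], se[lab], float(z), len(t_vals[lab]))
            )
    results.sort(key=lambda r: (r.pool, -(r.pscore_z if np.isfinite(r.pscore_z) else -np.inf)))
    return results
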