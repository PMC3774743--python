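"""Synthetic population generation and continuous-gene-flow admixture.

Three generators cover the study design end to end:

* :func:`synth_ancestral_panels` draws differentiated ancestral panels under
  the Balding-Nichols model (beta-distributed population frequencies around
  a shared ancestral frequency, divergence parameterized by FST), attaching
  a linear genetic map.
* :func:`expand_population` grows a phased panel by generation-by-generation
  Wright-Fisher random mating with exponential size interpolation between an
  initial and a final effective size (Rogers-Harpending style expansion),
  with crossovers as a Poisson process of rate 1 per Morgan and optional
  per-site mutation.
* :func:`simulate_admixed` builds each admixed haplotype as a Markov chain
  of ancestry segments along the chromosome: after g generations of
  continuous gene flow, ancestry is re-sampled between adjacent SNPs at map
  distance d with probability 1 - exp(-g d), and within a segment alleles
  are copied from a randomly drawn donor haplotype of the segment's source.
  True local ancestry is recorded per haplotype and SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel_io import MISSING, GenotypePanel, PanelError, SnpRecord


@dataclass
class ExpansionParams:
    """Exponential-growth expansion: N(g) = N0 * (N1/N0)^(g/t) diploids.

    ``mu`` is the per-site per-generation probability of an allele flip.
    """

    N0: int
    N1: int
    t: int
    mu: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.N0 < 1 or self.N1 < 1:
            raise ValueError("effective sizes must be >= 1")
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if not 0 <= self.mu < 1:
            raise ValueError("mu must be in [0, 1)")


@dataclass
class AdmixedCohort:
    """Simulated diploid cohort with per-SNP true local ancestry.

    ``local_ancestry`` has one row per haplotype (2 per individual) holding
    the source index that donated the allele at each SNP.
    """

    panel: GenotypePanel
    local_ancestry: np.ndarray
    proportions: np.ndarray
    generations: int
    source_labels: list[str]
    seed: int


def _linear_snps(n_snps, n_chrom, morgans_per_chrom, bp_per_chrom=100_000_000):
    snps = []
    per = n_snps // n_chrom
    counts = [per + (1 if i < n_snps % n_chrom else 0) for i in range(n_chrom)]
    for ci, cnt in enumerate(counts):
        for j in range(cnt):
            frac = j / max(cnt - 1, 1)
            snps.append(
                SnpRecord(
                    str(ci + 1),
                    int(frac * (bp_per_chrom - 1)) + 1,
                    f"rs{ci + 1}_{j}",
                    "A",
                    "G",
                    frac * morgans_per_chrom,
                )
            )
    return snps


def synth_ancestral_panels(
    n_pops: int,
    fst: list[float],
    n_snps: int,
    n_haps: int,
    maf_floor: float = 0.05,
    seed: int = 0,
    morgans_per_chrom: float = 1.0,
    n_chrom: int = 1,
    labels: list[str] | None = None,
) -> list[GenotypePanel]:
    """Balding-Nichols differentiated panels sharing one SNP list and map.

    A shared ancestral frequency pi_j ~ Uniform(maf_floor, 1 - maf_floor) is
    drawn per SNP; population i's frequency is Beta(pi (1-F_i)/F_i,
    (1-pi)(1-F_i)/F_i), and haplotype alleles are i.i.d. Bernoulli draws.
    """
    fst = np.asarray(fst, float)
    if len(fst) != n_pops:
        raise ValueError("fst vector length must equal n_pops")
    if np.any(fst <= 0) or np.any(fst >= 1):
        raise ValueError("each fst must lie strictly in (0, 1)")
    n_haps_per_pop = [n_haps] * n_pops if np.isscalar(n_haps) else list(n_haps)
    if any(h % 2 for h in n_haps_per_pop):
        raise ValueError("n_haps must be even (diploid panels)")
    rng = np.random.default_rng(seed)
    snps = _linear_snps(n_snps, n_chrom, morgans_per_chrom)
    pi = rng.uniform(maf_floor, 1 - maf_floor, size=n_snps)
    labels = labels or [f"pop{i}" for i in range(n_pops)]
    panels = []
    for i in range(n_pops):
        F = fst[i]
        p = rng.beta(pi * (1 - F) / F, (1 - pi) * (1 - F) / F)
        haps = (rng.random((n_haps_per_pop[i], n_snps)) < p).astype(np.int8)
        panels.append(GenotypePanel.from_haplotypes(labels[i], snps, haps))
    return panels


def _recombine(h0, h1, gpos, chrom_ids, total_morgans, rng):
    """One gamete from a parent's haplotype pair; crossovers Poisson(1/Morgan)."""
    n_x = rng.poisson(total_morgans)
    start = rng.integers(2)
    if n_x == 0:
        return (h0 if start == 0 else h1).copy()
    xpos = np.sort(rng.uniform(0, total_morgans, n_x))
    # map SNPs to cumulative genetic coordinate (chromosomes laid end to end)
    phase = (np.searchsorted(xpos, _cumpos(gpos, chrom_ids)) + start) % 2
    return np.where(phase == 0, h0, h1).astype(np.int8)


def _cumpos(gpos, chrom_ids):
    # cumulative genetic position across chromosomes laid end to end
    cum = gpos.copy()
    offset = 0.0
    for c in np.unique(chrom_ids):
        m = chrom_ids == c
        cum[m] = gpos[m] - gpos[m].min() + offset
        offset = cum[m].max() + 0.5  # half-Morgan spacer decouples chromosomes
    return cum


def expand_population(
    panel: GenotypePanel, params: ExpansionParams, n_out_haps: int | None = None
) -> GenotypePanel:
    """Wright-Fisher expansion of a phased panel over ``t`` generations.

    Each generation g has N(g) = N0 (N1/N0)^(g/t) diploids; every offspring
    haplotype is a recombinant gamete of a uniformly chosen parent, with
    allele flips at rate ``mu`` per site. With t = 0 the output is a seeded
    resample of the input haplotypes.
    """
    if not panel.phased or panel.haplotypes is None:
        raise PanelError("expand_population requires a phased panel")
    rng = np.random.default_rng(params.seed)
    gpos, chrom_ids = panel.gpos, panel.chroms
    total_m = 0.0
    for c in np.unique(chrom_ids):
        g = gpos[chrom_ids == c]
        total_m += g.max() - g.min()
    haps = panel.haplotypes
    if params.t == 0:
        n_out = n_out_haps or haps.shape[0]
        sel = rng.integers(haps.shape[0], size=n_out)
        return GenotypePanel.from_haplotypes(panel.pop_label, panel.snps, haps[sel])
    sizes = [
        max(1, round(params.N0 * (params.N1 / params.N0) ** (g / params.t)))
        for g in range(1, params.t + 1)
    ]
    for N in sizes:
        n_parents = haps.shape[0] // 2
        children = np.empty((2 * N, haps.shape[1]), dtype=np.int8)
        for i in range(2 * N):
            pa = rng.integers(n_parents)
            children[i] = _recombine(haps[2 * pa], haps[2 * pa + 1], gpos, chrom_ids, total_m, rng)
        if params.mu > 0:
            flips = rng.random(children.shape) < params.mu
            children[flips] = 1 - children[flips]
        haps = children
    n_out = n_out_haps or haps.shape[0]
    if n_out > haps.shape[0]:
        raise ValueError(
            f"requested {n_out} haplotypes but the final generation has {haps.shape[0]}"
        )
    sel = rng.permutation(haps.shape[0])[:n_out]
    return GenotypePanel.from_haplotypes(panel.pop_label, panel.snps, haps[sel])


def simulate_admixed(
    sources: list[GenotypePanel],
    proportions,
    n_ind: int,
    generations: int,
    seed: int = 0,
    pop_label: str = "admixed",
) -> AdmixedCohort:
    """Continuous-gene-flow admixture with true local-ancestry tracking.

    Each of the 2*n_ind haplotypes is a Markov chain along every chromosome:
    initial ancestry drawn from ``proportions``; between adjacent SNPs at
    genetic distance d an ancestry re-sampling event occurs with probability
    1 - exp(-g d) (the g-generation recombination-break model), after which
    the source is drawn afresh from ``proportions``. Within a segment the
    alleles are copied from one uniformly drawn donor haplotype of the
    segment's source (with replacement across segments).
    """
    proportions = np.asarray(proportions, float)
    if np.any(proportions < 0) or abs(proportions.sum() - 1) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")
    if len(sources) != len(proportions):
        raise ValueError("one proportion per source required")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    snp_ids = sources[0].snp_ids
    for s in sources[1:]:
        if s.snp_ids != snp_ids:
            raise PanelError("sources must share harmonized SNP lists")
    for s in sources:
        if not s.phased or s.haplotypes is None:
            raise PanelError(f"source {s.pop_label} must be phased")

    rng = np.random.default_rng(seed)
    m = len(snp_ids)
    H = 2 * n_ind
    gpos, chrom_ids = sources[0].gpos, sources[0].chroms
    # forced segment break at every chromosome start
    new_chrom = np.zeros(m, bool)
    new_chrom[0] = True
    new_chrom[1:] = chrom_ids[1:] != chrom_ids[:-1]
    gaps = np.diff(gpos)
    p_switch = 1.0 - np.exp(-generations * gaps)
    p_switch = np.where(new_chrom[1:], 1.0, p_switch)

    breaks = np.empty((H, m), dtype=bool)
    breaks[:, 0] = True
    breaks[:, 1:] = rng.random((H, m - 1)) < p_switch
    seg_id = np.cumsum(breaks, axis=1, dtype=np.int32) - 1  # per-hap segment index
    seg_offsets = np.concatenate([[0], np.cumsum(seg_id[:, -1] + 1)])[:-1]
    flat_seg = (seg_id + seg_offsets[:, None]).ravel()
    n_segs = int(flat_seg[-1]) + 1

    seg_source = rng.choice(len(sources), size=n_segs, p=proportions)
    local_anc = seg_source[flat_seg].reshape(H, m).astype(np.uint8)
    seg_donor = np.empty(n_segs, dtype=np.int64)
    for si, s in enumerate(sources):
        msk = seg_source == si
        seg_donor[msk] = rng.integers(s.haplotypes.shape[0], size=msk.sum())
    donor_flat = seg_donor[flat_seg].reshape(H, m)

    haps = np.empty((H, m), dtype=np.int8)
    col = np.broadcast_to(np.arange(m), (H, m))
    for si, s in enumerate(sources):
        msk = local_anc == si
        haps[msk] = s.haplotypes[donor_flat[msk], col[msk]]

    panel = GenotypePanel.from_haplotypes(pop_label, sources[0].snps, haps)
    return AdmixedCohort(
        panel, local_anc, proportions, generations, [s.pop_label for s in sources], seed
    )


def true_global_proportions(cohort: AdmixedCohort) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual and cohort-mean true ancestry fractions.

    Fractions are the share of haplotype-SNP slots assigned to each source;
    each individual's vector sums to 1 exactly.
    """
    la = cohort.local_ancestry
    n_src = len(cohort.proportions)
    H, m = la.shape
    counts = np.stack([(la == s).sum(axis=1) for s in range(n_src)], axis=1)
    per_ind = (counts[0::2] + counts[1::2]) / (2.0 * m)
    return per_ind, per_ind.mean(axis=0)


def mask_genotypes(
    panel: GenotypePanel, snp_ids=None, fraction: float | None = None, seed: int = 0
) -> tuple[GenotypePanel, dict[str, np.ndarray]]:
    """Set chosen SNPs' genotypes to missing, keeping a truth table.

    ``snp_ids`` selects SNPs explicitly; alternatively ``fraction`` masks a
    seeded uniform subset. Masking every SNP is refused. The truth table maps
    SNP id -> original dosage column, for concordance scoring of an external
    imputation via :func:`imputation_concordance`.
    """
    all_ids = panel.snp_ids
    if snp_ids is not None:
        missing_targets = set(snp_ids) - set(all_ids)
        if missing_targets:
            raise PanelError(f"mask targets absent from panel: {sorted(missing_targets)[:5]}")
        mask_idx = [i for i, s in enumerate(all_ids) if s in set(snp_ids)]
    elif fraction is not None:
        if not 0 <= fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")
        rng = np.random.default_rng(seed)
        k = int(round(fraction * len(all_ids)))
        mask_idx = sorted(rng.choice(len(all_ids), size=k, replace=False).tolist())
    else:
        raise ValueError("provide snp_ids or fraction")
    if len(mask_idx) == panel.n_snps and panel.n_snps > 0:
        raise ValueError("refusing to mask every SNP")
    geno = panel.genotypes.copy()
    truth = {all_ids[i]: panel.genotypes[:, i].copy() for i in mask_idx}
    for i in mask_idx:
        geno[:, i] = MISSING
    haps = None
    if panel.haplotypes is not None:
        haps = panel.haplotypes.copy()
        for i in mask_idx:
            haps[:, i] = 0
    masked = GenotypePanel(
        panel.pop_label, list(panel.snps), geno, list(panel.sample_ids), False, None
    )
    return masked, truth


def imputation_concordance(imputed: GenotypePanel, truth: dict[str, np.ndarray]) -> float:
    """Fraction of masked genotype entries restored to their original dosage."""
    ids = {s: j for j, s in enumerate(imputed.snp_ids)}
    n_ok = n_tot = 0
    for snp_id, col in truth.items():
        if snp_id not in ids:
            raise PanelError(f"imputed panel lacks masked SNP {snp_id}")
        obs = imputed.genotypes[:, ids[snp_id]]
        n_ok += int((obs == col).sum())
        n_tot += len(col)
    return n_ok / n_tot if n_tot else np.nan
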