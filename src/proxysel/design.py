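"""The five-way admixture study design, packaged as reusable conditions.

One scenario drives every demonstration in this package: a cohort admixed
over 100 generations of continuous gene flow from five differentiated
sources — analogs of a European, a Bantu-speaking African, a Khoesan, an
East-Asian and a South-Asian population — in proportions
(0.20, 0.32, 0.29, 0.08, 0.11). Sources are Balding-Nichols panels with
per-population divergence (FST from the shared ancestral pool) of
(0.05, 0.08, 0.15, 0.07, 0.06): moderate for the out-of-Africa analogs and
largest for the Khoesan analog, mirroring the deep differentiation of
Khoesan groups. Donor haplotypes used to build the cohort are disjoint from
the reference samples used to evaluate the selection methods, so that
evaluation never reuses the exact haplotypes that generated the cohort.

Pool construction for proxy-selection experiments places each true source
in a pool with decoy populations drawn from the same ancestral frequencies
at strictly greater divergence (default +0.03, +0.06, +0.09), i.e. related
but worse proxies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .admix_sim import AdmixedCohort, simulate_admixed, synth_ancestral_panels
from .panel_io import GenotypePanel

SOURCE_LABELS = ("european", "african_bantu", "khoesan", "east_asian", "south_asian")
DEFAULT_PROPORTIONS = (0.20, 0.32, 0.29, 0.08, 0.11)
DEFAULT_SOURCE_FST = (0.05, 0.08, 0.15, 0.07, 0.06)
DEFAULT_GENERATIONS = 100


def _split(panel: GenotypePanel, n_first_haps: int) -> tuple[GenotypePanel, GenotypePanel]:
    n_first = n_first_haps // 2
    a = panel.subset_samples(np.arange(n_first))
    b = panel.subset_samples(np.arange(n_first, panel.n_samples))
    return a, b


@dataclass
class FiveWayStudy:
    """Materialized study conditions: donors, held-out references, pools, cohort."""

    donor_panels: list[GenotypePanel]
    ref_panels: list[GenotypePanel]
    pools: dict[str, list[GenotypePanel]]
    proportions: np.ndarray
    generations: int
    cohort: AdmixedCohort | None = None


def five_way_sources(
    n_snps: int = 10_000,
    n_donor_haps: int = 600,
    n_ref_haps: int = 400,
    seed: int = 0,
    fst=DEFAULT_SOURCE_FST,
    morgans_per_chrom: float = 1.0,
    n_chrom: int = 1,
    maf_floor: float = 0.05,
) -> tuple[list[GenotypePanel], list[GenotypePanel]]:
    """Five Balding-Nichols source panels, split into donor and reference halves."""
    panels = synth_ancestral_panels(
        5,
        list(fst),
        n_snps,
        n_donor_haps + n_ref_haps,
        maf_floor=maf_floor,
        seed=seed,
        morgans_per_chrom=morgans_per_chrom,
        n_chrom=n_chrom,
        labels=list(SOURCE_LABELS),
    )
    donors, refs = [], []
    for p in panels:
        d, r = _split(p, n_donor_haps)
        donors.append(d)
        refs.append(r)
    return donors, refs


def five_way_study(
    n_snps: int = 10_000,
    n_ind: int = 750,
    n_donor_haps: int = 600,
    n_ref_haps: int = 400,
    generations: int = DEFAULT_GENERATIONS,
    proportions=DEFAULT_PROPORTIONS,
    seed: int = 0,
    fst=DEFAULT_SOURCE_FST,
    n_decoys: int = 0,
    decoy_fst_step: float = 0.03,
    n_decoy_haps: int = 200,
    morgans_per_chrom: float = 1.0,
    n_chrom: int = 1,
    simulate: bool = True,
) -> FiveWayStudy:
    """Generate the full design: sources, optional decoy pools, admixed cohort.

    With ``n_decoys`` > 0, each source's pool holds its held-out reference
    panel plus ``n_decoys`` decoys at divergence fst + step*(1..n_decoys),
    all drawn on the shared SNP list and ancestral frequencies.
    """
    fst = list(fst)
    all_fst = list(fst)
    all_haps = [n_donor_haps + n_ref_haps] * 5
    all_labels = list(SOURCE_LABELS)
    for i, lab in enumerate(SOURCE_LABELS):
        for k in range(1, n_decoys + 1):
            all_fst.append(min(fst[i] + decoy_fst_step * k, 0.95))
            all_haps.append(n_decoy_haps)
            all_labels.append(f"{lab}_decoy{k}")
    panels = synth_ancestral_panels(
        len(all_fst),
        all_fst,
        n_snps,
        all_haps,
        seed=seed,
        morgans_per_chrom=morgans_per_chrom,
        n_chrom=n_chrom,
        labels=all_labels,
    )
    donors, refs = [], []
    for p in panels[:5]:
        d, r = _split(p, n_donor_haps)
        donors.append(d)
        refs.append(r)
    pools: dict[str, list[GenotypePanel]] = {}
    if n_decoys:
        for i, lab in enumerate(SOURCE_LABELS):
            decs = [p for p in panels[5:] if p.pop_label.startswith(lab + "_decoy")]
            pools[lab] = [refs[i]] + decs
    cohort = None
    if simulate:
        cohort = simulate_admixed(
            donors, np.asarray(proportions, float), n_ind, generations, seed=seed + 1
        )
    return FiveWayStudy(donors, refs, pools, np.asarray(proportions, float), generations, cohort)
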