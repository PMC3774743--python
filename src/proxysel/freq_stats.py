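"""Allele frequencies, frequency differentiation and the f3 admixture test.

The f3 three-population statistic f3(T; A, B) averages
(p_T - p_A)(p_T - p_B) over SNPs, minus the target's heterozygosity
correction p_T(1-p_T)/(n_T-1) which removes the upward bias from finite
target sample size. A significantly negative value (z well below -3 by
block jackknife) is evidence that T is admixed between relatives of A and B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .panel_io import MISSING, GenotypePanel, PanelError


@dataclass
class FrequencyTable:
    """Per-SNP alt-allele frequency and observed allele count for one population.

    ``alt_freq`` is NaN at SNPs with no genotyped sample (allele_count 0).
    """

    pop_label: str
    snp_ids: list[str]
    alt_freq: np.ndarray
    allele_count: np.ndarray
    gpos: np.ndarray | None = None
    chroms: np.ndarray | None = None

    def __post_init__(self):
        self.alt_freq = np.asarray(self.alt_freq, dtype=float)
        self.allele_count = np.asarray(self.allele_count, dtype=float)
        ok = ~np.isnan(self.alt_freq)
        if np.any((self.alt_freq[ok] < 0) | (self.alt_freq[ok] > 1)):
            raise ValueError("allele frequencies outside [0, 1]")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class F3Result:
    f3: float
    se: float
    z: float
    n_blocks: int
    n_snps: int


def allele_frequencies(panel: GenotypePanel) -> FrequencyTable:
    """Observed alt-allele frequency p and allele count n = 2 x genotyped samples."""
    if panel.n_snps == 0:
        raise PanelError("empty panel")
    g = panel.genotypes
    called = g != MISSING
    n = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, g, 0).sum(axis=0) / n
    p = np.where(n > 0, p, np.nan)
    return FrequencyTable(panel.pop_label, panel.snp_ids, p, n, panel.gpos, panel.chroms)


def freq_difference(popA: FrequencyTable, popB: FrequencyTable) -> np.ndarray:
    """Signed per-SNP frequency difference delta = p_A - p_B.

    SNPs with an undefined frequency in either table yield NaN (callers drop
    them); a warning reports how many.
    """
    if popA.snp_ids != popB.snp_ids:
        raise ValueError("frequency tables are not on identical SNP lists")
    delta = popA.alt_freq - popB.alt_freq
    n_bad = int(np.isnan(delta).sum())
    if n_bad:
        warnings.warn(f"{n_bad} SNPs dropped (undefined frequency)")
    return delta


def _f3_terms(target, pop1, pop2, correction):
    t = (target.alt_freq - pop1.alt_freq) * (target.alt_freq - pop2.alt_freq)
    if correction:
        nT = target.allele_count
        with np.errstate(invalid="ignore", divide="ignore"):
            t = t - target.alt_freq * (1 - target.alt_freq) / (nT - 1)
    return t


def block_jackknife(values: np.ndarray, block_size: int) -> tuple[float, float, int]:
    """Delete-one-block jackknife for the mean of ``values``.

    Blocks are contiguous runs of ``block_size`` entries (last block takes the
    remainder). Returns (mean, se, n_blocks).
    """
    values = np.asarray(values, float)
    values = values[~np.isnan(values)]
    m = len(values)
    n_blocks = m // block_size + (1 if m % block_size else 0)
    if n_blocks < 2:
        raise ValueError("jackknife undefined: fewer than 2 blocks")
    total = values.sum()
    theta = total / m
    loo = np.empty(n_blocks)
    for b in range(n_blocks):
        lo, hi = b * block_size, min((b + 1) * block_size, m)
        loo[b] = (total - values[lo:hi].sum()) / (m - (hi - lo))
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()))
    return float(theta), se, n_blocks


def f3_statistic(
    target: FrequencyTable,
    pop1: FrequencyTable,
    pop2: FrequencyTable,
    block_size_snps: int = 500,
    correction: bool = True,
) -> F3Result:
    """Patterson-style three-population test with block-jackknife SE."""
    for p in (pop1, pop2):
        if p.snp_ids != target.snp_ids:
            raise ValueError("frequency tables are not on identical SNP lists")
    terms = _f3_terms(target, pop1, pop2, correction)
    ok = ~np.isnan(terms)
    f3, se, n_blocks = block_jackknife(terms[ok], block_size_snps)
    z = f3 / se if se > 0 else np.nan
    return F3Result(f3, se, z, n_blocks, int(ok.sum()))
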