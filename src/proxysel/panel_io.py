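"""Genotype panel I/O, SNP harmonization across panels, and per-population QC.

Panels are sample x SNP matrices of alt-allele dosage {0, 1, 2} with a
dedicated missing sentinel (:data:`MISSING`, never 0 — 0 is a valid dosage).
Genetic positions are stored in Morgans internally; map files in the standard
PLINK dialect carry centimorgans and are converted on read.

Supported formats: PLINK text (.ped/.map), PLINK binary (.bed/.bim/.fam) and
VCF 4.x (GT field only, read through cyvcf2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import lgamma
from pathlib import Path

import numpy as np

MISSING: int = -1

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class PanelError(ValueError):
    """Malformed or inconsistent panel input."""


@dataclass(frozen=True)
class SnpRecord:
    """A single biallelic SNP with physical and genetic coordinates.

    ``gpos_morgans`` is the genetic position in Morgans (1 Morgan = 100 cM).
    ``pos_bp`` is 1-based, following PLINK/VCF convention.
    """

    chrom: str
    pos_bp: int
    id: str
    allele_ref: str
    allele_alt: str
    gpos_morgans: float

    def __post_init__(self):
        if self.pos_bp < 1:
            raise PanelError(f"SNP {self.id}: pos_bp must be >= 1")
        if self.allele_ref == self.allele_alt:
            raise PanelError(f"SNP {self.id}: ref and alt alleles are equal")


@dataclass
class GenotypePanel:
    """A labelled population sample of diploid genotypes.

    genotypes : (n_samples, n_snps) int8 array of alt-allele dosages with
        :data:`MISSING` for no-calls.
    haplotypes : optional (2*n_samples, n_snps) int8 array of phased alleles;
        rows 2i and 2i+1 are the two haplotypes of individual i and sum to
        the genotype at every non-missing entry.
    """

    pop_label: str
    snps: list[SnpRecord]
    genotypes: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    phased: bool = False
    haplotypes: np.ndarray | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != len(self.snps):
            raise PanelError(
                f"panel {self.pop_label}: genotype matrix shape "
                f"{self.genotypes.shape} inconsistent with {len(self.snps)} SNPs"
            )
        if not self.sample_ids:
            self.sample_ids = [f"{self.pop_label}_{i}" for i in range(self.n_samples)]
        if len(self.sample_ids) != self.n_samples:
            raise PanelError(f"panel {self.pop_label}: sample_ids length mismatch")
        if self.phased:
            if self.haplotypes is None:
                raise PanelError("phased panel requires haplotypes")
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (2 * self.n_samples, self.n_snps):
                raise PanelError("haplotype matrix shape mismatch")
            hsum = self.haplotypes[0::2] + self.haplotypes[1::2]
            ok = self.genotypes == MISSING
            if not np.array_equal(np.where(ok, hsum, self.genotypes), hsum) and not np.all(
                (hsum == self.genotypes) | ok
            ):
                raise PanelError("haplotype pairs do not sum to genotypes")

    @classmethod
    def from_haplotypes(cls, pop_label, snps, haplotypes, sample_ids=None):
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
        if haplotypes.shape[0] % 2:
            raise PanelError("haplotype count must be even (diploid pairs)")
        geno = (haplotypes[0::2] + haplotypes[1::2]).astype(np.int8)
        return cls(pop_label, list(snps), geno, sample_ids or [], True, haplotypes)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    @property
    def gpos(self) -> np.ndarray:
        return np.array([s.gpos_morgans for s in self.snps], dtype=float)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.snps])

    def subset_snps(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        snps = [self.snps[i] for i in idx]
        haps = self.haplotypes[:, idx] if self.haplotypes is not None else None
        return GenotypePanel(
            self.pop_label, snps, self.genotypes[:, idx], list(self.sample_ids), self.phased, haps
        )

    def subset_samples(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        haps = None
        if self.haplotypes is not None:
            hidx = np.repeat(2 * idx, 2) + np.tile([0, 1], len(idx))
            haps = self.haplotypes[hidx]
        return GenotypePanel(
            self.pop_label,
            list(self.snps),
            self.genotypes[idx],
            [self.sample_ids[i] for i in idx],
            self.phased,
            haps,
        )


def _sort_canonical(panel: GenotypePanel) -> GenotypePanel:
    def chromkey(c):
        try:
            return (0, int(c), "")
        except ValueError:
            return (1, 0, c)

    order = sorted(range(panel.n_snps), key=lambda i: (chromkey(panel.snps[i].chrom), panel.snps[i].pos_bp))
    if order == list(range(panel.n_snps)):
        return panel
    return panel.subset_snps(order)


def _check_dup_ids(snps):
    seen = set()
    for s in snps:
        if s.id in seen:
            raise PanelError(f"duplicated SNP id: {s.id}")
        seen.add(s.id)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_panel(path: str | Path, format: str, pop_label: str, phased: bool = False) -> GenotypePanel:
    """Read a genotype panel from disk.

    ``path`` is the fileset prefix for PLINK dialects (``prefix.ped`` /
    ``prefix.map`` or ``prefix.bed/.bim/.fam``) and the file path for VCF.
    SNPs are returned sorted by (chrom, pos_bp); genetic positions are
    converted from the map column's centimorgans to Morgans.

    For PLINK text input, which carries no ref/alt designation, the alt
    allele is defined as the minor allele (ties broken toward the
    lexicographically greater allele). VCF input carries no genetic map; a
    linear 1 cM/Mb map is attached (see :func:`attach_genetic_map`).

    With ``phased=True`` (plink-text only) the allele order within each
    genotype pair is interpreted as haplotype order — the dialect
    :func:`write_panel` emits for phased panels.
    """
    readers = {"plink-text": _read_ped, "plink-binary": _read_bed, "vcf": _read_vcf}
    if format not in readers:
        raise PanelError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    if phased and format != "plink-text":
        raise PanelError("phased reading is supported for plink-text only")
    if format == "plink-text":
        panel = _read_ped(Path(path), pop_label, phased=phased)
    else:
        panel = readers[format](Path(path), pop_label)
    _check_dup_ids(panel.snps)
    return _sort_canonical(panel)


def _read_map(path: Path) -> list[tuple[str, str, float, int]]:
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise PanelError(f"{path}:{ln}: expected 4 map columns, got {len(parts)}")
        chrom, snp_id, cm, bp = parts
        try:
            rows.append((chrom, snp_id, float(cm) / 100.0, int(bp)))
        except ValueError as e:
            raise PanelError(f"{path}:{ln}: {e}") from None
    return rows


def _read_ped(prefix: Path, pop_label: str, phased: bool = False) -> GenotypePanel:
    mp = _read_map(prefix.with_suffix(".map"))
    n_snps = len(mp)
    sample_ids: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    ped = prefix.with_suffix(".ped")
    for ln, line in enumerate(ped.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_snps:
            raise PanelError(
                f"{ped}:{ln}: expected {6 + 2 * n_snps} columns, got {len(parts)}"
            )
        sample_ids.append(parts[1])
        allele_rows.append([(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_snps)])

    # choose per-SNP ref/alt: alt = minor allele, ties -> lexicographically greater
    snps, geno_cols, hap_cols = [], [], []
    for j, (chrom, snp_id, gpos, bp) in enumerate(mp):
        counts: dict[str, int] = {}
        for row in allele_rows:
            for a in row[j]:
                if a not in ("0", "N"):
                    counts[a] = counts.get(a, 0) + 1
        alleles = sorted(counts, key=lambda a: (counts[a], tuple(-ord(ch) for ch in a)))
        if len(alleles) > 2:
            raise PanelError(f"SNP {snp_id}: more than two alleles observed")
        if not alleles:
            ref, alt = "A", "G"  # fully missing column; placeholder alleles
        elif len(alleles) == 1:
            ref, alt = alleles[0], ("G" if alleles[0] != "G" else "A")
        else:
            alt, ref = alleles[0], alleles[1]
        snps.append(SnpRecord(chrom, bp, snp_id, ref, alt, gpos))
        col = np.full(len(allele_rows), MISSING, dtype=np.int8)
        hcol = np.zeros((2 * len(allele_rows),), dtype=np.int8)
        for i, row in enumerate(allele_rows):
            a1, a2 = row[j]
            if a1 in ("0", "N") or a2 in ("0", "N"):
                continue
            col[i] = (a1 == alt) + (a2 == alt)
            hcol[2 * i] = a1 == alt
            hcol[2 * i + 1] = a2 == alt
        geno_cols.append(col)
        hap_cols.append(hcol)
    geno = np.column_stack(geno_cols) if geno_cols else np.zeros((len(sample_ids), 0), np.int8)
    if phased:
        if np.any(geno == MISSING):
            raise PanelError("phased reading requires complete genotypes")
        haps = np.column_stack(hap_cols) if hap_cols else np.zeros((2 * len(sample_ids), 0), np.int8)
        return GenotypePanel(pop_label, snps, geno, sample_ids, True, haps)
    return GenotypePanel(pop_label, snps, geno, sample_ids)


def _read_bim(path: Path) -> list[SnpRecord]:
    snps = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise PanelError(f"{path}:{ln}: expected 6 bim columns, got {len(parts)}")
        chrom, snp_id, cm, bp, a1, a2 = parts
        # PLINK convention: A1 is the counted (alt) allele, A2 the other (ref)
        snps.append(SnpRecord(chrom, int(bp), snp_id, a2, a1, float(cm) / 100.0))
    return snps


def _read_bed(prefix: Path, pop_label: str) -> GenotypePanel:
    snps = _read_bim(prefix.with_suffix(".bim"))
    fam_lines = [l.split() for l in prefix.with_suffix(".fam").read_text().splitlines() if l.strip()]
    sample_ids = [l[1] for l in fam_lines]
    n, m = len(sample_ids), len(snps)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != b"\x6c\x1b\x01":
        raise PanelError(f"{prefix}.bed: bad magic or not SNP-major")
    bytes_per_snp = (n + 3) // 4
    if len(raw) != 3 + bytes_per_snp * m:
        raise PanelError(f"{prefix}.bed: size inconsistent with {n} samples x {m} SNPs")
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample-within-byte little-endian
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    # 00 -> hom A1 (dosage 2), 10 -> het, 11 -> hom A2 (0), 01 -> missing
    lut = np.array([2, MISSING, 1, 0], dtype=np.int8)
    geno = lut[codes].T
    return GenotypePanel(pop_label, snps, geno, sample_ids)


def _read_vcf(path: Path, pop_label: str) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    snps, cols = [], []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue  # biallelic SNPs only
        snps.append(SnpRecord(str(v.CHROM), v.POS, v.ID or f"{v.CHROM}:{v.POS}", v.REF, v.ALT[0], 0.0))
        g = v.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g[g == 3] = MISSING
        cols.append(g)
    geno = np.column_stack(cols) if cols else np.zeros((len(sample_ids), 0), np.int8)
    panel = GenotypePanel(pop_label, snps, geno, sample_ids)
    return attach_genetic_map(panel, morgans_per_bp=1e-8)


def attach_genetic_map(panel: GenotypePanel, morgans_per_bp: float = 1e-8) -> GenotypePanel:
    """Attach a linear genetic map (default 1 cM/Mb) derived from bp positions."""
    snps = [replace(s, gpos_morgans=s.pos_bp * morgans_per_bp) for s in panel.snps]
    return GenotypePanel(
        panel.pop_label, snps, panel.genotypes, list(panel.sample_ids), panel.phased, panel.haplotypes
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_panel(panel: GenotypePanel, path: str | Path, format: str) -> None:
    """Write a panel as PLINK text, PLINK binary or (sites-only GT) VCF."""
    writers = {"plink-text": _write_ped, "plink-binary": _write_bed, "vcf": _write_vcf}
    if format not in writers:
        raise PanelError(f"unknown format {format!r}")
    writers[format](panel, Path(path))


def _map_lines(panel):
    return [
        f"{s.chrom}\t{s.id}\t{s.gpos_morgans * 100.0:.10g}\t{s.pos_bp}" for s in panel.snps
    ]


def _write_ped(panel: GenotypePanel, prefix: Path) -> None:
    prefix.with_suffix(".map").write_text("\n".join(_map_lines(panel)) + "\n")
    lines = []
    for i, sid in enumerate(panel.sample_ids):
        fields = [panel.pop_label, sid, "0", "0", "0", "-9"]
        for j, s in enumerate(panel.snps):
            g = panel.genotypes[i, j]
            if g == MISSING:
                fields += ["0", "0"]
            elif panel.phased:
                # allele order encodes haplotype order (phase-preserving dialect)
                pair = (panel.haplotypes[2 * i, j], panel.haplotypes[2 * i + 1, j])
                fields += [s.allele_alt if a else s.allele_ref for a in pair]
            else:
                fields += [s.allele_alt] * g + [s.allele_ref] * (2 - g)
        lines.append(" ".join(fields))
    prefix.with_suffix(".ped").write_text("\n".join(lines) + "\n")


def _write_bed(panel: GenotypePanel, prefix: Path) -> None:
    bim = [
        f"{s.chrom}\t{s.id}\t{s.gpos_morgans * 100.0:.10g}\t{s.pos_bp}\t{s.allele_alt}\t{s.allele_ref}"
        for s in panel.snps
    ]
    prefix.with_suffix(".bim").write_text("\n".join(bim) + "\n")
    fam = [f"{panel.pop_label} {sid} 0 0 0 -9" for sid in panel.sample_ids]
    prefix.with_suffix(".fam").write_text("\n".join(fam) + "\n")
    n, m = panel.n_samples, panel.n_snps
    inv = np.array([3, 2, 0], dtype=np.uint8)  # dosage -> 2-bit code; missing handled below
    codes = np.where(panel.genotypes == MISSING, 1, inv[np.clip(panel.genotypes, 0, 2)]).astype(np.uint8)
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.full((pad, m), 3, np.uint8)], axis=0)
    codes = codes.T.reshape(m, -1, 4)
    packed = (codes[:, :, 0] | codes[:, :, 1] << 2 | codes[:, :, 2] << 4 | codes[:, :, 3] << 6).astype(np.uint8)
    prefix.with_suffix(".bed").write_bytes(b"\x6c\x1b\x01" + packed.tobytes())


def _write_vcf(panel: GenotypePanel, path: Path) -> None:
    out = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    out.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.sample_ids))
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j, s in enumerate(panel.snps):
        gts = "\t".join(gt_code[int(g)] for g in panel.genotypes[:, j])
        out.append(f"{s.chrom}\t{s.pos_bp}\t{s.id}\t{s.allele_ref}\t{s.allele_alt}\t.\t.\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _is_ambiguous(a: str, b: str) -> bool:
    return {a, b} in ({"A", "T"}, {"C", "G"})


def intersect_panels(panels: list[GenotypePanel]) -> list[GenotypePanel]:
    """Reduce panels to their shared SNPs and harmonize allele coding.

    After harmonization every panel carries an identical ordered SNP list
    and ``allele_alt`` designates the same physical allele everywhere; a
    panel whose coding was swapped relative to the first panel has its
    dosages flipped x -> 2-x (so alt-allele frequency p -> 1-p). Alleles
    recorded on the opposite strand are complemented, except that
    strand-ambiguous A/T and C/G sites with disagreeing alleles are
    rejected — a silent flip there would corrupt every downstream frequency
    difference.
    """
    if len(panels) < 2:
        raise PanelError("intersect_panels requires at least two panels")
    shared = set(panels[0].snp_ids)
    for p in panels[1:]:
        shared &= set(p.snp_ids)
    if not shared:
        raise PanelError("empty intersection: no SNP ids shared by all panels")

    ref_panel = panels[0]
    keep = [i for i, s in enumerate(ref_panel.snps) if s.id in shared]
    anchor = ref_panel.subset_snps(keep)
    anchor_by_id = {s.id: s for s in anchor.snps}
    order = [s.id for s in anchor.snps]

    out = [anchor]
    for p in panels[1:]:
        pos = {s.id: i for i, s in enumerate(p.snps)}
        idx = [pos[i] for i in order]
        sub = p.subset_snps(idx)
        geno = sub.genotypes.copy()
        haps = sub.haplotypes.copy() if sub.haplotypes is not None else None
        new_snps, offenders = [], []
        for j, s in enumerate(sub.snps):
            a = anchor_by_id[s.id]
            pair = (s.allele_ref, s.allele_alt)
            target = (a.allele_ref, a.allele_alt)
            flip = False
            if pair == target:
                pass
            elif _is_ambiguous(*pair) or _is_ambiguous(*target):
                # A/T and C/G sites: a swap is indistinguishable from a
                # strand flip, so any disagreement is rejected
                offenders.append(s.id)
                continue
            elif pair == (target[1], target[0]):
                flip = True
            elif (_COMPLEMENT.get(pair[0]), _COMPLEMENT.get(pair[1])) == target:
                pass  # opposite strand, same orientation
            elif (_COMPLEMENT.get(pair[1]), _COMPLEMENT.get(pair[0])) == target:
                flip = True
            else:
                raise PanelError(
                    f"SNP {s.id}: alleles {pair} irreconcilable with {target}"
                )
            if flip:
                mask = geno[:, j] != MISSING
                geno[mask, j] = 2 - geno[mask, j]
                if haps is not None:
                    haps[:, j] = 1 - haps[:, j]
            new_snps.append(a)
        if offenders:
            raise PanelError(
                "strand-ambiguous allele mismatch at: " + ", ".join(offenders)
            )
        out.append(
            GenotypePanel(p.pop_label, new_snps, geno, list(sub.sample_ids), sub.phased, haps)
        )
    return out


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    pop_label: str
    n_snps_in: int
    n_removed_hwe: int
    n_removed_callrate: int
    n_snps_out: int
    hwe_p_max: float
    call_rate_min: float


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact test.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities of configurations no more probable
    than the observed one (Wigginton-style mid-tail-free exact test).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise PanelError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise PanelError("no genotyped samples")
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n_hom_ref + n_het
    rare = min(n_alt, n_ref)
    obs_het = n_het

    def logprob(h):
        # P(het = h | n, allele counts), unnormalized by the common allele term
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            lgamma(n + 1) - lgamma(hom_rare + 1) - lgamma(h + 1) - lgamma(hom_common + 1)
            + h * np.log(2.0)
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = np.array([logprob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[list(hets).index(obs_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(
    panel: GenotypePanel, hwe_p_max: float = 1e-6, call_rate_min: float = 0.95
) -> tuple[GenotypePanel, QcReport]:
    """Drop SNPs failing the HWE exact test or the call-rate threshold.

    Applied to one population at a time; each removed SNP is counted once,
    under the HWE cause if it fails both filters.
    """
    if panel.n_snps == 0:
        raise PanelError("empty panel")
    g = panel.genotypes
    called = g != MISSING
    call_rate = called.mean(axis=0)
    n_hom_ref = ((g == 0) & called).sum(axis=0)
    n_het = (g == 1).sum(axis=0)
    n_hom_alt = (g == 2).sum(axis=0)
    fail_hwe = np.zeros(panel.n_snps, bool)
    for j in range(panel.n_snps):
        total = n_hom_ref[j] + n_het[j] + n_hom_alt[j]
        if total == 0:
            continue
        if hwe_exact_test(int(n_hom_ref[j]), int(n_het[j]), int(n_hom_alt[j])) < hwe_p_max:
            fail_hwe[j] = True
    fail_cr = (call_rate < call_rate_min) & ~fail_hwe
    keep = ~(fail_hwe | fail_cr)
    report = QcReport(
        panel.pop_label,
        panel.n_snps,
        int(fail_hwe.sum()),
        int(fail_cr.sum()),
        int(keep.sum()),
        hwe_p_max,
        call_rate_min,
    )
    if not keep.any():
        warnings.warn(f"qc_filter removed every SNP in panel {panel.pop_label}")
    return panel.subset_snps(np.where(keep)[0]), report
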