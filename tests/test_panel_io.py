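"""Panel I/O, allele harmonization and QC filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import proxysel as px
from proxysel.panel_io import _read_map

from oracles import hwe_exact_oracle


@pytest.mark.parametrize("fmt", ["plink-text", "plink-binary", "vcf"])
def test_write_read_round_trip(toy_panel, tmp_path, fmt):
    """Writing then reading a panel reproduces genotypes and metadata."""
    target = tmp_path / ("panel.vcf" if fmt == "vcf" else "panel")
    px.write_panel(toy_panel, target, fmt)
    back = px.read_panel(target, fmt, "toy")
    assert np.array_equal(back.genotypes, toy_panel.genotypes)
    assert back.snp_ids == toy_panel.snp_ids
    assert [s.pos_bp for s in back.snps] == [s.pos_bp for s in toy_panel.snps]
    assert [(s.allele_ref, s.allele_alt) for s in back.snps] == [
        (s.allele_ref, s.allele_alt) for s in toy_panel.snps
    ]
    if fmt != "vcf":  # VCF carries no genetic map; a linear one is attached
        assert np.allclose(back.gpos, toy_panel.gpos)


def test_phased_round_trip_preserves_haplotypes(tmp_path):
    """The text dialect's allele order carries phase through write/read."""
    (panel,) = px.synth_ancestral_panels(1, [0.1], 60, 20, seed=33)
    px.write_panel(panel, tmp_path / "ph", "plink-text")
    back = px.read_panel(tmp_path / "ph", "plink-text", "p", phased=True)
    # orientation may flip per SNP (minor-alt convention); compare genotype
    # sums and within-pair order, which are orientation-invariant
    assert back.phased
    hsum = back.haplotypes[0::2] + back.haplotypes[1::2]
    assert np.array_equal(hsum, back.genotypes)
    flip = np.array(
        [b.allele_alt != a.allele_alt for a, b in zip(panel.snps, back.snps)]
    )
    expect = np.where(flip, 1 - panel.haplotypes, panel.haplotypes)
    assert np.array_equal(back.haplotypes, expect)


def test_map_centimorgans_converted_to_morgans(tmp_path):
    (tmp_path / "x.map").write_text("1 rs1 12.5 500\n")
    rows = _read_map(tmp_path / "x.map")
    assert rows[0][2] == pytest.approx(0.125)


def test_malformed_ped_column_count_raises(toy_panel, tmp_path):
    px.write_panel(toy_panel, tmp_path / "p", "plink-text")
    ped = tmp_path / "p.ped"
    ped.write_text(ped.read_text().rstrip("\n") + " A\n")  # one extra column
    with pytest.raises(px.PanelError, match="columns"):
        px.read_panel(tmp_path / "p", "plink-text", "toy")


def test_duplicate_snp_id_raises(toy_panel, tmp_path):
    px.write_panel(toy_panel, tmp_path / "p", "plink-binary")
    bim = tmp_path / "p.bim"
    lines = bim.read_text().splitlines()
    lines[1] = lines[0]  # duplicate the first SNP id
    bim.write_text("\n".join(lines) + "\n")
    with pytest.raises(px.PanelError, match="duplicated SNP id"):
        px.read_panel(tmp_path / "p", "plink-binary", "toy")


class TestIntersect:
    def _panel(self, label, snps, geno):
        return px.GenotypePanel(label, snps, np.asarray(geno, np.int8))

    def test_identical_snp_sets_unchanged(self, toy_panel):
        other = px.GenotypePanel("b", list(toy_panel.snps), toy_panel.genotypes.copy())
        out = px.intersect_panels([toy_panel, other])
        for p in out:
            assert p.snp_ids == toy_panel.snp_ids
            assert np.array_equal(p.genotypes, toy_panel.genotypes)

    def test_disjoint_ids_error(self):
        s1 = [px.SnpRecord("1", 1, "a", "A", "G", 0.0)]
        s2 = [px.SnpRecord("1", 1, "b", "A", "G", 0.0)]
        p1 = self._panel("x", s1, [[0], [1]])
        p2 = self._panel("y", s2, [[0], [1]])
        with pytest.raises(px.PanelError, match="empty intersection"):
            px.intersect_panels([p1, p2])

    def test_swapped_alleles_flip_dosage_and_frequency(self):
        """ref/alt G/A vs A/G: the flipped panel's alt frequency 0.3 becomes 0.7."""
        sA = [px.SnpRecord("1", 10, "rs1", "G", "A", 0.0)]
        sB = [px.SnpRecord("1", 10, "rs1", "A", "G", 0.0)]
        pA = self._panel("anchor", sA, [[1], [1], [0], [2], [1]])
        # alt(G) dosages with freq 0.3 over 5 diploids
        pB = self._panel("flipme", sB, [[1], [1], [1], [0], [0]])
        outA, outB = px.intersect_panels([pA, pB])
        fB = px.allele_frequencies(outB)
        assert fB.alt_freq[0] == pytest.approx(0.7)
        assert (outB.snps[0].allele_ref, outB.snps[0].allele_alt) == ("G", "A")

    def test_strand_ambiguous_mismatch_rejected(self):
        sA = [px.SnpRecord("1", 10, "rs1", "A", "T", 0.0)]
        sB = [px.SnpRecord("1", 10, "rs1", "T", "A", 0.0)]
        pA = self._panel("x", sA, [[1]])
        pB = self._panel("y", sB, [[1]])
        with pytest.raises(px.PanelError, match="strand-ambiguous.*rs1"):
            px.intersect_panels([pA, pB])

    def test_idempotent(self, bn_panels):
        once = px.intersect_panels(list(bn_panels))
        twice = px.intersect_panels(once)
        for a, b in zip(once, twice):
            assert a.snp_ids == b.snp_ids
            assert np.array_equal(a.genotypes, b.genotypes)

    def test_harmonization_conserves_minor_allele_count(self):
        """Dosage flipping relabels alleles but never changes which is minor."""
        rng = np.random.default_rng(5)
        snps_f = [px.SnpRecord("1", 10 * (j + 1), f"m{j}", "C", "A", 0.0) for j in range(8)]
        snps_s = [px.SnpRecord("1", 10 * (j + 1), f"m{j}", "A", "C", 0.0) for j in range(8)]
        g = rng.integers(0, 3, size=(12, 8)).astype(np.int8)
        pA = self._panel("a", snps_f, rng.integers(0, 3, size=(10, 8)))
        pB = self._panel("b", snps_s, g)
        _, outB = px.intersect_panels([pA, pB])
        for j in range(8):
            before = sorted([int((g[:, j] == 0).sum() * 2 + (g[:, j] == 1).sum()),
                             int((g[:, j] == 2).sum() * 2 + (g[:, j] == 1).sum())])
            gb = outB.genotypes[:, j]
            after = sorted([int((gb == 0).sum() * 2 + (gb == 1).sum()),
                            int((gb == 2).sum() * 2 + (gb == 1).sum())])
            assert before == after


class TestHweExact:
    def test_monomorphic_p_is_one(self):
        assert px.hwe_exact_test(0, 0, 50) == 1.0

    @pytest.mark.parametrize(
        "counts", [(1, 0, 1), (25, 50, 25), (3, 1, 4), (0, 5, 10), (7, 2, 0), (10, 10, 10)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert px.hwe_exact_test(*counts) == pytest.approx(hwe_exact_oracle(*counts), abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=0, max_value=20),
    )
    def test_oracle_agreement_all_small_totals(self, a, b, c):
        if a + b + c == 0:
            return
        assert px.hwe_exact_test(a, b, c) == pytest.approx(hwe_exact_oracle(a, b, c), abs=1e-12)

    def test_zero_total_raises(self):
        with pytest.raises(px.PanelError):
            px.hwe_exact_test(0, 0, 0)


class TestQcFilter:
    def test_clean_panel_fully_retained(self, bn_panels):
        filtered, rep = px.qc_filter(bn_panels[0])
        assert rep.n_snps_out == rep.n_snps_in
        assert filtered.n_snps == bn_panels[0].n_snps

    def test_call_rate_below_95_percent_removed(self):
        snps = [px.SnpRecord("1", j + 1, f"c{j}", "A", "G", 0.0) for j in range(2)]
        geno = np.ones((20, 2), dtype=np.int8)
        geno[:2, 0] = px.MISSING  # 18/20 called = 0.90
        panel = px.GenotypePanel("p", snps, geno)
        filtered, rep = px.qc_filter(panel)
        assert rep.n_removed_callrate == 1
        assert filtered.snp_ids == ["c1"]

    def test_extreme_hwe_failure_removed(self):
        # all-homozygote split: exact p far below 1e-6
        snps = [px.SnpRecord("1", j + 1, f"h{j}", "A", "G", 0.0) for j in range(2)]
        geno = np.zeros((100, 2), dtype=np.int8)
        geno[:50, 0] = 2  # 50 hom-ref / 0 het / 50 hom-alt
        geno[:, 1] = np.tile([0, 1, 1, 2], 25)  # near-HWE column
        panel = px.GenotypePanel("p", snps, geno)
        assert px.hwe_exact_test(50, 0, 50) < 1e-6
        filtered, rep = px.qc_filter(panel)
        assert rep.n_removed_hwe == 1
        assert filtered.snp_ids == ["h1"]

    def test_report_counts_each_snp_once(self):
        snps = [px.SnpRecord("1", j + 1, f"x{j}", "A", "G", 0.0) for j in range(1)]
        geno = np.zeros((100, 1), dtype=np.int8)
        geno[:40, 0] = 2
        geno[94:, 0] = px.MISSING  # fails call rate AND HWE
        panel = px.GenotypePanel("p", snps, geno)
        _, rep = px.qc_filter(panel)
        assert rep.n_removed_hwe + rep.n_removed_callrate == 1
        assert rep.n_snps_out == rep.n_snps_in - 1
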