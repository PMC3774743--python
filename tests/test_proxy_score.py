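"""Pairwise LD, the Fisher statistic and the proxy-ancestry score."""

import math

import numpy as np
import pytest
from scipy import stats

import proxysel as px
from proxysel.proxy_score import DegeneratePairingError

from oracles import permutation_slope_pvalue


def _panel_from_dosages(cols, label="p", spacing=0.001):
    cols = np.asarray(cols, np.int8)
    snps = [
        px.SnpRecord("1", 100 * (j + 1), f"s{j}", "A", "G", spacing * j)
        for j in range(cols.shape[1])
    ]
    return px.GenotypePanel(label, snps, cols)


def _freq_table(label, p, n=1000.0):
    p = np.asarray(p, float)
    return px.FrequencyTable(label, [f"s{j}" for j in range(len(p))], p, np.full(len(p), n))


class TestPairwiseLd:
    def test_duplicated_column_r2_one(self):
        col = np.array([0, 1, 2, 0, 1, 2])
        ld = px.pairwise_ld(_panel_from_dosages(np.column_stack([col, col])))
        assert ld.n_pairs == 1
        assert ld.r2[0] == pytest.approx(1.0)

    def test_orthogonal_columns_r2_zero(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([1, 1, 2, 0, 1, 1])  # constructed uncorrelated with a
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(0.0, abs=1e-12)
        ld = px.pairwise_ld(_panel_from_dosages(np.column_stack([a, b])))
        assert ld.r2[0] == pytest.approx(0.0, abs=1e-12)

    def test_six_sample_pair_matches_hand_calculation(self):
        a = [0, 1, 2, 0, 1, 2]
        b = [0, 2, 1, 0, 0, 2]
        ld = px.pairwise_ld(_panel_from_dosages(np.column_stack([a, b])))
        # plain-arithmetic Pearson correlation
        ma, mb = sum(a) / 6, sum(b) / 6
        cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
        va = sum((x - ma) ** 2 for x in a)
        vb = sum((y - mb) ** 2 for y in b)
        r_hand = cov / math.sqrt(va * vb)
        assert ld.r[0] == pytest.approx(r_hand, abs=1e-12)
        assert ld.r2[0] == pytest.approx(r_hand**2, abs=1e-12)

    def test_distance_threshold_and_chromosomes_respected(self, bn_panels):
        ld = px.pairwise_ld(bn_panels[0], max_dist_morgans=0.05)
        assert np.all(ld.dist_morgans < 0.05)
        assert np.all(ld.dist_morgans > 0)

    def test_zero_variance_snp_skipped(self):
        cols = np.column_stack([[0, 1, 2, 1], [1, 1, 1, 1], [2, 1, 0, 1]])
        ld = px.pairwise_ld(_panel_from_dosages(cols))
        assert ld.n_pairs_skipped == 2
        assert ld.n_pairs == 1

    def test_subsampling_is_seeded(self, bn_panels):
        ld1 = px.pairwise_ld(bn_panels[0], max_pairs=500, seed=9)
        ld2 = px.pairwise_ld(bn_panels[0], max_pairs=500, seed=9)
        assert np.array_equal(ld1.idx_j, ld2.idx_j)
        assert np.array_equal(ld1.r, ld2.r)


class TestFisherLd:
    def test_zero_at_zero(self):
        assert px.fisher_ld(0.0, 100) == 0.0

    def test_closed_form_value(self):
        assert px.fisher_ld(0.5, 103) == pytest.approx(math.atanh(0.5) * 10, abs=1e-12)

    def test_strictly_increasing_in_r(self):
        r = np.linspace(-0.99, 0.99, 199)
        d = px.fisher_ld(r, 50)
        assert np.all(np.diff(d) > 0)
        assert np.all(np.sign(d) == np.sign(r))

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError, match="transform undefined"):
            px.fisher_ld(1.0, 50)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            px.fisher_ld(0.5, 3)


class TestLdVsDeltaRegression:
    def _ld_fixture(self, n_pairs=50, seed=0):
        rng = np.random.default_rng(seed)
        m = n_pairs + 1
        idx_j = np.arange(n_pairs)
        idx_k = np.arange(1, n_pairs + 1)
        return m, px.LDTable(
            idx_j,
            idx_k,
            np.full(n_pairs, 0.01),
            np.zeros(n_pairs),
            np.zeros(n_pairs),
            rng.normal(size=n_pairs),
            np.full(n_pairs, 100),
        )

    def test_identical_references_degenerate(self):
        m, ld = self._ld_fixture()
        f = _freq_table("a", np.full(m, 0.4))
        with pytest.raises(DegeneratePairingError):
            px.ld_vs_delta_regression(ld, f, _freq_table("b", np.full(m, 0.4)))

    def test_perfect_positive_fit_tiny_p(self):
        m, ld = self._ld_fixture()
        rng = np.random.default_rng(1)
        pa = rng.uniform(0.1, 0.9, m)
        pb = rng.uniform(0.1, 0.9, m)
        fa, fb = _freq_table("a", pa), _freq_table("b", pb)
        delta = pa - pb
        ld.D = 3.0 * delta[ld.idx_j] * delta[ld.idx_k]
        slope, p = px.ld_vs_delta_regression(ld, fa, fb)
        assert slope == pytest.approx(3.0, abs=1e-10)
        assert p < 1e-10

    def test_matches_permutation_oracle(self):
        m, ld = self._ld_fixture(seed=2)
        rng = np.random.default_rng(3)
        pa = rng.uniform(0.1, 0.9, m)
        pb = rng.uniform(0.1, 0.9, m)
        delta = pa - pb
        x = delta[ld.idx_j] * delta[ld.idx_k]
        ld.D = 2.0 * x + rng.normal(scale=np.std(x) * 2, size=len(x))
        slope, p = px.ld_vs_delta_regression(ld, _freq_table("a", pa), _freq_table("b", pb))
        p_perm = permutation_slope_pvalue(x, ld.D, n_perm=10_000, seed=4)
        mc_err = 3 * math.sqrt(p_perm * (1 - p_perm) / 10_000) + 1 / 10_000
        assert abs(p - p_perm) <= mc_err + 0.005

    def test_too_few_pairs_raises(self):
        m, ld = self._ld_fixture(n_pairs=5)
        fa = _freq_table("a", np.linspace(0.1, 0.9, m))
        fb = _freq_table("b", np.linspace(0.9, 0.1, m))
        with pytest.raises(ValueError, match="fewer than 10"):
            px.ld_vs_delta_regression(ld, fa, fb)


@pytest.fixture(scope="module")
def toy_setup():
    panels = px.synth_ancestral_panels(
        5, [0.05, 0.08, 0.11, 0.14, 0.17], 800, 120, seed=21,
        labels=["src", "decoyA", "decoyB", "far", "far2"],
    )
    cohort = px.simulate_admixed([panels[0], panels[3]], [0.6, 0.4], 80, 50, seed=22)
    pools = {"main": panels[:3], "other": panels[3:]}
    return cohort, pools, panels


class TestProxyAncestryScores:

    def test_raw_score_matches_reaggregation_oracle(self, toy_setup):
        cohort, pools, panels = toy_setup
        ld = px.pairwise_ld(cohort.panel, seed=5)
        results = px.proxy_ancestry_scores(cohort.panel, pools, seed=5, ld=ld)
        freqs = {p.pop_label: px.allele_frequencies(p) for ps in pools.values() for p in ps}
        for res in results:
            ts = []
            for other in freqs:
                if other == res.pop_label:
                    continue
                _, p = px.ld_vs_delta_regression(ld, freqs[res.pop_label], freqs[other])
                ts.append(stats.norm.isf(p))
            assert res.n_pairings == len(ts)
            assert res.raw_score == pytest.approx(np.mean(ts), abs=1e-12)

    def test_invariant_under_sample_relabeling(self, toy_setup):
        cohort, pools, _ = toy_setup
        res1 = px.proxy_ancestry_scores(cohort.panel, pools, seed=5)
        shuffled = {
            name: [
                px.GenotypePanel(
                    p.pop_label,
                    list(p.snps),
                    p.genotypes[::-1].copy(),
                    list(reversed(p.sample_ids)),
                )
                for p in ps
            ]
            for name, ps in pools.items()
        }
        res2 = px.proxy_ancestry_scores(cohort.panel, shuffled, seed=5)
        for a, b in zip(res1, res2):
            assert a.pop_label == b.pop_label
            assert a.raw_score == pytest.approx(b.raw_score, abs=1e-10)

    def test_duplicate_decoy_adds_exactly_one_pairing(self, toy_setup):
        """A duplicated panel shifts each score by one extra pairing's mean term."""
        cohort, pools, panels = toy_setup
        ld = px.pairwise_ld(cohort.panel, seed=5)
        base = {r.pop_label: r for r in px.proxy_ancestry_scores(cohort.panel, pools, ld=ld)}
        dup = px.GenotypePanel(
            "decoyB_twin", list(panels[2].snps), panels[2].genotypes.copy()
        )
        pools_dup = {"main": pools["main"] + [dup], "other": pools["other"]}
        new = {r.pop_label: r for r in px.proxy_ancestry_scores(cohort.panel, pools_dup, ld=ld)}
        freqs = {p.pop_label: px.allele_frequencies(p) for ps in pools.values() for p in ps}
        for lab, res in base.items():
            k = res.n_pairings
            if lab == "decoyB":
                # its pairing with the twin is degenerate and skipped
                assert new[lab].raw_score == pytest.approx(res.raw_score, abs=1e-12)
                continue
            _, p = px.ld_vs_delta_regression(ld, freqs[lab], freqs["decoyB"])
            t_twin = stats.norm.isf(p)
            assert new[lab].raw_score == pytest.approx(
                (k * res.raw_score + t_twin) / (k + 1), abs=1e-10
            )

    def test_true_source_outranks_decoys(self, toy_setup):
        cohort, pools, _ = toy_setup
        res = px.proxy_ancestry_scores(cohort.panel, pools, seed=5)
        main = [r for r in res if r.pool == "main"]
        other = [r for r in res if r.pool == "other"]
        assert max(main, key=lambda r: r.raw_score).pop_label == "src"
        assert max(other, key=lambda r: r.raw_score).pop_label == "far"

    def test_single_candidate_pool_rejected(self, toy_setup):
        cohort, _, panels = toy_setup
        with pytest.raises(ValueError, match="single candidate"):
            px.proxy_ancestry_scores(cohort.panel, {"solo": [panels[0]]})

    def test_identical_candidates_all_degenerate(self, toy_setup):
        cohort, _, panels = toy_setup
        clones = [
            px.GenotypePanel(f"c{i}", list(panels[0].snps), panels[0].genotypes.copy())
            for i in range(3)
        ]
        with pytest.raises(DegeneratePairingError, match="all pairings degenerate"):
            px.proxy_ancestry_scores(cohort.panel, {"clones": clones})

    def test_pool_normalization_uses_other_members(self, toy_setup):
        cohort, pools, _ = toy_setup
        res = px.proxy_ancestry_scores(cohort.panel, pools, seed=5)
        main = {r.pop_label: r for r in res if r.pool == "main"}
        raws = {lab: r.raw_score for lab, r in main.items()}
        for lab, r in main.items():
            others = [v for o, v in raws.items() if o != lab]
            expect = (r.raw_score - np.mean(others)) / np.std(others, ddof=1)
            assert r.pscore_z == pytest.approx(expect, abs=1e-12)
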