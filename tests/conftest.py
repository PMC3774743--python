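import numpy as np
import pytest

import proxysel as px


@pytest.fixture(scope="session")
def bn_panels():
    """Three phased Balding-Nichols panels, 600 SNPs, 100 haplotypes each."""
    return px.synth_ancestral_panels(
        3, [0.05, 0.10, 0.20], n_snps=600, n_haps=100, seed=11, labels=["P1", "P2", "P3"]
    )


@pytest.fixture(scope="session")
def small_cohort(bn_panels):
    """60 diploids admixed (0.5, 0.3, 0.2) over 100 generations."""
    return px.simulate_admixed(bn_panels, [0.5, 0.3, 0.2], 60, 100, seed=12)


@pytest.fixture(scope="session")
def study():
    """Shared five-way study: 2,000 SNPs, 150 admixed diploids, 3 decoys per pool."""
    return px.five_way_study(
        n_snps=2000,
        n_ind=150,
        n_donor_haps=300,
        n_ref_haps=100,
        n_decoys=3,
        n_decoy_haps=100,
        seed=7,
    )


@pytest.fixture
def toy_panel():
    """Hand-sized panel: 4 samples x 5 SNPs with one missing call."""
    snps = [
        px.SnpRecord("1", 100 * (j + 1), f"s{j}", "A", "G", 0.001 * j) for j in range(5)
    ]
    # every column keeps the alt allele at or below 50% frequency, so the
    # text-PLINK reader's minor-alt convention round-trips orientation
    geno = np.array(
        [
            [0, 1, 2, 0, 1],
            [1, 0, 0, 1, 1],
            [2, 1, 0, px.MISSING, 0],
            [0, 2, 1, 1, 2],
        ],
        dtype=np.int8,
    )
    return px.GenotypePanel("toy", snps, geno)
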