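"""Enumerate one-panel-per-pool combinations and rank them by F.

With two candidates per pool (true source + one decoy), all 2^5 = 32
five-panel combinations are fitted; the combination of the five generating
panels should minimize the objective.
"""

import proxysel as px

study = px.five_way_study(
    n_snps=3000, n_ind=200, n_donor_haps=400, n_ref_haps=150,
    n_decoys=1, n_decoy_haps=150, seed=9,
)
adm = px.allele_frequencies(study.cohort.panel)
pools = {name: [px.allele_frequencies(p) for p in ps] for name, ps in study.pools.items()}
solutions = px.rank_combinations(adm, pools, block_size_snps=500)

print(f"{'rank':>4s}  {'F':>10s}  combination")
for i, s in enumerate(solutions[:5], 1):
    print(f"{i:4d}  {s.F:10.3e}  {' + '.join(s.labels)}")
print(f"... ({len(solutions)} combinations total)")
print("\nLower F = closer frequency match; the generating five-panel set should rank 1.")
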