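# proxysel

Selecting proxy ancestral reference panels for multi-way admixed populations.

Admixture mapping, local-ancestry inference and genotype imputation in an
admixed cohort all lean on reference panels standing in for the (usually
unsampled) true ancestral populations. When the cohort descends from three
or more sources — the motivating case is a Southern African population with
Khoesan, Bantu, European, South-Asian and East-Asian ancestry — choosing
the wrong panel from a pool of plausible relatives measurably corrupts
every downstream inference. `proxysel` implements two complementary
selectors that need only genotype data, together with the simulation
machinery to validate them end to end:

* **Mixture quadratic program.** Model the admixed population's alt-allele
  frequencies as a convex combination of L candidate panels and minimize

      F(α) = (1/M) Σ_j ( p̂_A,j − Σ_i α_i p̂_i,j )²,   α ≥ 0, Σ α_i = 1,

  with finite-sample debiasing (each squared observed frequency corrected
  by p̂(1−p̂)/(n−1)). F is quadratic in α, the simplex-constrained global
  minimum is found exactly by active-set enumeration, and one-panel-per-pool
  combinations are ranked by their minimized F with block-jackknife
  standard errors.
* **Proxy-ancestry score.** Admixture between differentiated sources
  creates LD whose expectation at a SNP pair (j, k) carries the cross term
  α(1−α)·δ_j·δ_k, δ being the between-source frequency difference. For each
  candidate i and every partner l, the Fisher-transformed short-range LD of
  the cohort, D = atanh(r)·√(n−3) for pairs closer than 0.2 Morgans, is
  regressed on δ_jδ_k; one-sided p-values are combined over pairings by
  t = Φ⁻¹(1−p) and averaged into a score S_i, normalized within each pool.
* **Supporting toolkit.** Patterson-style f3 three-population test with
  block-jackknife Z; expected and maximum expected admixture LD
  D_Z(α) = αD_X + (1−α)D_Y + α(1−α)δ_jδ_k in closed form; LD decay
  profiles; unbiased haplotype diversity H = n/(n−1)(1−Σp²); HWE exact-test
  and call-rate QC; PLINK text/binary and VCF I/O with allele
  harmonization; a Balding–Nichols panel generator, Wright–Fisher
  exponential-expansion, and a continuous-gene-flow admixture simulator
  that records true local ancestry.

## Worked example

`examples/` holds one short script per capability. The headline round trip
(`examples/01_simulate_and_fit_proportions.py`) simulates 200 diploids by
continuous gene flow over 100 generations from five synthetic sources in
proportions (0.20, 0.32, 0.29, 0.08, 0.11), then refits those proportions
from held-out reference samples:

```
source          generating  realized   fitted
european             0.200     0.198    0.201
african_bantu        0.320     0.320    0.317
khoesan              0.290     0.290    0.290
east_asian           0.080     0.083    0.086
south_asian          0.110     0.108    0.106

F = 9.924e-05  (SE 1.9e-05, 95% CI [6.147e-05, 1.370e-04])
```

`realized` is the cohort's true mean local ancestry from the simulator's
bookkeeping; `fitted` is the QP estimate from allele frequencies alone.
Other examples rank candidate pools by proxy-ancestry score (the
generating source tops each of the five pools), enumerate all
one-per-pool panel combinations (the generating combination minimizes F),
contrast f3 on true versus unrelated source pairs, and display the
admixture-LD and haplotype-diversity signatures that distinguish admixture
from a bottleneck.

A thin CLI mirrors the library:

```bash
proxysel simulate --sources eu,xh,kh,ch,gu --props 0.20,0.32,0.29,0.08,0.11 \
                  --n 750 --gens 100 --seed 42 --out run/
proxysel score    --admixed run/admixed --pool khoesan:kh,ju,bush --pool european:eu,ru,it \
                  --max-dist 0.2 --seed 7 --out scores/
proxysel optimize --admixed run/admixed --pool khoesan:kh,ju --pool european:eu,ru --out opt/
proxysel qc --panel eu --hwe-p 1e-6 --call-rate 0.95 --out qc/
```

Every run writes TSV tables plus a JSON manifest (parameters, seeds, input
checksums) for reproducibility.

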