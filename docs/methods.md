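# Methods

## Problem and model

An admixed cohort A descends from L unobserved ancestral populations; the
practical question is which of several sampled candidate panels best
stands in for each ancestor. Candidates are organised into pools (one pool
per suspected continental/regional source), and two selectors are run
against the cohort's genotypes.

### Mixture quadratic program

With p̂_A,j the observed alt-allele frequency of the cohort at SNP j and
p̂_i,j that of candidate panel i, the objective is the mean squared
frequency distance of the cohort from the convex combination of the
panels:

    F(α) = (1/M) Σ_j ( p̂_A,j − Σ_i α_i p̂_i,j )²  −  bias terms,

minimized over the probability simplex. Observed squared frequencies are
upwardly biased estimates of squared population frequencies, so with the
default debiasing each p̂² term is corrected by its sampling variance
p̂(1−p̂)/(n−1), where n is the observed allele count (2 × genotyped
samples): the constant term by the cohort's correction and each diagonal
Q_ii by panel i's. Cross terms need no correction because the panels are
independent samples. `bias_correction=False` reproduces the naive
least-squares objective. F is reported on the mean-per-SNP scale so that
values are comparable across panel subsets and jackknife deletions;
rankings are unaffected by this choice of scale.

Expanding the square gives F = α'Qα + c'α + const. The debiasing can push
Q slightly indefinite; eigenvalues below zero are clipped at zero (the
count is recorded on the solution) so the program stays convex, and the
reported F is always evaluated with the uncorrected coefficients. The
solver enumerates all 2^L − 1 support sets, solves each
equality-constrained KKT system directly, and keeps the best
primal-feasible candidate — exact, deterministic, and fast for the L ≤ 8
panels this problem meets; ranking ties break lexicographically by label.
Standard errors of F come from a delete-one-block jackknife over
contiguous SNP blocks (default 500 SNPs), refitting α for every deletion;
the 95% CI is F ± 1.96·SE. Combination ranking fits every element of the
Cartesian product of the pools (capped, default 20,000) and sorts
ascending by F.

### Proxy-ancestry score

Admixture in proportion α : 1−α between sources with frequency differences
δ_j, δ_k creates LD at a pair (j, k) whose cross term is α(1−α)δ_jδ_k. The
score turns this into a regression signal:

1. Pairwise LD of the cohort: Pearson correlation r of dosage vectors over
   complete samples, for all within-chromosome pairs closer than 0.2
   Morgans (the operative threshold; configurable). D = atanh(r)·√(n−3),
   the variance-stabilized Fisher statistic, keeps pairs with different
   complete-sample counts comparable; a plain-atanh variant is available.
   Pairs at |r| = 1 are retained with D evaluated just inside the open
   interval; zero-variance SNPs are skipped and counted. Above a cap
   (default 2×10⁵) a seeded uniform subsample of pairs is used.
2. For every ordered-free pairing (i, l) of reference populations across
   all pools, OLS of D on the signed product δ_jδ_k, with a one-sided
   p-value for a positive slope (the sign admixture theory predicts). A
   pairing whose δ product has no variance (e.g. duplicated panels) is
   degenerate and skipped.
3. Evidence combines as t_il = Φ⁻¹(1−p_il) (probit; small p → large t),
   S_i = mean over the pairings, SE by delete-one-partner jackknife.
4. Within each pool, the normalized score is
   z_i = (S_i − mean of S over the other pool members) / (sd over the
   other members). Both S and z are reported, named explicitly, since
   published presentations of such scores are ambiguous about which is
   which. No weighting beyond the δ_jδ_k product is applied.

### f3 three-population test

f3(T; A, B) averages (p̂_T−p̂_A)(p̂_T−p̂_B) over SNPs minus the target's
heterozygosity correction p̂_T(1−p̂_T)/(n_T−1); the unnormalized
(Patterson-style) form is used. SE is a delete-one-block jackknife over
contiguous SNP blocks (default 500; SNP-count blocks rather than cM blocks
so the statistic works on synthetic maps of any density). Z = f3/SE below
−3 is read as evidence of admixture. f3 serves as the comparison baseline
for the two selectors: it flags admixture for divergent major-contributor
pairs but is uninformative for minor contributors and for non-source
pairs, which is precisely the gap the selectors fill.

### Admixture LD and diversity

Expected admixture LD is the quadratic
D_Z(α) = αD_X + (1−α)D_Y + α(1−α)δ_jδ_k on a signed LD scale (the
quadratic form does not hold for r²; an r²-based variant exists for purely
descriptive comparisons). Its maximum over α ∈ [0,1] is at
α* = (D_X−D_Y+δ_jδ_k)/(2δ_jδ_k) when the parabola is concave
(δ_jδ_k > 0), else at the better boundary. LD decay profiles bin pairwise
r² by genetic distance; cohorts of unequal size should be subsampled to a
common size first (seeded, without replacement). Haplotype diversity uses
the unbiased estimator H = n/(n−1)(1−Σp²) over observed haplotype
frequencies in non-overlapping windows of phased SNPs (default 5 SNPs; a
window must be chosen because diversity of unbounded haplotypes is
degenerate, and 5 common SNPs approximate the scale of a small haplotype
block).

## Quality control and I/O

QC follows the standard per-population recipe: drop SNPs with HWE
exact-test p < 10⁻⁶ or call rate < 95%, each SNP counted once (HWE cause
first). The HWE test is the two-sided exact test — summing conditional
probabilities of heterozygote configurations no more probable than the
observed one — applied to each population separately. Genetic positions
are stored in Morgans (map files carry cM and are divided by 100) because
every distance threshold in the methods is stated in Morgans; coordinates
are 1-based and SNPs are canonicalized by (chrom, pos_bp). Missing
genotypes use a dedicated sentinel (−1), never 0, since 0 is a valid
dosage. Harmonization across panels flips swapped ref/alt coding
(dosage x → 2−x) and complements opposite-strand records, but rejects
strand-ambiguous A/T and C/G sites whose alleles disagree: a silent flip
there would corrupt the δ terms every method depends on. Text-PLINK input
carries no ref/alt designation, so the reader takes the minor allele as
alt (ties → lexicographically greater); the phase-preserving text dialect
stores haplotype order as allele order within each genotype pair.

## Synthetic data: what it emulates and what it does not

`synth_ancestral_panels` draws Balding–Nichols populations: a shared
ancestral frequency π_j ~ Uniform(maf_floor, 1−maf_floor) per SNP, each
population's frequency Beta-distributed around π with divergence F (its
FST from the ancestral pool), haplotype alleles i.i.d. Bernoulli, and a
linear genetic map (default 1 Morgan per chromosome). This reproduces
realistic *differentiation* but deliberately not background LD, mutation
spectra, or realistic site-frequency spectra; source panels are in linkage
equilibrium, so any LD observed in a simulated cohort is attributable to
admixture (or finite sample size) by construction. Passing tests therefore
demonstrate the methods' behaviour under admixture signal specifically,
not robustness to background-LD confounding in real genomes.

`expand_population` implements exponential growth N(g) = N0(N1/N0)^(g/t)
as explicit generation-by-generation Wright–Fisher random mating:
offspring gametes recombine a random parent's haplotype pair with
crossovers as a Poisson process of rate 1 per Morgan along the map, plus
optional per-site allele flips at rate mu (default 0 for fixtures, since
per-generation mutation is negligible at these scales).

`simulate_admixed` operationalizes continuous gene flow over g
generations as a Markov chain along each chromosome: initial ancestry
drawn from the proportion vector; between adjacent SNPs at map distance d
an ancestry re-sampling event fires with probability 1 − exp(−g·d) (the
standard g-generation recombination-break model — a literal independent
per-SNP re-sample would destroy all LD structure), after which ancestry is
drawn afresh from the proportions. Within a segment alleles are copied
from one uniformly drawn donor haplotype of the segment's source, with
replacement across segments (panel sizes are small relative to cohort
size). True local ancestry is recorded per haplotype and SNP, giving exact
realized global proportions against which estimates are judged.

## Study conditions and problem sizes

The reference scenario mirrors a five-way admixture: proportions
(0.20, 0.32, 0.29, 0.08, 0.11), g = 100 generations, 750 diploids, 10,000
SNPs on a 1-Morgan map. Source divergences default to
F = (0.05, 0.08, 0.15, 0.07, 0.06) — moderate for the European, East-Asian
and South-Asian analogs, higher for the Bantu analog and highest for the
Khoesan analog, reflecting the deep differentiation of Khoesan
populations. Donor haplotypes (600 per source) are disjoint from the
reference halves (400) used for fitting and scoring, so evaluation never
reuses the generating haplotypes. Decoy pools place each true source with
decoys at divergence F + 0.03k (k = 1..3): related, but strictly worse
proxies.

Test-suite problem sizes are scaled to desk scale as the package's own
choice of fixture size: proportion recovery runs the full reference
scenario; pool-ranking replication uses 5,000 SNPs, 300 admixed diploids
and 20 seeded replicates; combination ranking, f3 contrast and LD
signatures share one 2,000-SNP, 150-diploid study. At these sizes the
proxy score resolves the 8% and 11% contributors' pools in ≈97% of pool
events, so the ≥95% replication bar is met with little margin — the
score's power, not its correctness, is what shrinks with problem size.

## Numerical choices

* Simplex solver: support enumeration with KKT solves; singular systems
  fall back to least squares; feasibility tolerance 1e-9; deterministic
  tie-break toward the first enumerated support.
* PSD repair: eigenvalue clipping at 0, count logged on the solution.
* One-sided regression p-values are floored at 1e-300 before the probit
  transform to keep t finite.
* Jackknife (blocks of SNPs or partners) uses the standard
  (B−1)/B·Σ(θ_b−θ̄)² variance with remainder SNPs absorbed into the final
  block.
* Monomorphic SNPs: HWE p = 1 (single configuration); LD pairs involving
  zero-variance SNPs are skipped and counted; fully missing SNPs carry
  allele count 0 and undefined frequency, and are dropped (with counts)
  by consumers.
* `mask_genotypes` refuses to mask every SNP; concordance is the fraction
  of masked entries restored exactly.

## Known limitations

* Sources are simulated in linkage equilibrium; background LD in real
  panels adds noise (and some signal leakage) to the LD-vs-δ regression
  that these tests do not exercise.
* The proxy score uses genotype-dosage r², not haplotype LD; phased input
  improves nothing by design.
* The QP assumes the candidate set spans the true sources; with all
  candidates poor, F ranks them but its absolute value has no calibrated
  interpretation.
* Pool normalization needs at least three members per pool for a finite
  z-score (the sd over "other members" is undefined below that); two-member
  pools fall back to ranking by the raw score.
* The expansion model regenerates panels by random mating only; selection,
  migration and non-random mating are out of scope.
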