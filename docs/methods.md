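# Methods

Models, estimators, numerical choices and limitations of `msatpop`. Nothing in
this document is an empirical claim about real organisms; every number quoted
comes from computations this package performs (its test suite and calibration
runs on its own simulator).

## Genotype representation

A genotype table is strains × loci, each cell a sorted tuple of distinct
allele values (amplicon sizes in bp, or repeat counts after conversion); the
empty tuple is a missing cell. The slash-separated text format cannot encode
allele dosage, so `187/187` and `187` are the same cell: a single-allele cell
records "only one allele observed". Diploid estimators therefore expand
single-allele cells to dosage 2 ("apparent homozygote"), which is correct for
true homozygotes and a documented approximation when a second allele dropped
out of amplification.

Size-to-repeat conversion is affine per locus:
`repeats = ref_repeats + (size − ref_size) / motif_length`, anchored at a
reference allele of known repeat count. Fractional repeat values (off-ladder
alleles) are kept, not rounded; downstream methods accept them.

Ploidy classes: `homozygous_all_loci`, `two_alleles_max` (diploid-compatible
heterozygote), `three_alleles_one_locus`, `complex`. Estimators that assume
diploidy (HWE, Weir–Cockerham, structure) use only the first two classes.

## Bruvo distance

Per allele pair, `d(x, y) = 1 − 2^(−|x−y|)` in repeat units. Genotype
distance is the minimum over one-to-one allele assignments of the mean allele
distance, found with `scipy.optimize.linear_sum_assignment`. For unequal
cardinalities the `infinity` model (default) pads the smaller genotype with
virtual alleles at distance 1 from everything; `genome_addition` /
`genome_loss` average the equal-cardinality distance over all paddings drawn
from the smaller / larger genotype respectively; `addition_loss_average` is
the mean of those two. The strain-pair distance is the mean over loci scored
in both strains (pairwise deletion); a pair sharing no locus is an error.
Dosage expansion to the base ploidy is applied at matrix assembly, so two
homozygous diploids one repeat apart are at distance 0.5 at that locus.

## Neighbor joining and AU support

Saitou–Nei agglomeration on the Q-matrix; ties broken by the first (row-major
upper-triangle) minimum, so results are deterministic; negative branch
lengths are clamped to zero and counted on the tree object. The final three
taxa are joined by the three-point formulas, leaving the standard unrooted
trifurcation. On additive matrices the reconstruction is exact (tested
against path-length matrices of random trees and against scikit-bio's NJ on
generic matrices). On clonal data many distances tie and NJ topology is not
unique; implementations may legitimately differ there.

Cluster support uses the multiscale bootstrap: loci are resampled at scales
r ∈ {0.5, …, 1.4} (⌈rL⌉ loci per replicate; the realised ratio is used in the
fit), trees rebuilt, and each observed bipartition's recovery frequency BP(r)
recorded. With `z(r) = −Φ⁻¹(BP)`, weighted least squares fits
`z = v√r + c/√r` (weights from the delta method,
`n_boot·φ(z)²/(BP(1−BP))`), and the approximately unbiased p-value is
`AU = 1 − Φ(v − c)`. Clusters recovered in all or no replicates get AU 1 or 0
and are flagged `degenerate`. With fewer than 10 loci the resampling unit is
coarse and a warning is issued; AU values on an 8-locus panel are
qualitative.

## Structure model

No-admixture Bayesian clustering of diploid-compatible strains: each strain
belongs wholly to one of K populations; population allele frequencies carry a
symmetric Dirichlet(λ=1) prior. Gibbs sampling alternates frequency draws
(Dirichlet via gamma variates) and label draws (Gumbel-max over per-population
diploid log-likelihoods: `2 log p` homozygote, `log 2pq` heterozygote,
missing loci skipped). Posterior memberships are averaged assignment
indicators over recorded iterations. The per-K model score is the deviance
estimate of log evidence, `mean(logL) − var(logL)/2`; the sweep reports the
whole profile rather than thresholding it, because under strong selfing real
clonal substructure keeps adding likelihood as K grows — choosing K is a
judgment call, and on panmictic simulated data the evidence profile does peak
at the true K. Label switching across chains is resolved by maximum
column-correlation assignment.

## Population statistics

- **Ho**: fraction of scored strains with ≥2 distinct alleles.
- **HWE**: chi-square goodness of fit of genotype counts to Hardy–Weinberg
  proportions, df = k(k−1)/2; optionally Monte Carlo (alleles shuffled among
  individuals, p = (1+hits)/(n+1)), which is the recommended mode for sparse
  multiallelic tables. Under null simulations the Monte Carlo test's type-I
  rate at α=0.05 measures ≈0.03–0.05 (slightly conservative, from the
  discreteness of permuted statistics).
- **F-statistics**: Weir–Cockerham variance components a, b, c computed per
  allele and summed per locus; multilocus values sum components across loci.
  `F_ST = Σa/Σ(a+b+c)`, `F_IT = 1 − Σc/Σ(a+b+c)`, `F_IS = 1 − Σc/Σ(b+c)`.
- **AMOVA**: one level, on squared Bruvo distances. `SS_total = Σd²/N` over
  all pairs, `SS_within` per group divided by group size;
  `σ²_a = (MS_among − MS_within)/n₀` with `n₀ = (N − Σn_g²/N)/(g−1)`.
  Significance by permuting strain labels, `p = (1+hits)/(n_perm+1)`; on n=6
  the permutation p matches exhaustive enumeration over all relabellings.

## Divergence dating

(δμ)² between two groups: per locus, the squared difference of mean repeat
counts (dosage-2 expansion, all scored strains), averaged over loci scored in
both groups. Under the strict stepwise mutation model E[(δμ)²] = 2μτ, so
`τ = D/(2μ)` and `years = τ / generations_per_year`; slope recovery on
simulated splits is within a few percent.

The 95% CI is a **studentized (bootstrap-t) locus bootstrap**: resample loci,
form `t* = (D* − D)/se*`, and invert the 2.5/97.5 t*-quantiles around D with
the full-sample standard error; the lower limit is clamped at 0. The
percentile interval was rejected because per-locus (δμ)² values are strongly
right-skewed (squared near-normal quantities) and its upper limit sits too
low — true split times escaped above it in calibration. Resamples with zero
spread are excluded from studentization; if almost all are degenerate the
code falls back to the percentile interval.

## Simulator

Forward-in-time diploid Wright–Fisher with partial selfing: each offspring
selfs with probability s, otherwise outcrosses; loci assort freely; each
transmitted allele mutates ±1 repeat with probability μ, reflecting at a
floor of 2 repeats. An ancestral population is burned in, copied into
`n_pops` isolated demes, evolved `split_time` further generations, and
sampled. Output is a bp-sized genotype table (via the locus anchors) with
missing cells and aneuploid cells (padded to 3 distinct alleles) injected at
configured rates, plus ground-truth labels.

Defaults are the study-like conditions and are treated as fixed experimental
settings, not tunables: four demes, split 400, deme size 200, s = 0.95
(matching multilocus F_IS ≈ 0.9 via F = s/(2−s)), μ = 5×10⁻⁴ per allele per
generation (desk-scale: equilibrium diversity comparable to the real panel is
reached in hundreds of generations), the eight-locus panel, 28 strains per
deme, 1% missing cells, 0.7% aneuploid cells. On these defaults the analysis
chain recovers F_IS ≈ 0.9, strong among-deme AMOVA structure, and accurate
deme assignment.

## Test problem sizes (design choices)

The acceptance property tests fix their own simulation conditions a priori;
they are design choices of this package, recorded here:

- Slope recovery: 32 generic dinucleotide loci, μ = 5×10⁻⁴,
  τ ∈ {100, 300, 600}, 8 replicates each, deme size 100, s = 0.95; slope of
  mean D on τ through the origin required within 20% of 2μ.
- F_IS ordering: s ∈ {0, 0.5, 0.99}, 16 loci, μ = 2×10⁻³, 3 replicates per s.
- HWE type-I: 125 panmictic simulations × 4 loci, N = 150, 100 strains
  sampled, μ = 2×10⁻³, Monte Carlo with 199 permutations; required rate
  0.05 ± 0.02.
- Structure accuracy: two demes split 1200 generations, deme size 100, 30
  strains each; required ≥95% correct assignment.
- CI coverage: 200 simulations at 64 loci, μ = 2×10⁻³, τ = 400 (μτ = 0.8),
  s = 0.95, deme size 100, 28 strains per deme, 400 bootstrap replicates;
  required ≥90% coverage of a nominal 95% interval.

## Limitations

- **Divergence CI is mildly anti-conservative.** Measured coverage of the
  nominal 95% bootstrap-t interval at 64 loci and μτ = 0.8 is roughly
  0.88–0.93 across independent 200-simulation blocks (≈0.91 overall); the
  residual deficit comes from the heavy-tailed distribution of per-locus
  (δμ)² values, which no locus-resampling interval fully repairs at this
  sample size. With the study-scale 8-locus panel the interval is qualitative
  only (warned at <10 loci).
- **Dosage is unobservable** in the input format; apparent homozygotes may be
  allele dropout, biasing Ho downward and F_IS upward by an unknown amount.
- **AU support with few loci** rests on a coarse resampling unit; values from
  an 8-locus panel should not be over-read.
- **Evidence-based K selection is not automatic** under strong selfing:
  clonal substructure is real signal and the profile can rise with K; the
  package reports the profile and leaves the cut to the analyst.
- **NJ on clonal data** has tied joins; topology among identical strains is
  arbitrary (deterministic here, but implementation-specific).
- The simulator models free recombination between loci, no migration after
  the split, constant deme size, and strict single-step mutation; none of
  these are fit to data.
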