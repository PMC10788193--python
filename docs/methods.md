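# Methods

This note documents the models implemented in `ednapop`, the choices
made where the design was genuinely open, and what the synthetic data
do and do not establish about real eDNA.

## The generative model of the synthetic lake

The simulator is built around three layers.

**Source populations.**  Two populations diverged at a target F_ST are
drawn with the Balding–Nichols model: the ancestral reference-allele
frequency `p` of each SNP is uniform on [0.05, 0.95] (avoiding
near-fixed ancestral sites that make divergence unobservable), and each
population frequency is `Beta(p(1−F)/F, (1−p)(1−F)/F)`, so
`Var(p_i) = F p (1−p)` per population and the expected variance of
`p₁ − p₂` is `2 F p (1−p)`.  The default F = 0.3 produces a marker
panel with many strongly differentiated SNPs, as expected of loci
pre-selected for segregating between ecomorphs.

**The ancestry cline.**  Fish ancestry is logistic in depth:
`q(d) = 1 / (1 + exp((d − m)/s))` with midpoint `m = 15` m (the
thermo-oxycline) and scale `s = 1.5` m by default, which leaves the
0–5 m and 20–25 m strata essentially pure and transitions within the
10–20 m band — a smooth stand-in for an abrupt break between 12 and
18 m.  A fish in a stratum takes `q` at the stratum midpoint and
dosage `~ Binomial(2, q p₁ + (1−q) p₂)` (dosage counts reference
alleles).  `s → 0` gives the step-cline limit.

**Pooled eDNA read counts.**  The expected reference-allele frequency
of a sample at depth `d` is a mixture of the local and opposite-side
pools: `f = (1−τ) f_local + τ f_opposite`.  Because the logistic cline
is symmetric about its midpoint, the opposite-side frequency equals the
cline evaluated at the reflected depth, so the mixture collapses to an
effective ancestry weight `q' = (1−τ) q + τ (1−q)` — one scalar τ, no
hydrodynamics.  Per cell, read depth is `Poisson(λ)` (default λ = 40)
independently zeroed with probability `dropout` (default 0.1), and the
reference count is beta-binomial with intra-class correlation ρ
(default 0.05): `p* ~ Beta(f(1−ρ)/ρ, (1−f)(1−ρ)/ρ)`, `x ~ Bin(n, p*)`,
giving `Var(x) = n f(1−f)(1 + (n−1)ρ)`.  The beta-binomial stands in
for PCR amplification bias; dropout is a separate knob because the
presence filter acts on presence/absence, not depth.  Poisson-plus-
dropout was chosen over a negative binomial so the two failure modes
(missing cell vs noisy frequency) stay independently tunable.

**Sampling design defaults.**  16 eDNA samples at {3, 7, 12, 18, 22} m
with 5/2/2/2/5 replication; 120 SNPs in 98 amplified loci (the first 22
amplicons carry two SNPs); fish in five strata 0–5 … 20–25 m.  The
microbial generator draws shallow and deep order profiles from a
symmetric Dirichlet (concentration 0.5, giving realistically uneven
communities over 30 orders) and mixes them by a logistic weight in
depth (sharpness 2 /m); counts are multinomial with 20,000 reads per
sample over the 3/1/1/1/3 nine-sample ONT design.

**What the simulator does not model.**  Heterospecific reads, numts,
mapping error, per-PCR-replicate variance (replicates are pooled before
sequencing, so it is not separable), eDNA transport dynamics or decay.
Passing recovery tests therefore shows the estimators are correct under
the pooled binomial model with overdispersion — not that real eDNA
satisfies that model.

## Allele counting

Each mapped SAM record overlapping a panel SNP contributes at most one
count: the CIGAR is walked (via pysam aligned pairs) to the read base
aligned at the SNP; deletions spanning the SNP and bases other than the
declared ref/alt are ignored; unmapped, secondary, supplementary and
duplicate-flagged records are skipped.  Default quality floors are
MAPQ ≥ 20 and base quality ≥ 20, usual practice for allele-specific
counting; both are parameters.  Fragments are deduplicated by query
name per SNP, so overlapping mates count once.  The panel stores SNP
positions 1-based (VCF convention) and ingests amplicon intervals as
0-based half-open BED, converting on read.

"Present" for the 75% filter means total cell depth ≥ 1 read (a
representation filter, not a coverage floor); the floor is exposed as
`min_depth`.  The threshold is `ceil(fraction × n_samples)` — 12 of 16
at the default 0.75.

## Frequency estimation and correspondence

Per-stratum eDNA frequency is the **unweighted mean of per-sample
frequencies**; a depth-pooled-count estimator (summing reads before
dividing) is provided for comparison and diverges when coverage varies
across samples, since it weights well-covered samples more.  Missing
propagates: a cell with zero reads is missing, a stratum cell is
missing only if every sample is.

Correlations use pairwise-complete deletion and report `r`, `df =
n_pairs − 2`, `t = r√df/√(1−r²)` and a two-sided p from the t
distribution.  No multiple-testing correction is applied across depths;
the per-depth tests are reported raw.  Perfect correlation returns
`t = ±inf, p = 0` rather than an error.

One published consistency note: in depth-correlation tables of this
kind the printed (r, df, t) triplets can be checked against the closed
form; our tests verify the four self-consistent rows and the docs flag
(rather than "fix") a row where the printed t disagrees with its own
(r, df) by ~1.6%.  Similarly, a shift correlation reported as
"r² = 0.268 with n = 71, p = 0.0237" is only internally consistent if
0.268 is read as r (t = 2.31, p ≈ 0.024); reading it as r² (r = 0.518)
would imply p ≈ 3×10⁻⁶.  The package reports plain r alongside p so
the ambiguity cannot arise.

## Admixture EM

The likelihood is `Σ_il [g log f + (2−g) log(1−f)]` with
`f_il = Σ_k q_ik p_kl`.  E-step responsibilities split each of the two
allele draws among components; M-step updates are responsibility-
weighted averages.  Plain EM was chosen over quasi-Newton block
relaxation: the stationary points are identical and monotonicity of the
log-likelihood is exact, which the tests assert at every iteration.
Defaults: `max_iter = 2000`, `tol = 1e−6` on the log-likelihood gain,
`P` clamped to [1e−6, 1−1e−6], `Q` initialised from a symmetric
Dirichlet and `P` from the pooled frequency ± 0.05, all from one
explicit seed.  Label switching is resolved (in tests and the
acceptance script) by choosing the column permutation minimising the
mean |Q̂ − Q_true|.  Missing dosages contribute nothing to either step.

The pooled-ancestry estimator maximises the binomial likelihood of one
sample's counts over the scalar mixture `q ∈ [0,1]` on a 1001-point
grid with bounded local refinement, and reports the profile-likelihood
interval {q : ℓ(q) ≥ ℓ_max − 1.92} (asymptotic 95%).  If `p₁ = p₂`
everywhere the likelihood is flat in q; the estimate is returned as NaN
with a flag rather than an arbitrary number.

## LD pruning

Composite-genotype LD: squared Pearson correlation of dosage vectors
over pairwise-complete individuals (≥3 required; monomorphic vectors
are warned and treated as r² = 0 for pruning).  Pruning is greedy
within 50 kb windows, removing the later SNP of any pair above the
threshold; windows advance by 10 **variants** by default.  The step in
the cited pruning convention ("50 kb / 10 / 0.1") counts variants, and
that reading is the default here; a base-pair step is available via
`step_unit="bp"`.  A final sweep starts a window at every retained
variant, which guarantees the documented invariant — no retained pair
within any 50 kb window exceeds the threshold — and makes the output a
fixed point of re-pruning regardless of step size.

## PCA with missing values

NIPALS: columns are mean-centred over observed entries; each component
is extracted by alternating regressions that skip missing cells, then
deflated from observed cells only.  On complete data this is power
iteration and reproduces the truncated SVD; the tests require agreement
to 1e−8.  Signs are fixed by making each component's largest-magnitude
loading positive.  Convergence tolerance 1e−12 on the score vector,
2000 iterations cap.  All-missing columns are dropped with a warning.
NIPALS was chosen among missing-value PCA algorithms because it is the
classical default, deterministic given the data, and exact in the
complete case; it is not a maximum-likelihood imputation and can be
biased when missingness is informative (eDNA dropout is mostly
depth-of-coverage driven, i.e. close to missing-at-random per cell).

## Canonical correspondence analysis

The count table is converted to relative frequencies with row/column
weights `r, c`; the chi-square standardised residual matrix is
`Q̄ = (P − rcᵀ)/√(rcᵀ)`, whose squared norm is the total inertia.  The
constraint matrix is weighted-centred, scaled by √r and the fitted part
`HQ̄` obtained by least squares; SVD of the fitted and residual parts
gives constrained and unconstrained eigenvalues.  The decomposition
`constrained + residual = total` is exact to 1e−9 by construction and
asserted.  Eigenvalues were verified against both an independently
coded two-step textbook implementation (1e−10) and the R vegan
implementation (both in the test suite).

The permutation ANOVA uses `pseudo-F = (constrained/q)/(residual/
(n−q−1))` and permutes the **rows of the constraint matrix** directly
(the community table and its row weights stay fixed) — whether to
permute constraints or residuals is an open choice in constrained
ordination; direct permutation is exact for a single constraint and is
documented here as the package's choice.  The p-value is the add-one
estimator `(1 + #{F* ≥ F})/(1 + n_perm)`, which never returns zero;
ties at F (including the perfect-fit F = ∞ case, where the residual
inertia is numerically zero) count toward the numerator.  Taxa with
zero total count are dropped silently; no abundance filtering is
applied.

## Pipeline, formats, reproducibility

Exchange formats are plain text: SAM v1.6, minimal VCF v4.2 (GT only,
dosage = reference-allele count, `./.` missing), BED (0-based
half-open), TSV tables.  The CLI (`edna-popgen`) wraps the library
stages; `run` executes the full chain from a flat YAML config and
writes every intermediate plus a `summary.json` carrying the seed and a
stable configuration digest.  Every generator and stochastic algorithm
takes an explicit seed and draws from its own `numpy.random.Generator`;
equal seeds give byte-identical outputs.

## Problem sizes

The test-suite and acceptance-script simulations use the design sizes
above (16 samples × 120 SNPs; 200 fish × 500 SNPs for admixture
recovery; 200 replicate datasets × 199 permutations for the CCA size
check; coverage ladder {10, 50, 250}× for the consistency check).
These sizes give stable Monte-Carlo behaviour at interactive runtimes
and are the package's chosen reference conditions.

## Known limitations

- Frequencies are method-of-moments ratios; no shrinkage or Bayesian
  pool-seq estimator is provided, and with an unknown number of eDNA
  contributors the effective sample size per cell is unknown.
- The admixture model assumes Hardy–Weinberg within components and
  unlinked loci; it is run after LD pruning but linkage within
  amplicons (SNPs sharing a locus) violates independence mildly.
- The CCA permutation test assumes exchangeable samples; depth-ordered
  autocorrelation would inflate significance.
- No heterospecific-read screening: reads from non-target species that
  happen to map are counted if they carry a declared allele.
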