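# Methods

## Model

The package fits ordinal categorical phenotypes observed across
environments with a cumulative-probit (threshold) mixed model. Each record
*y<sub>ijk</sub>* ∈ {1, …, C} is generated by an unobserved Gaussian
liability

l<sub>ijk</sub> = x′<sub>ij</sub>β + z′<sub>ij</sub>b + ε<sub>ijk</sub>,
ε<sub>ijk</sub> ~ N(0, σ²<sub>ε</sub>),

cut at ordered thresholds γ = (−∞, γ₁, …, γ<sub>C−1</sub>, +∞): the
observed category is the interval the liability falls into. Because
liabilities are latent, two constraints make the model identified: the
residual variance is fixed at 1 and the first threshold at γ₁ = 0; the
per-environment fixed effects E<sub>i</sub> absorb the intercept (there is
no separate global intercept). Equivalently, on the probability scale the
c-th cumulative link value is η<sub>c</sub> = γ<sub>c</sub> − x′β − z′b
(fixed and random effects enter with reversed sign) and
π<sub>c</sub> = Φ(η<sub>c</sub>) − Φ(η<sub>c−1</sub>).

Nine model variants combine six effect blocks — E (fixed environments),
L (IID lines), G (genomic main effects), G×G (additive×additive epistasis),
G×E and G×G×E (their environment interactions):

1 = {E, L};  2 = {E, G};  3 = {E, G, G×G};  4 = {E, L, G};
5 = {E, L, G, G×G};  6 = {E, G, G×E};  7 = {E, G, G×G, G×E, G×G×E};
8 = {E, L, G, G×E};  9 = all six.

### Kernels

* Marker QC removes SNPs with a missing fraction strictly above 0.10, then
  SNPs with minor allele frequency ≤ 0.05 (boundary excluded) among the
  survivors; remaining missing calls are imputed to 2p<sub>m</sub>, which
  leaves the allele frequency used for centering unchanged. Frequencies are
  the post-QC sample frequencies; lines are never dropped (per-line call
  rate is only reported).
* The genomic relationship matrix is G = ZZ′/p from the standardized scores
  z<sub>jm</sub> = (x<sub>jm</sub> − 2p<sub>m</sub>)/√(2p<sub>m</sub>(1−p<sub>m</sub>)),
  with no further rescaling (no division by the mean diagonal, no identity
  blending). Standardization makes σ²<sub>g</sub> interpretable as a genomic
  variance; the mean diagonal of G is ≈ 1 + O(1/p).
* The epistasis kernel is the Hadamard square GA = G # G (PSD by the Schur
  product theorem).
* Interaction kernels are record-level: (Z<sub>g</sub>K Z<sub>g</sub>′) #
  (Z<sub>E</sub>Z<sub>E</sub>′) for K ∈ {G, GA}. Entry (r, s) is
  K[line<sub>r</sub>, line<sub>s</sub>] when the records share an
  environment and 0 otherwise, so with records grouped by environment the
  kernel is block-diagonal. The sampler exploits this: interaction effects
  are equivalent to independent per-environment line-level effects with
  covariance K σ², which is how they are parameterized internally. A dense
  Hadamard construction is kept as a testing reference and the two are
  checked for equality to 1e−12.

### Priors

Fixed effects get a flat Gaussian prior (mean 0, variance 10¹⁰). Each
variance component gets a scaled-inverse-χ² prior with df = 5 and scale
S<sub>k</sub> chosen by a 50/50 prior variance split: with K random blocks,
S<sub>k</sub> = (df + 2)/(K · mean diag K<sub>k</sub>), so the prior mode
S<sub>k</sub>/(df + 2) places liability variance 1/K on each block,
jointly matching the unit residual. For line-level blocks the mean diagonal
of the line kernel is used; for interaction blocks the record-level
diagonal (the kernel as it enters the model). Whether other software's
internal scale rule divides by the mean kernel diagonal in exactly this way
is not pinned down anywhere we could verify, so the rule is explicit here
and both df and the scales are user-overridable.

## Gibbs sampler

Each sweep updates, in order:

1. **Liabilities** — truncated-normal draws: l ~ N(η, 1) restricted to the
   observed category's interval, via inverse-CDF sampling (Φ/Φ⁻¹ from
   scipy); draws are clipped into the open interval with a 1e−12 margin to
   guard tail round-off, with a midpoint fallback for pathological cases.
2. **Thresholds** — the classical uniform full conditionals (data
   augmentation à la Albert–Chib): γ<sub>c</sub> ~ U(max{l : y = c},
   min{l : y = c+1}) for c = 2, …, C−1; γ₁ stays 0. If a category is empty
   the corresponding end falls back to the adjacent threshold; if the upper
   end would be +∞ (empty topmost categories) the threshold is kept at its
   current value and a warning is logged. Records can never be scored into
   categories above C.
3. **Fixed effects** — per-environment Gaussian full conditionals (the
   environment designs are disjoint, so these are scalars).
4. **Random blocks** — each block is parameterized as b = F u with
   K = FF′ from the eigendecomposition of its kernel (eigenvalues below
   1e−10 × the largest are dropped, constraining b to the kernel column
   space and avoiding any explicit K⁻¹). The coefficients u have an
   independent N(0, σ²I) prior, so their full conditional is a ridge-type
   Gaussian. Because W′W (W the record-level design of u) is constant
   across sweeps, its eigendecomposition is precomputed once per block and
   each update costs only matrix–vector products. Interaction blocks update
   each environment's coefficients independently.
5. **Variances** — σ²<sub>k</sub> = (S<sub>k</sub> + SS<sub>k</sub>) /
   χ²<sub>df+q<sub>k</sub></sub> with SS<sub>k</sub> = b′K⁻b = u′u and
   q<sub>k</sub> the number of retained eigencomponents (the dimension of
   the space the effect actually lives in; equal to the block dimension for
   full-rank kernels). The residual variance is never sampled.

Chains are initialized at probit transforms of the observed category
frequencies (thresholds from pooled cumulative frequencies, fixed effects
from per-environment category-1 frequencies), which matters because the
uniform threshold updates are a slow-mixing random walk whose step size
shrinks as 1/n: a frequency-based start places the chain in the right
region immediately. A single seeded generator (`numpy` PCG64) drives every
step; the seed is recorded with all outputs and identical settings
reproduce chains exactly. Defaults are 30,000 iterations, 10,000 burn-in,
thinning 5 — deliberately conservative for the slow threshold mixing, and
fully configurable.

The sampler was verified against an independently written naive Gibbs
implementation (explicit kernel pseudo-inverse, dense multivariate-normal
solves, scipy truncated-normal draws); the two agree on posterior means
within Monte-Carlo error, and this cross-check is part of the test suite.

## Prediction and scoring

Predictive category probabilities use the cumulative-probit link,
π̂<sub>c</sub> = Φ(γ<sub>c</sub> − η) − Φ(γ<sub>c−1</sub> − η). Two modes
are exposed: `per-draw-average` (the default; evaluates the link at every
retained draw and averages — the full posterior predictive) and `plug-in`
(posterior means only). Which of the two a given historical analysis used
is generally not documentable, so reported metrics are labeled with the
mode.

The headline metric is the Brier score, BS = n⁻¹ΣΣ(π̂ − d)², which uses
the entire predictive distribution and is a strictly proper scoring rule;
its raw range is [0, 2] and BS/2 is reported so scores live in [0, 1].
Hit-rate and the ordinal log-likelihood are computable
(`ordinal_log_likelihood`) but not the headline metric, since both depend
on only one coordinate of the predictive distribution.

Cross-validation assigns *records* (not lines) to the test set completely
at random — CV2-style, so a line can be trained in one environment and
tested in another, which is precisely where G×E kernels help. Defaults are
20 partitions with test fraction 0.20 (the split size is a logged,
configurable choice; 0.20 is a conventional default). Partitions are
redrawn (and the redraw logged) until every environment appears in both
training and test sets; `test_fraction = 0` is a degenerate in-sample
diagnostic mode. Per-partition chains derive their seeds deterministically
from the CV seed.

Variance partitions report each component against the total liability
variance (components + the unit residual), percentages 100·v/total, and
pairwise total-variance ratios between models; prediction-ability gains are
100·(BS<sub>ref</sub> − BS<sub>new</sub>)/BS<sub>new</sub>, the convention
that reproduces the published-style gain figures from mean Brier scores.

## Synthetic data

The generator draws biallelic genotypes as binomial(2, p<sub>m</sub>) with
per-marker frequencies uniform in a configurable range (default 0.1–0.9) —
Hardy–Weinberg sampling with no linkage disequilibrium, no QTL
architecture, and no pedigree structure. Effects are drawn through the same
kernel eigen-factorization the sampler uses, so simulation and inference
share one covariance convention; liabilities add N(0, error_variance) noise
(default 1, matching the fitted model; settable to 0 for deterministic
mapping checks) and categories follow from the thresholds. Replication per
(environment, line) cell is uniform on {1, …, 6} by default, mimicking
unequal cell counts in real trials.

`study_shaped_fixture` is a synthetic desk-scale stand-in for a
three-environment disease-score trial: 60 lines × 300 SNPs, C = 5,
environment record totals strictly ordered (echoing proportions
1485/832/481), and a G×E-dominated variance profile
(σ²<sub>L</sub> = 0.05, σ²<sub>g</sub> = 0.2, σ²<sub>gE</sub> = 1.0) with
fixed effects (1.0, 1.2, 1.5) and thresholds (0, 0.8, 1.6, 2.4).

Because the generator omits linkage disequilibrium and marker-level
architecture, passing recovery tests demonstrate correctness of the
*model machinery* — kernels, sampler, scoring — under the model's own
assumptions; they do not certify prediction accuracy on real germplasm,
where LD structure, allele-frequency spectra and non-additive biology
differ.

## Problem sizes and test design choices

* Sampler recovery tests run at J = 300 lines × 500 markers, C = 3,
  n = 900 records (3 environments × 1 replicate), σ²<sub>g</sub> = 0.5,
  with 30,000-iteration chains. With only three ordinal records per line,
  single-realization posterior means of σ²<sub>g</sub> scatter noticeably
  around the truth (and the heavy-tailed prior, mean S/(df−2), pulls
  upward), so recovery is asserted on posterior means averaged over three
  replicate data sets — realization noise shrinks while the conditions and
  tolerances stay fixed.
* Interval-coverage checks (90% posterior intervals covering the
  generating variances in ≥ 7 of 10 replicates, models 2 and 6) use
  4,000-iteration chains; coverage is assessed per component.
* Interaction-dominance checks use σ²<sub>g</sub> = 0.3 vs
  σ²<sub>gE</sub> = 1.0 — a G×E-dominated regime with a still
  well-identified main effect.

## Numerical choices and degenerate inputs

* Kernel eigenvalues below 1e−10 × the largest are treated as zero; if an
  eigendecomposition fails, a one-shot diagonal jitter of 1e−8 × mean
  diagonal is applied.
* Sampled variance components are floored at 1e−12 to keep the state
  strictly positive.
* Monomorphic markers cannot be standardized and raise an error (QC removes
  them first in the normal pipeline; the simulator drops chance
  monomorphics before kernel construction).
* Ragged genotype files, out-of-domain calls, out-of-range or duplicate
  phenotype records, non-increasing thresholds and unnormalized probability
  vectors all raise errors naming the offender.
* Summaries are reported to 4 decimals in file outputs; CSV floats use
  shortest-round-trip repr so all writers round-trip exactly.

## Known limitations

* The threshold update is the classical uniform conditional; for very large
  n its mixing is slow (mitigated by the frequency-based initialization,
  but posterior SDs of thresholds from short chains should be treated with
  care).
* Marker-effect-level priors (BayesA/B/Cπ-style differential shrinkage),
  logit links, dominance and RKHS kernels, and pedigree relationship
  matrices are out of scope.
* Record-level interaction kernels assume environments are unstructured
  (no environmental covariates); the G×E kernel is block-diagonal by
  construction.
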