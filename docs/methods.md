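# Methods

## Decomposed interaction testing

The package studies genetic modification of a mediated pathway
E → M → Y: exposure E, molecular mediator M, outcome Y, biallelic
genotype G coded additively (dosage in [0, 2]). Three product-term Wald
tests partition the question "does G modify the E–Y association?":

| test       | regression                     | what the product term measures        |
|------------|--------------------------------|---------------------------------------|
| standard   | Y ~ G + E + G·E + covariates   | modification of the full E→Y pathway  |
| upstream   | M ~ G + E + G·E + covariates   | modification of E→M                   |
| downstream | Y ~ G + M + G·M + covariates   | modification of M→Y                   |

All tests use ordinary least squares with a heteroscedasticity-robust
sandwich covariance and a standard-normal reference for the Wald z.
Product terms with a genotype factor are intrinsically heteroscedastic
under the alternative, so robust covariance is the correct default, and
the normal (rather than t) reference matches the large-sample regime the
method targets.

### Simulation model

Genotypes are Binomial(2, MAF), exposures standard normal. Signal sizes
are *variance fractions*: in the upstream scenario the mediator is

    M = β_GE · (G·E) + ε,   β_GE² · Var(G·E) = v_int,   Var(M) = 1,

and the outcome Y = β_M·M + ε with β_M² = v_transmit; the downstream
scenario swaps the roles (M = β_E·E + ε with β_E² = v_transmit;
Y = β_GM·(G·M) + ε with β_GM²·Var(G·M) = v_int). Coefficients are sized
from the analytic moments E[G²] = 2·maf(1−maf) + (2·maf)², so a scenario
maps deterministically to coefficients and realized trait variances
fluctuate around 1 (checked to ±0.05 at n = 10⁵).

Two conventions exist for the product term and the generative
description does not pin one down: the default takes the *uncentered*
dosage (marginal product variance E[G²]; the orthogonalized — partial —
interaction fraction is then v_int · Var(G)/E[G²], i.e. 0.6·v_int at
MAF 0.25), and a `product_centering="centered"` switch makes the whole
fraction partial. The uncentered convention reproduces the published
downstream power pair closely and is the default.

The measured mediator is M_meas = M + ε with
Var(ε) = Var(M)·(1−ICC)/ICC computed from the *sample* variance of the
realized M, so the intraclass correlation holds conditionally on the
generated data; ICC = 1 returns M exactly (bitwise). Only the true M
enters the outcome equation; the analyst-visible M_meas enters the
upstream and downstream regressions, which is what produces the
power attenuation by ICC.

### Power

Monte-Carlo power is the fraction of replicates with product-term
p < α; each replicate draws from a child stream of the master seed, so
grids are reproducible and order-independent. The analytic oracle is the
non-central chi-square tail

    power = P(χ²₁(ncp) > q_{1−α}),
    ncp = n · v_partial / (1 − v_explained),

with v_partial the orthogonalized interaction fraction above, multiplied
by v_transmit for the standard test (the signal reaches the tested
outcome only through the mediating leg) and by ICC wherever the measured
mediator enters. The closed form follows from Cov(G·X, X) = E[G] and
Cov(G·X, G) = 0 for X ⟂ G with E[X] = 0, giving residual product
variance Var(G) after projection on {1, G, X}.

Two calibration facts surfaced by the test suite are worth knowing.
First, HC0 is mildly anticonservative in finite samples: at n = 1,000
the null rejection rate of the product-term test is ≈0.053–0.056 at
nominal 0.05 (HC3 restores ≈0.050); HC0 remains the default because it
is the convention of large-sample GWIS tools, and HC1/HC3 are one
keyword away. Second, under the uncentered convention the upstream and
downstream tests at the primary settings (v_int = 0.005,
v_transmit = 0.10, n = 1,000) share ncp ≈ 3.0 and true power ≈ 0.41,
while the standard test has ncp ≈ 0.30 and power ≈ 0.085; the analytic
oracle cannot produce a standard-test power near 0.21 in the upstream
scenario under either product convention, with or without main effects,
so that particular reference value is treated as provisional and the
standard test is validated against the oracle instead.

## Mediation

For continuous exposure and outcome (both standardized internally to
mean 0, SD 1), the causal-mediation estimands reduce to the linear
structural equation decomposition: fit M ~ X (+C) for path a and
Y ~ X + M (+C) for paths c′ (direct) and b; then ACME = a·b,
total = c′ + a·b, additivity exact by construction. Intervals are
quasi-Bayesian: (a) and (b, c′) are drawn from normal approximations
centered at the estimates with HC0 covariance (the a-draw and the
(b, c′)-draw are independent, as the two fits are), the estimands formed
per draw, and percentile intervals taken. The default of 20 draws
follows the original analysis convention but gives unstable percentile
endpoints; the package logs a warning and the tests use ≥1,000 draws,
where 95% intervals for ACME achieve 95% ± 3% coverage on synthetic
replicates. Proportion mediated is reported only when |total| exceeds a
tolerance, and *inconsistent mediation* is flagged when |ACME| > |total|
(opposing direct/indirect paths or residual confounding). Mediator
subspecies are compared by running the decomposition per component,
one at a time, optionally deriving a remainder component by subtraction.

## Synthetic cohort

The generator emulates the *structure* of a biobank diet–biomarker–
inflammation dataset, not its values:

- **Panel.** Per chromosome, two latent AR(1) Gaussian chains per sample
  (parameter `ld_rho`) are thresholded at the allele-frequency quantile
  and summed to a dosage in {0, 1, 2}; LD decays geometrically with
  variant distance in index space and breaks at chromosome boundaries.
  Defaults: 20,000 samples × 2,000 variants on 3 mock chromosomes;
  tests use smaller panels generated on the fly.
- **Phenotypes.** A latent "healthy lifestyle" confounder raises fish
  intake, raises the mediator and lowers the outcome, inducing the
  marginal diet–outcome association that attenuates on adjustment. Fish
  intake is ordinal (servings/day levels 0–1), fish-oil indicators carry
  MCAR missingness (default 15%) to exercise the impute-as-no-intake
  rule. The mediator (percent-of-total units, default mean 4.5, SD 1.2,
  clipped to a 0.5–15 physiological range) is a linear combination of a
  genotype main effect, the weighted diet index, the genotype×diet
  product, the confounder and Gaussian noise, with component sizes given
  as variance fractions; the interaction coefficient is sized against
  the *residualized* product so `v_gxd` is the partial fraction and the
  upstream Wald ncp at the causal variant is ≈ n·v_gxd. The outcome is
  generated multiplicatively, log-linear in the standardized mediator
  (default: mediator explains 0.9% of log-outcome variance), so the
  pipeline's log transform is the correct link and the raw outcome is
  right-skewed and strictly positive.

What this generator does *not* emulate: realistic human LD maps or
allele-frequency spectra, ancestry structure, relatedness, non-MCAR
missingness, or measurement-platform artifacts. Passing pipeline tests
therefore demonstrate algorithmic correctness and calibration under a
clean causal structure, not robustness to those real-data complications.

## GWIS pipeline

- **Outcome preparation.** Non-positive values are excluded, the rest
  log-transformed; the mean/SD of the log values are computed once and
  observations beyond 5 SD removed, with a per-observation report.
- **Derived exposure.** The mediator is regressed jointly on the four
  dietary sources (missing fish-oil reports imputed as zero intake);
  the exposure is the weight-combined source sum and carries the
  mediator's units. Zero-variance sources are dropped with a report.
- **Scan.** Per variant (MAF strictly > 0.01 on the analysis sample) and
  pathway, the design is intercept, dosage, exposure, product,
  covariates (categoricals expanded against the most frequent level;
  sentinel levels like "do not know" kept as ordinary levels);
  complete-case per regression; per-variant failures become
  missing-statistics rows, never fatal.
- **Clumping.** Greedy: smallest-p unassigned variant with
  p < 5×10⁻⁸ (configurable) seeds a clump and absorbs unassigned
  same-chromosome variants within 5,000 kb with dosage r² > 0.2; each
  variant joins at most one clump. Dosage (not hard-call) correlations
  are used.
- **Gene windows.** 1-based inclusive; + strand genes get
  [start−2,000, end+1,000], − strand genes the mirrored flanks.
- **Gene test.** Fisher's T = Σ −2·ln p per gene, referenced to a
  scaled chi-square matched to Brown's mean/variance under dependence;
  the covariance of the −2·ln p terms is the Brown polynomial evaluated
  at the squared dosage correlation, whose coefficients sum to 4 so
  duplicate variants saturate rather than double count, and the
  single-variant and zero-LD limits are exactly the identity and
  Fisher's combination. This is an intentionally transparent, principal
  components-free stand-in for gene-level enrichment; BH q-values are
  computed within each pathway separately.
- **Stratified summaries.** Dosages are hard-called by rounding, with
  calls in (0.4, 0.6) ∪ (1.4, 1.6) excluded as ambiguous (configurable);
  cells under a minimum count are suppressed with a report.
- **Sensitivity models.** Three expansions of the covariate set:
  exposure×PC products (10 PCs), genotype×covariate products for every
  covariate column, and BMI adjustment; the interaction term is retained
  and re-tested on the expanded design.

## Numerical and design choices

- Robust flavor HC0 by default (GWIS convention), HC1/HC3 selectable;
  rank deficiency is detected on X′X and reported with the collinear
  term names from pivoted QR.
- In the downstream regression both the main-effect and product slots
  hold the *measured* mediator (what an analyst observes); the spec of
  the design matrix is centralized so the literal alternative (true M in
  the main slot) is a one-line change via the role fields.
- Missing data: complete-case per regression, count reported.
- All randomness flows from one master seed through named/spawned
  substreams; identical config + seed reproduces every table
  byte-for-byte.
- Problem sizes in the test suite (e.g., 2,000–10,000 power replicates
  at n = 1,000; 200 replicates at n = 200,000; panels of 60–400 variants
  on 2,000–3,000 samples) were chosen to make Monte-Carlo error small
  against the tolerances being checked while keeping the default run at
  desk scale.

## Known limitations

- The non-centrality formula assumes an independent unit-variance
  modifier and additively coded genotype; it is an approximation when
  main effects are large or the modifier is non-Gaussian.
- Brown's method approximates the dependence of −2·ln p terms from
  pairwise dosage r² only; long-range haplotype structure beyond
  pairwise correlation is not modeled.
- The quasi-Bayesian intervals are percentile (not bias-corrected);
  with very small draw counts (the 20-draw default) they should be
  treated as indicative only.
- Binary outcomes, 2-df joint interaction tests, multi-variant polygenic
  DGPs and exposure–mediator interaction in the outcome model are out of
  scope.
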