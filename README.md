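# gxedecomp

Decomposed gene–environment interaction (GxE) testing for mediated
exposure–outcome pathways, with Monte-Carlo power simulation, linear
mediation analysis, and a miniature genome-wide interaction study (GWIS)
pipeline that runs entirely on synthetic cohorts.

## The problem

GxE discovery — finding variants G that modify an exposure–outcome
association — is chronically underpowered. When a molecular mediator M on
the causal path E → M → Y is measured (the motivating case: dietary
long-chain omega-3 intake → plasma omega-3 fraction → hsCRP, a log-scale
inflammatory biomarker), the overall modification can be decomposed into
two mechanistically distinct components, each tested in its own
regression with heteroscedasticity-robust (sandwich) Wald tests of the
product term:

```
standard:    Y ~ G + E + G·E  (+ covariates)
upstream:    M ~ G + E + G·E  (+ covariates)     # G modifies E → M
downstream:  Y ~ G + M + G·M  (+ covariates)     # G modifies M → Y
```

If the interaction truly acts on one leg of the pathway, the standard
test sees its signal attenuated by the strength of the other
(transmission) leg: the Wald non-centrality drops by the variance
fraction v(transmission) that the mediating main effect explains.
Testing the right leg directly recovers the full non-centrality

```
ncp = n · v_int · Var(G) / E[G²] / (1 − v_int),
```

for an uncentered-dosage product with an independent unit-variance
modifier, attenuated by the mediator's measurement reliability (its
intraclass correlation, ICC) when the measured mediator enters the test.
With a weak transmission leg (10% of variance) the decomposed tests are
~5× more powerful than the standard test at the same interaction size.

The package provides:

- `simulate` — the data-generating processes for upstream/downstream
  scenarios (variance-fraction parameterized, ICC measurement-error model);
- `regression` — OLS with HC0/HC1/HC3 sandwich covariance and the three
  pathway design builders;
- `power` — Monte-Carlo rejection rates over scenario grids plus the
  closed-form non-central chi-square oracle;
- `mediation` — Baron–Kenny product-of-coefficients decomposition (total
  effect, ACME, direct effect) with quasi-Bayesian percentile intervals
  and inconsistent-mediation flagging;
- `cohort` — a synthetic biobank-style generator (LD panel via a latent
  AR(1) Gaussian copula, dietary sources, confounders, a genotype×diet
  interaction on the mediator, a log-normal outcome) with recorded ground
  truth;
- `gwis` — the applied pipeline: 5-SD log outlier filter, derived
  weighted exposure, three-pathway scan, greedy LD clumping, strand-aware
  gene windows (2 kb upstream / 1 kb downstream), Brown's-method
  gene-level p-value combination, BH FDR per pathway, stratified
  summaries, and sensitivity-model covariate expansion;
- a thin CLI (`gxedecomp power-grid|mediate|synth-cohort|gwis|clump|gene-test|stratify`).

## Worked example

```python
from gxedecomp import (SimScenario, PowerConfig, estimate_power,
                       analytic_power, scenario_ncp)

sc = SimScenario("downstream", n=1000, maf=0.25,
                 v_interaction=0.005, v_transmit=0.10)
est = estimate_power(sc, config=PowerConfig(n_reps=1000, alpha=0.05, seed=42))
for pw, e in est.items():
    print(pw, round(e.power, 3), "analytic",
          round(analytic_power(scenario_ncp(sc, pw), 0.05), 3))
```

prints

```
standard 0.082 analytic 0.085
downstream 0.418 analytic 0.412
```

i.e., when a G×M interaction explains 0.5% of the outcome variance but E
explains only 10% of the mediator variance, the downstream test rejects
in ~42% of replicates at α=0.05 while the standard exposure–outcome test
rejects in ~8% — a ~5× power advantage, matching the analytic oracle.
The scripts in `examples/` walk through the other capabilities
(mediation decomposition, the full synthetic GWIS chain) with printed,
annotated output.

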