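"""Mediation decomposition on a synthetic diet -> biomarker -> inflammation cohort.

Builds a small synthetic cohort, derives the weighted dietary exposure from
its four source variables, and decomposes the exposure-outcome effect into
the average causal mediation effect (ACME, through the plasma mediator)
and the direct effect, with quasi-Bayesian percentile intervals.
"""

import numpy as np

from gxedecomp import (
    CohortConfig,
    derive_weighted_exposure,
    fit_mediation,
    generate_cohort,
    generate_variant_panel,
    prepare_outcome,
)
from gxedecomp.cohort import SOURCE_COLUMNS

panel = generate_variant_panel(n_samples=8000, n_variants=50, ld_rho=0.5, seed=1)
cohort, truth = generate_cohort(panel, CohortConfig(), seed=2)

log_y, removed = prepare_outcome(cohort["outcome_raw"])
cohort = cohort.loc[log_y.index]
print(f"outcome: log-transformed, {len(removed)} outliers/nonpositive removed")

weights, exposure, _ = derive_weighted_exposure(
    cohort[list(SOURCE_COLUMNS)], cohort["mediator_pct"]
)
print("derived exposure weights (per source):")
for name, w in weights.items():
    print(f"  {name:22s} {w:+.3f}")

res = fit_mediation(
    exposure.to_numpy(),
    cohort["mediator_pct"].to_numpy(),
    log_y.to_numpy(),
    n_draws=2000,
    seed=3,
)
print("\nmediation decomposition (standardized exposure and outcome):")
print(res.to_frame().round(4).to_string(index=False))
print(f"inconsistent mediation: {res.inconsistent}")
print(
    "\nACME is the product of the exposure->mediator and mediator->outcome "
    "path coefficients; total = direct + ACME exactly. A negative ACME here "
    "reflects the generative model: higher omega-3-like intake raises the "
    "plasma mediator, which lowers the log inflammatory marker."
)
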