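"""A miniature decomposed genome-wide interaction study, end to end.

Generates a synthetic cohort carrying a genotype x diet interaction on the
plasma mediator at one causal variant, runs the three-pathway interaction
scan, clumps the hits, combines variant p-values into gene-level tests,
and prints the stratified means that visualize the interaction.
"""

import numpy as np
import pandas as pd

from gxedecomp import (
    ClumpSpec,
    CohortConfig,
    GwisRoles,
    clump,
    derive_weighted_exposure,
    gene_enrichment,
    generate_cohort,
    generate_variant_panel,
    map_variants_to_genes,
    prepare_outcome,
    run_gwis,
    stratified_summary,
)
from gxedecomp.cohort import SOURCE_COLUMNS

panel = generate_variant_panel(n_samples=4000, n_variants=60, ld_rho=0.8, seed=10)
cohort, truth = generate_cohort(panel, CohortConfig(v_gxd=0.008), seed=11)
print(f"causal variant: {truth.causal_variant} "
      f"(interaction explains {truth.v_gxd:.1%} of mediator variance)")

log_y, _ = prepare_outcome(cohort["outcome_raw"])
cohort = cohort.loc[log_y.index].copy()
cohort["log_outcome"] = log_y
_, cohort["exposure"], _ = derive_weighted_exposure(
    cohort[list(SOURCE_COLUMNS)], cohort["mediator_pct"]
)

records = run_gwis(panel, cohort, GwisRoles(covariates=("age", "sex")))
print("\nsmallest interaction p per pathway:")
for pw, sub in records.groupby("pathway"):
    top = sub.loc[sub["p_int"].idxmin()]
    print(f"  {pw:10s} {top['id']:>14s}  p_int = {top['p_int']:.2e}")

up = records[records["pathway"] == "upstream"]
clumps = clump(up, panel, ClumpSpec(p_threshold=1e-4))
print(f"\nclumping (p<1e-4, r2>0.2): {int(clumps['is_index'].sum())} clump(s), "
      f"{len(clumps)} variant(s) assigned")

# three mock genes tiling the causal chromosome
vm = panel.variant_map
chrom = vm.set_index("id").loc[truth.causal_variant, "chrom"]
sub = vm[vm["chrom"] == chrom]["pos"]
genes = pd.DataFrame(
    {
        "gene_id": ["GENE_A", "GENE_B", "GENE_C"],
        "chrom": chrom,
        "start": np.linspace(sub.min(), sub.max(), 4)[:3].astype(int),
        "end": np.linspace(sub.min(), sub.max(), 4)[1:].astype(int),
        "strand": ["+", "-", "+"],
    }
)
assignments = map_variants_to_genes(vm, genes)
gene_table = gene_enrichment(up, assignments, panel)
print("\ngene-level enrichment (upstream pathway, Brown's method + BH):")
print(gene_table.round(6).to_string(index=False))

strat = stratified_summary(
    cohort, panel.column(truth.causal_variant)[log_y.index.to_numpy()], "oily_fish"
)
print("\nmean mediator by genotype x oily-fish intake (servings/day):")
print(strat.pivot(index="exposure_level", columns="genotype", values="mean_mediator")
      .round(3).to_string())
print(
    "\nthe intake-mediator slope steepens with dosage at the causal variant — "
    "the signature of an upstream interaction, detected by the upstream scan "
    "but invisible to the standard exposure-outcome test."
)
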