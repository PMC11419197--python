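"""Pipeline operations: phenotype prep, derived exposure, scan, clumping,
gene windows, LD-aware gene combination, FDR, stratification, sensitivity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxedecomp import (
    ClumpSpec,
    GwisRoles,
    VariantPanel,
    apply_sensitivity_spec,
    bh_fdr,
    clump,
    derive_weighted_exposure,
    gene_enrichment,
    map_variants_to_genes,
    prepare_outcome,
    run_gwis,
    stratified_summary,
)
from gxedecomp.gwis import InsufficientDataError
from gxedecomp.regression import SingularDesignError
from gxedecomp.simulate import ParameterError


# ---------------------------------------------------------------- outcome prep
class TestPrepareOutcome:
    def test_constant_values_keep_everything(self):
        kept, report = prepare_outcome(np.full(10, 3.0))
        assert len(kept) == 10
        assert report.empty

    def test_single_extreme_value_removed(self):
        rng = np.random.default_rng(0)
        values = np.exp(rng.standard_normal(100))
        contaminated = np.append(values, np.exp(8.0))
        kept, report = prepare_outcome(contaminated)
        assert len(kept) == 100
        assert list(report["id"]) == [100]
        assert (report["reason"] == "outlier").all()

    def test_exp_round_trips_when_nothing_removed(self):
        rng = np.random.default_rng(1)
        values = np.exp(rng.standard_normal(50) * 0.5)
        kept, report = prepare_outcome(values)
        assert report.empty
        np.testing.assert_allclose(np.exp(kept.to_numpy()), values)

    def test_nonpositive_excluded_before_log(self):
        kept, report = prepare_outcome(np.array([1.0, 2.0, 3.0, 0.0, -1.0]))
        assert len(kept) == 3
        assert set(report["reason"]) == {"nonpositive_or_missing"}

    def test_too_few_positive_rejected(self):
        with pytest.raises(InsufficientDataError):
            prepare_outcome(np.array([1.0, -1.0, 0.0]))


# ------------------------------------------------------------ derived exposure
class TestDerivedExposure:
    def _sources(self, rng, n=5000):
        return pd.DataFrame(
            {
                "oily_fish": rng.choice([0, 0.14, 0.43, 1.0], n),
                "nonoily_fish": rng.choice([0, 0.14, 0.43], n),
                "fishoil_touchscreen": rng.integers(0, 2, n).astype(float),
                "fishoil_interview": rng.integers(0, 2, n).astype(float),
            }
        )

    def test_single_source_dependency(self, rng):
        src = self._sources(rng)
        mediator = 2.0 * src["oily_fish"] + rng.standard_normal(len(src)) * 0.1
        weights, exposure, dropped = derive_weighted_exposure(src, mediator)
        assert weights["oily_fish"] == pytest.approx(2.0, abs=0.05)
        for other in ("nonoily_fish", "fishoil_touchscreen", "fishoil_interview"):
            assert weights[other] == pytest.approx(0.0, abs=0.05)
        assert np.corrcoef(exposure, src["oily_fish"])[0, 1] > 0.99
        assert dropped.empty

    def test_recovers_generative_weights(self, interaction_cohort):
        cohort, truth = interaction_cohort
        weights, _, _ = derive_weighted_exposure(
            cohort[list(truth.source_weights)], cohort["mediator_pct"]
        )
        true_w = np.array([truth.source_weights[c] for c in weights.index])
        assert np.corrcoef(weights.to_numpy(), true_w)[0, 1] > 0.95

    def test_missing_fishoil_imputed_as_no_intake(self, rng):
        src = self._sources(rng, 2000)
        mediator = src.sum(axis=1) + rng.standard_normal(2000) * 0.5
        src_missing = src.copy()
        mask = rng.random(2000) < 0.3
        src_missing.loc[mask, "fishoil_touchscreen"] = np.nan
        weights, exposure, _ = derive_weighted_exposure(src_missing, mediator)
        # exposure defined for every sample, using 0 where the report is missing
        assert np.isfinite(exposure).all()
        imputed = src_missing.fillna({"fishoil_touchscreen": 0.0})
        np.testing.assert_allclose(
            exposure, imputed.to_numpy() @ weights.to_numpy(), atol=1e-10
        )

    def test_entirely_missing_column_dropped_with_report(self, rng):
        src = self._sources(rng, 500)
        src["fishoil_interview"] = np.nan
        mediator = src["oily_fish"] + rng.standard_normal(500)
        weights, _, dropped = derive_weighted_exposure(src, mediator)
        assert "fishoil_interview" not in weights.index
        assert list(dropped["column"]) == ["fishoil_interview"]

    def test_collinear_sources_rejected(self, rng):
        src = self._sources(rng, 500)
        src["nonoily_fish"] = 2.0 * src["oily_fish"]
        with pytest.raises(SingularDesignError):
            derive_weighted_exposure(src, rng.standard_normal(500))

    def test_fewer_than_four_sources_rejected(self, rng):
        with pytest.raises(ParameterError):
            derive_weighted_exposure(
                pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]}), np.ones(2)
            )


# ------------------------------------------------------------------- the scan
def _prepared(cohort, truth):
    log_y, _ = prepare_outcome(cohort["outcome_raw"])
    out = cohort.loc[log_y.index].copy()
    out["log_outcome"] = log_y
    _, exposure, _ = derive_weighted_exposure(
        out[list(truth.source_weights)], out["mediator_pct"]
    )
    out["exposure"] = exposure
    return out


class TestRunGwis:
    def test_upstream_signal_invisible_to_other_pathways(
        self, small_panel, interaction_cohort
    ):
        """The decomposition signature: an upstream-only causal interaction is
        detected by the upstream test and missed by standard/downstream."""
        cohort, truth = interaction_cohort
        data = _prepared(cohort, truth)
        rec = run_gwis(small_panel, data, GwisRoles(covariates=("age", "sex")))
        at_causal = rec[rec["id"] == truth.causal_variant].set_index("pathway")
        assert at_causal.loc["upstream", "p_int"] < 1e-4
        assert at_causal.loc["upstream", "p_int"] < at_causal.loc["standard", "p_int"]
        assert at_causal.loc["upstream", "p_int"] < at_causal.loc["downstream", "p_int"]
        # genome-wide minimum for upstream sits at the causal locus or an LD partner
        up = rec[rec["pathway"] == "upstream"]
        top = up.loc[up["p_int"].idxmin()]
        causal_pos = small_panel.variant_map.set_index("id").loc[truth.causal_variant]
        assert top["chrom"] == causal_pos["chrom"]

    def test_null_cohort_calibrated(self, small_panel, null_cohort):
        cohort, truth = null_cohort
        data = _prepared(cohort, truth)
        rec = run_gwis(small_panel, data, GwisRoles())
        for pw, sub in rec.groupby("pathway"):
            frac = (sub["p_int"] < 0.05).mean()
            assert frac < 0.25  # 60 LD-correlated variants; coarse bound
        assert rec["p_int"].between(0, 1).all()

    def test_single_variant_panel_matches_direct_fit(self, small_panel, null_cohort):
        from gxedecomp.regression import PathwaySpec, build_pathway_design, fit_ols_robust

        cohort, truth = null_cohort
        data = _prepared(cohort, truth)
        vid = small_panel.variant_map["id"].iloc[3]
        single = VariantPanel(
            dosages=small_panel.dosages[:, [3]],
            variant_map=small_panel.variant_map.iloc[[3]].reset_index(drop=True),
            sample_ids=small_panel.sample_ids,
        )
        rec = run_gwis(single, data, GwisRoles(), pathways=("upstream",))
        design, labels, yv = build_pathway_design(
            {
                "g": small_panel.dosages[:, 3],
                "exposure": data["exposure"].to_numpy(),
                "mediator_pct": data["mediator_pct"].to_numpy(),
            },
            PathwaySpec("upstream", outcome_role="mediator_pct", exposure_role="exposure"),
        )
        ref = fit_ols_robust(design, yv, term_names=labels)
        assert rec["p_int"].iloc[0] == pytest.approx(
            ref.p[ref.term("g:exposure")], rel=1e-10
        )

    def test_maf_filter_is_strict(self, null_cohort):
        cohort, truth = null_cohort
        data = _prepared(cohort, truth)
        n = len(data)
        rare = np.zeros(n)
        rare[: int(0.008 * 2 * n)] = 1.0  # MAF 0.008 < 0.01
        common = np.random.default_rng(0).binomial(2, 0.3, n).astype(float)
        panel = VariantPanel(
            dosages=np.column_stack([rare, common]),
            variant_map=pd.DataFrame(
                {
                    "id": ["rare", "common"],
                    "chrom": ["1", "1"],
                    "pos": [100, 200],
                    "ref": ["A", "A"],
                    "alt": ["G", "G"],
                    "maf": [0.008, 0.3],
                }
            ),
            sample_ids=[f"S{i}" for i in range(n)],
        )
        rec = run_gwis(panel, data, GwisRoles(), pathways=("standard",))
        assert set(rec["id"]) == {"common"}


# ------------------------------------------------------------------- clumping
def _toy_panel(columns, positions, chroms=None, ids=None):
    k = len(positions)
    chroms = chroms or ["1"] * k
    ids = ids or [f"v{i}" for i in range(k)]
    n = columns.shape[0]
    return VariantPanel(
        dosages=columns,
        variant_map=pd.DataFrame(
            {
                "id": ids, "chrom": chroms, "pos": positions,
                "ref": ["A"] * k, "alt": ["G"] * k,
                "maf": columns.mean(axis=0) / 2,
            }
        ),
        sample_ids=[f"S{i}" for i in range(n)],
    )


def _records(ids, chroms, positions, pvals, pathway="upstream"):
    return pd.DataFrame(
        {
            "id": ids, "chrom": chroms, "pos": positions, "p_int": pvals,
            "pathway": pathway,
        }
    )


class TestClump:
    def test_no_significant_records_gives_empty_list(self, rng):
        cols = rng.binomial(2, 0.3, (200, 2)).astype(float)
        panel = _toy_panel(cols, [100, 200])
        out = clump(_records(["v0", "v1"], ["1", "1"], [100, 200], [1e-6, 0.5]), panel)
        assert out.empty

    def test_correlated_pair_forms_one_clump_with_smaller_p_index(self, rng):
        g = rng.binomial(2, 0.3, 500).astype(float)
        noisy = g.copy()
        flip = rng.random(500) < 0.05
        noisy[flip] = rng.binomial(2, 0.3, flip.sum())
        cols = np.column_stack([g, noisy])
        r2 = np.corrcoef(g, noisy)[0, 1] ** 2
        assert r2 > 0.8
        panel = _toy_panel(cols, [10_000, 20_000])
        out = clump(
            _records(["v0", "v1"], ["1", "1"], [10_000, 20_000], [1e-8, 1e-9]), panel
        )
        assert int(out["is_index"].sum()) == 1
        assert out.loc[out["is_index"], "id"].iloc[0] == "v1"  # smaller p
        assert set(out["id"]) == {"v0", "v1"}

    def test_different_chromosomes_never_clump(self, rng):
        g = rng.binomial(2, 0.3, 500).astype(float)
        cols = np.column_stack([g, g])  # r^2 = 1 but on different chromosomes
        panel = _toy_panel(cols, [100, 100], chroms=["1", "2"])
        out = clump(_records(["v0", "v1"], ["1", "2"], [100, 100], [1e-9, 1e-9]), panel)
        assert int(out["is_index"].sum()) == 2

    def test_radius_limits_assignment(self, rng):
        g = rng.binomial(2, 0.3, 500).astype(float)
        cols = np.column_stack([g, g])
        panel = _toy_panel(cols, [100, 100 + 6_000_000])  # 6 Mb apart > 5,000 kb
        out = clump(
            _records(["v0", "v1"], ["1", "1"], [100, 6_000_100], [1e-9, 1e-8]), panel
        )
        assert int(out["is_index"].sum()) == 2

    def test_unknown_variant_raises(self, rng):
        cols = rng.binomial(2, 0.3, (100, 1)).astype(float)
        panel = _toy_panel(cols, [100])
        with pytest.raises(KeyError):
            clump(_records(["missing"], ["1"], [100], [1e-9]), panel)


# ---------------------------------------------------------------- gene windows
GENES = pd.DataFrame(
    {
        "gene_id": ["PLUS", "MINUS"],
        "chrom": ["1", "1"],
        "start": [10_000, 10_000],
        "end": [20_000, 20_000],
        "strand": ["+", "-"],
    }
)


class TestGeneWindows:
    @pytest.mark.parametrize(
        "pos,gene,expected",
        [
            (8_000, "PLUS", True),    # 10,000 - 2,000 boundary, inclusive
            (7_999, "PLUS", False),
            (21_000, "PLUS", True),   # 20,000 + 1,000
            (21_001, "PLUS", False),
            (22_000, "MINUS", True),  # mirrored flanks on - strand
            (22_001, "MINUS", False),
            (9_000, "MINUS", True),   # 10,000 - 1,000
            (8_999, "MINUS", False),
        ],
    )
    def test_strand_aware_boundaries(self, pos, gene, expected):
        vm = pd.DataFrame(
            {"id": ["v"], "chrom": ["1"], "pos": [pos], "ref": "A", "alt": "G", "maf": 0.3}
        )
        hits = map_variants_to_genes(vm, GENES[GENES["gene_id"] == gene])
        assert (len(hits) == 1) is expected

    def test_overlapping_genes_yield_multiple_assignments(self):
        vm = pd.DataFrame(
            {"id": ["v"], "chrom": ["1"], "pos": [15_000], "ref": "A", "alt": "G",
             "maf": 0.3}
        )
        hits = map_variants_to_genes(vm, GENES)
        assert sorted(hits["gene_id"]) == ["MINUS", "PLUS"]

    def test_unknown_strand_rejected(self):
        bad = GENES.assign(strand=["+", "*"])
        vm = pd.DataFrame(
            {"id": ["v"], "chrom": ["1"], "pos": [15_000], "ref": "A", "alt": "G",
             "maf": 0.3}
        )
        from gxedecomp.gwis import AnnotationError

        with pytest.raises(AnnotationError):
            map_variants_to_genes(vm, bad)


# --------------------------------------------------------------- gene combine
class TestGeneEnrichment:
    def _panel_and_assignments(self, cols, gene="G1"):
        k = cols.shape[1]
        panel = _toy_panel(cols, list(range(100, 100 + k)))
        assignments = pd.DataFrame(
            {"gene_id": [gene] * k, "id": [f"v{i}" for i in range(k)],
             "chrom": ["1"] * k, "pos": list(range(100, 100 + k)),
             "window_start": 0, "window_end": 10_000, "strand": "+"}
        )
        return panel, assignments

    def test_single_variant_gene_is_identity(self, rng):
        cols = rng.binomial(2, 0.3, (200, 1)).astype(float)
        panel, assign = self._panel_and_assignments(cols)
        rec = _records(["v0"], ["1"], [100], [0.0123])
        out = gene_enrichment(rec, assign, panel)
        assert out["p_gene"].iloc[0] == pytest.approx(0.0123, rel=1e-6)

    def test_independent_variants_reduce_to_fisher(self, rng):
        k = 5
        cols = rng.binomial(2, 0.3, (5000, k)).astype(float)
        panel, assign = self._panel_and_assignments(cols)
        pvals = [0.01, 0.2, 0.5, 0.03, 0.8]
        rec = _records([f"v{i}" for i in range(k)], ["1"] * k,
                       list(range(100, 100 + k)), pvals)
        out = gene_enrichment(rec, assign, panel)
        fisher = stats.chi2.sf(-2 * np.sum(np.log(pvals)), 2 * k)
        assert out["p_gene"].iloc[0] == pytest.approx(fisher, rel=0.25)

    def test_duplicate_variants_not_double_counted(self, rng):
        g = rng.binomial(2, 0.3, 300).astype(float)
        panel, assign = self._panel_and_assignments(np.column_stack([g, g]))
        rec = _records(["v0", "v1"], ["1", "1"], [100, 101], [0.02, 0.02])
        out = gene_enrichment(rec, assign, panel)
        assert out["p_gene"].iloc[0] == pytest.approx(0.02, rel=0.15)

    def test_null_gene_p_is_uniform_under_ld(self):
        """Gene p-values stay calibrated on a high-LD panel under the null."""
        rng = np.random.default_rng(77)
        from gxedecomp import generate_variant_panel
        from gxedecomp.regression import fit_ols_robust

        panel = generate_variant_panel(2000, 100, ld_rho=0.9, chromosomes=["1"], seed=5)
        n = panel.n_samples
        e = rng.standard_normal(n)
        y = rng.standard_normal(n)
        pvals = []
        for j in range(panel.n_variants):
            g = panel.dosages[:, j]
            X = np.column_stack([np.ones(n), g, e, g * e])
            pvals.append(fit_ols_robust(X, y).p[3])
        rec = pd.DataFrame(
            {"id": panel.variant_map["id"], "chrom": panel.variant_map["chrom"],
             "pos": panel.variant_map["pos"], "p_int": pvals, "pathway": "upstream"}
        )
        genes = pd.DataFrame(
            {"gene_id": [f"G{i}" for i in range(20)], "chrom": "1",
             "start": [panel.variant_map["pos"].iloc[i * 5] for i in range(20)],
             "end": [panel.variant_map["pos"].iloc[i * 5 + 4] for i in range(20)],
             "strand": "+"}
        )
        assign = map_variants_to_genes(panel.variant_map, genes)
        out = gene_enrichment(rec, assign, panel)
        assert stats.kstest(out["p_gene"], "uniform").pvalue > 0.01

    def test_unscored_assigned_variant_raises(self, rng):
        cols = rng.binomial(2, 0.3, (100, 2)).astype(float)
        panel, assign = self._panel_and_assignments(cols)
        rec = _records(["v0"], ["1"], [100], [0.1])
        with pytest.raises(KeyError):
            gene_enrichment(rec, assign, panel)


# ----------------------------------------------------------------------- FDR
class TestBhFdr:
    def test_single_p_is_its_own_q(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.037])), [0.037])

    def test_step_up_on_arithmetic_sequence(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_q_monotone_in_sorted_p(self, rng):
        p = rng.random(50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ParameterError):
            bh_fdr(np.array([0.5, 1.2]))


# -------------------------------------------------------------- stratification
class TestStratifiedSummary:
    def test_constant_mediator_gives_equal_means(self, rng):
        n = 600
        cohort = pd.DataFrame(
            {"oily_fish": rng.choice([0.0, 0.5, 1.0], n), "mediator_pct": 4.2}
        )
        dos = rng.binomial(2, 0.4, n).astype(float)
        out = stratified_summary(cohort, dos, "oily_fish")
        assert np.allclose(out.loc[~out["suppressed"], "mean_mediator"], 4.2)

    def test_interaction_steepens_slope_in_alt_homozygotes(
        self, small_panel, interaction_cohort
    ):
        cohort, truth = interaction_cohort
        dos = small_panel.column(truth.causal_variant)
        out = stratified_summary(cohort, dos, "oily_fish", min_count=3)

        def slope(gcall):
            sub = out[(out["genotype"] == gcall) & ~out["suppressed"]]
            return np.polyfit(sub["exposure_level"].astype(float), sub["mean_mediator"], 1)[0]

        # gamma_gxd > 0: mediator-vs-intake slope grows with dosage
        assert np.sign(slope(2) - slope(0)) == np.sign(truth.gamma_gxd)

    def test_uncertain_dosages_excluded(self, rng):
        cohort = pd.DataFrame({"oily_fish": [0.0] * 6, "mediator_pct": 1.0})
        dos = np.array([0.0, 0.5, 1.0, 1.45, 2.0, 0.1])
        out = stratified_summary(cohort, dos, "oily_fish", min_count=1)
        assert out["n"].sum() == 4  # 0.5 and 1.45 fall in the uncertain bands

    def test_unobserved_genotype_absent(self, rng):
        cohort = pd.DataFrame({"oily_fish": [0.0] * 50, "mediator_pct": 1.0})
        dos = np.zeros(50)  # no heterozygotes or alt homozygotes
        out = stratified_summary(cohort, dos, "oily_fish", min_count=1)
        assert set(out["genotype"]) == {0}

    def test_empty_stratification_rejected(self):
        cohort = pd.DataFrame({"oily_fish": [np.nan], "mediator_pct": [1.0]})
        with pytest.raises(ParameterError):
            stratified_summary(cohort, np.array([np.nan]), "oily_fish")


# ------------------------------------------------------------------ sensitivity
class TestSensitivity:
    def test_pc_exposure_mode_adds_ten_columns(self, interaction_cohort):
        cohort, _ = interaction_cohort
        g = np.zeros(len(cohort))
        out, cov = apply_sensitivity_spec(
            cohort, g, "oily_fish", ["age", "sex"], "gpc_exposure_interactions"
        )
        assert len(cov) == 12
        assert sum(c.startswith("oily_fish:pc") for c in cov) == 10

    def test_bmi_mode_with_independent_bmi_barely_moves_z(
        self, small_panel, interaction_cohort
    ):
        from gxedecomp.regression import PathwaySpec, build_pathway_design, fit_ols_robust

        cohort, truth = interaction_cohort
        g = small_panel.column(truth.causal_variant)
        data = {
            "g": g,
            "oily_fish": cohort["oily_fish"].to_numpy(),
            "mediator_pct": cohort["mediator_pct"].to_numpy(),
        }
        spec = PathwaySpec("upstream", outcome_role="mediator_pct", exposure_role="oily_fish")
        d0, l0, y0 = build_pathway_design(data, spec)
        z0 = fit_ols_robust(d0, y0, term_names=l0).z[3]
        _, cov = apply_sensitivity_spec(cohort, g, "oily_fish", [], "bmi_adjustment")
        d1, l1, y1 = build_pathway_design(
            data, spec, covariates=cohort[cov], covariate_names=cov
        )
        z1 = fit_ols_robust(d1, y1, term_names=l1).z[3]
        assert abs(z1 - z0) < 0.1

    def test_pc_confounded_interaction_attenuates_under_mode_one(self):
        """Signal carried by a PC x exposure term disappears once adjusted."""
        from gxedecomp.regression import fit_ols_robust

        rng = np.random.default_rng(42)
        n = 8000
        g = rng.binomial(2, 0.3, n).astype(float)
        e = rng.standard_normal(n)
        pc1 = 0.5 * g + rng.standard_normal(n)  # PC correlated with genotype
        cohort = pd.DataFrame({f"pc{i}": rng.standard_normal(n) for i in range(2, 11)})
        cohort["pc1"] = pc1
        cohort["e"] = e
        y = 0.1 * pc1 * e + rng.standard_normal(n)
        base = fit_ols_robust(
            np.column_stack([np.ones(n), g, e, g * e]), y, term_names=["c", "g", "e", "g:e"]
        )
        out, cov = apply_sensitivity_spec(cohort, g, "e", [], "gpc_exposure_interactions")
        adj = fit_ols_robust(
            np.column_stack([np.ones(n), g, e, g * e, out[cov].to_numpy()]),
            y,
            term_names=["c", "g", "e", "g:e", *cov],
        )
        assert abs(base.z[3]) > 2.0  # confounded signal looks significant
        assert abs(adj.z[3]) < abs(base.z[3]) / 2

    def test_genotype_covariate_mode_expands_all_covariates(self, interaction_cohort):
        cohort, _ = interaction_cohort
        g = np.ones(len(cohort))
        out, cov = apply_sensitivity_spec(
            cohort, g, "oily_fish", ["age", "smoking"], "genotype_covariate_interactions"
        )
        assert any(c.startswith("g:age") for c in cov)
        assert any(c.startswith("g:smoking[") for c in cov)

    def test_missing_columns_rejected(self, rng):
        cohort = pd.DataFrame({"e": rng.standard_normal(10)})
        with pytest.raises(KeyError):
            apply_sensitivity_spec(cohort, np.zeros(10), "e", [], "bmi_adjustment")
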