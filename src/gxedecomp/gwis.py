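"""Decomposed genome-wide interaction study (GWIS) pipeline.

Phenotype preparation (log transform + 5-SD outlier filter), derived
weighted exposure construction, the three-pathway per-variant interaction
scan with robust SEs, greedy LD clumping, strand-aware gene-window
mapping, an LD-aware gene-level p-value combination (Brown's method),
Benjamini-Hochberg FDR per pathway, genotype x exposure stratified
summaries, and sensitivity-model covariate expansion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import VariantPanel
from .regression import (
    PathwaySpec,
    Pathway,
    SingularDesignError,
    build_pathway_design,
    fit_ols_robust,
)
from .simulate import ParameterError

__all__ = [
    "ClumpSpec",
    "GwisRoles",
    "prepare_outcome",
    "derive_weighted_exposure",
    "run_gwis",
    "clump",
    "map_variants_to_genes",
    "gene_enrichment",
    "bh_fdr",
    "stratified_summary",
    "apply_sensitivity_spec",
    "GENOME_WIDE_P",
]

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8


class InsufficientDataError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class ClumpSpec:
    """Greedy clumping thresholds (PLINK-style defaults)."""

    p_threshold: float = GENOME_WIDE_P
    r2_threshold: float = 0.2
    radius_kb: float = 5000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold <= 1.0:
            raise ParameterError("p_threshold must lie in (0, 1]")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ParameterError("r2_threshold must lie in [0, 1]")
        if self.radius_kb <= 0:
            raise ParameterError("radius_kb must be positive")


@dataclass(frozen=True)
class GwisRoles:
    """Column roles mapping cohort columns to the three pathway regressions.

    ``outcome`` is the prepared (log-scale) outcome, ``exposure`` the
    derived dietary exposure, ``mediator`` the measured plasma mediator.
    """

    outcome: str = "log_outcome"
    exposure: str = "exposure"
    mediator: str = "mediator_pct"
    covariates: tuple[str, ...] = ()


def prepare_outcome(
    values: pd.Series | np.ndarray, sd_limit: float = 5.0
) -> tuple[pd.Series, pd.DataFrame]:
    """Log-transform a positive biomarker and drop extreme outliers.

    Non-positive values are excluded (reported) before the log.  The
    mean and SD of the log values are computed once on all loggable
    values; observations more than ``sd_limit`` SDs from that mean are
    removed.  Returns (retained log values indexed like the input,
    removal report with columns id/value/reason).
    """
    s = pd.Series(values).astype(float)
    if s.index.duplicated().any():
        s = s.reset_index(drop=True)
    report_rows: list[dict[str, object]] = []
    nonpos = s.index[(~(s > 0)) | s.isna()]
    for i in nonpos:
        report_rows.append({"id": i, "value": s.loc[i], "reason": "nonpositive_or_missing"})
    pos = s.drop(nonpos)
    if len(pos) < 3:
        raise InsufficientDataError("fewer than 3 positive values")
    logv = np.log(pos)
    mu, sd = float(logv.mean()), float(logv.std(ddof=1))
    dev = (logv - mu).abs()
    out = logv.index[dev > sd_limit * sd]
    for i in out:
        report_rows.append({"id": i, "value": s.loc[i], "reason": "outlier"})
    kept = logv.drop(out)
    report = pd.DataFrame(report_rows, columns=["id", "value", "reason"])
    return kept, report


def derive_weighted_exposure(
    sources: pd.DataFrame,
    mediator: pd.Series | np.ndarray,
    impute_zero: Sequence[str] = ("fishoil_touchscreen", "fishoil_interview"),
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Weight dietary sources by their joint association with the mediator.

    Missing values in the ``impute_zero`` columns (fish-oil reports) are
    treated as "no intake" (0) before the regression and when forming the
    weighted sum.  Weights are the multivariable OLS coefficients of the
    mediator on all sources jointly (no covariates); the derived exposure
    is ``sources @ weights`` and carries the mediator's units.
    Zero-variance columns (e.g., a fish-oil variable that is entirely
    missing and imputed to zeros) are dropped with a report.

    Returns (weights, exposure, dropped-column report).
    """
    if sources.shape[1] < 4:
        raise ParameterError("at least 4 source columns required")
    src = sources.copy().astype(float)
    for col in impute_zero:
        if col in src:
            src[col] = src[col].fillna(0.0)
    med = pd.Series(np.asarray(mediator, dtype=float), index=src.index)
    dropped = []
    for col in list(src.columns):
        if src[col].std(ddof=1) == 0.0 or src[col].isna().all():
            dropped.append({"column": col, "reason": "zero_variance"})
            src = src.drop(columns=col)
    if src.empty:
        raise SingularDesignError("all source columns degenerate")
    mask = src.notna().all(axis=1) & med.notna()
    x = np.column_stack([np.ones(mask.sum()), src.loc[mask].to_numpy()])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise SingularDesignError("source columns are collinear")
    coef, *_ = np.linalg.lstsq(x, med.loc[mask].to_numpy(), rcond=None)
    weights = pd.Series(coef[1:], index=src.columns, name="weight")
    exposure = pd.Series(src.to_numpy() @ weights.to_numpy(), index=sources.index,
                         name="exposure")
    return weights, exposure, pd.DataFrame(dropped, columns=["column", "reason"])


def _covariate_matrix(
    cohort: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Numeric covariates pass through; object/categorical columns expand to
    indicators with the most frequent level as reference."""
    from .regression import expand_categorical

    cols: list[np.ndarray] = []
    names: list[str] = []
    for c in covariates:
        s = cohort[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            ind = expand_categorical(s, c)
            for k in ind.columns:
                cols.append(ind[k].to_numpy(float))
                names.append(k)
        else:
            cols.append(s.to_numpy(float))
            names.append(c)
    if not cols:
        return np.empty((len(cohort), 0)), []
    return np.column_stack(cols), names


def run_gwis(
    panel: VariantPanel,
    cohort: pd.DataFrame,
    roles: GwisRoles,
    pathways: Sequence[Pathway] = ("standard", "upstream", "downstream"),
    maf_min: float = 0.01,
    se_type: str = "HC0",
) -> pd.DataFrame:
    """Per-variant, per-pathway interaction scan.

    For each variant passing the MAF filter (computed on the analysis
    sample, strict ``> maf_min``) and each requested pathway, fits
    outcome ~ g + exposure + g*exposure + covariates with robust SEs and
    records the product-term statistics.  Per-variant failures are logged
    and emitted as missing-statistics rows.
    """
    cmat, cnames = _covariate_matrix(cohort, roles.covariates)
    role_cols = {
        "standard": (roles.outcome, roles.exposure),
        "upstream": (roles.mediator, roles.exposure),
        "downstream": (roles.outcome, roles.mediator),
    }
    rows: list[dict[str, object]] = []
    for j in range(panel.n_variants):
        meta = panel.variant_map.iloc[j]
        dos = panel.dosages[:, j]
        ok = np.isfinite(dos)
        af = np.nanmean(dos) / 2.0
        maf = min(af, 1.0 - af)
        if not maf > maf_min:
            continue
        for pw in pathways:
            ycol, ecol = role_cols[pw]
            base = {
                "id": meta["id"],
                "chrom": meta["chrom"],
                "pos": int(meta["pos"]),
                "ref": meta["ref"],
                "alt": meta["alt"],
                "af": af,
                "maf": maf,
                "pathway": pw,
            }
            try:
                data = {
                    "g": np.where(ok, dos, np.nan),
                    ecol: cohort[ecol].to_numpy(float),
                    ycol: cohort[ycol].to_numpy(float),
                }
                spec = PathwaySpec(pathway=pw, outcome_role=ycol, exposure_role=ecol)
                design, labels, yv = build_pathway_design(
                    data, spec, covariates=cmat, covariate_names=cnames
                )
                fit = fit_ols_robust(design, yv, se_type=se_type, term_names=labels)
                t = fit.term(f"g:{ecol}")
                rows.append(
                    {
                        **base,
                        "beta_int": fit.beta[t],
                        "se_robust": fit.se_robust[t],
                        "z": fit.z[t],
                        "p_int": fit.p[t],
                        "n_used": fit.n_used,
                        "genome_wide": bool(fit.p[t] < GENOME_WIDE_P),
                        "error": "",
                    }
                )
            except Exception as exc:
                logger.warning("variant %s pathway %s failed: %s", meta["id"], pw, exc)
                rows.append(
                    {
                        **base,
                        "beta_int": np.nan,
                        "se_robust": np.nan,
                        "z": np.nan,
                        "p_int": np.nan,
                        "n_used": 0,
                        "genome_wide": False,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)


def clump(
    records: pd.DataFrame, panel_ref: VariantPanel, spec: ClumpSpec = ClumpSpec()
) -> pd.DataFrame:
    """Greedy LD clumping of one pathway's records.

    Repeatedly takes the smallest-p unassigned variant with
    ``p < p_threshold`` as an index, and assigns to it every unassigned
    variant on the same chromosome within ``radius_kb`` whose squared
    Pearson dosage correlation with the index (computed on the reference
    panel) exceeds ``r2_threshold``.  Each variant joins at most one
    clump.  Returns a table with columns id/chrom/pos/p_int/index_id.
    """
    rec = records.dropna(subset=["p_int"]).copy()
    id_to_col: dict[str, int] = {}
    for vid in rec["id"]:
        idx = panel_ref.variant_map.index[panel_ref.variant_map["id"] == vid]
        if len(idx) == 0:
            raise KeyError(f"variant {vid!r} in records but absent from reference panel")
        id_to_col[vid] = int(idx[0])

    rec = rec.sort_values(["p_int", "chrom", "pos"], kind="stable").reset_index(drop=True)
    assigned: dict[str, str] = {}
    out_rows: list[dict[str, object]] = []
    radius_bp = spec.radius_kb * 1000.0
    for _, row in rec.iterrows():
        vid = row["id"]
        if vid in assigned or not row["p_int"] < spec.p_threshold:
            continue
        assigned[vid] = vid
        out_rows.append(
            {"id": vid, "chrom": row["chrom"], "pos": row["pos"],
             "p_int": row["p_int"], "index_id": vid, "is_index": True}
        )
        x = panel_ref.dosages[:, id_to_col[vid]]
        near = rec[
            (rec["chrom"] == row["chrom"])
            & (~rec["id"].isin(assigned))
            & ((rec["pos"] - row["pos"]).abs() <= radius_bp)
        ]
        for _, other in near.iterrows():
            y = panel_ref.dosages[:, id_to_col[other["id"]]]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue
            r2 = float(np.corrcoef(x[ok], y[ok])[0, 1]) ** 2
            if r2 > spec.r2_threshold:
                assigned[other["id"]] = vid
                out_rows.append(
                    {"id": other["id"], "chrom": other["chrom"], "pos": other["pos"],
                     "p_int": other["p_int"], "index_id": vid, "is_index": False}
                )
    return pd.DataFrame(
        out_rows, columns=["id", "chrom", "pos", "p_int", "index_id", "is_index"]
    )


def map_variants_to_genes(
    variant_map: pd.DataFrame,
    genes: pd.DataFrame,
    upstream_kb: float = 2.0,
    downstream_kb: float = 1.0,
) -> pd.DataFrame:
    """Assign variants to strand-aware gene windows (1-based inclusive).

    For + strand genes the window is [start - upstream_kb*1000,
    end + downstream_kb*1000]; for - strand genes the flanks swap.  A
    variant may map to multiple overlapping genes.  Gene table columns:
    gene_id, chrom, start, end, strand.
    """
    up, down = upstream_kb * 1000.0, downstream_kb * 1000.0
    rows: list[dict[str, object]] = []
    for _, gene in genes.iterrows():
        strand = str(gene["strand"])
        if strand == "+":
            w0, w1 = gene["start"] - up, gene["end"] + down
        elif strand == "-":
            w0, w1 = gene["start"] - down, gene["end"] + up
        else:
            raise AnnotationError(
                f"unknown strand {strand!r} for gene {gene['gene_id']!r}"
            )
        sub = variant_map[
            (variant_map["chrom"].astype(str) == str(gene["chrom"]))
            & (variant_map["pos"] >= w0)
            & (variant_map["pos"] <= w1)
        ]
        for _, v in sub.iterrows():
            rows.append(
                {
                    "gene_id": gene["gene_id"],
                    "id": v["id"],
                    "chrom": v["chrom"],
                    "pos": v["pos"],
                    "window_start": int(w0),
                    "window_end": int(w1),
                    "strand": strand,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "id", "chrom", "pos", "window_start", "window_end", "strand"],
    )


# Brown's covariance polynomial evaluated at the squared dosage correlation;
# the coefficients sum to 4.0, so two perfectly correlated tests contribute
# the full Var(-2 ln p) = 4 and duplicates are not double counted.
def _brown_cov(r2: float) -> float:
    r2 = float(np.clip(r2, 0.0, 1.0))
    return 3.263 * r2 + 0.710 * r2**2 + 0.027 * r2**3


def gene_enrichment(
    records: pd.DataFrame,
    assignments: pd.DataFrame,
    panel_ref: VariantPanel,
) -> pd.DataFrame:
    """LD-aware gene-level combination of interaction p-values.

    Per gene, Fisher's statistic T = sum(-2 ln p) over member variants is
    referenced against a scaled chi-square (gamma) null whose mean/variance
    are corrected for dependence via Brown's method, with the covariance of
    the -2 ln p terms approximated from the pairwise squared dosage
    correlation on the reference panel.  With a single variant the gene p
    equals the variant p; with independent variants it reduces to Fisher's
    combination.  Adds BH q-values across genes (call per pathway).
    """
    pmap = dict(zip(records["id"], records["p_int"]))
    rows: list[dict[str, object]] = []
    for gene_id, sub in assignments.groupby("gene_id", sort=True):
        vids = [v for v in sub["id"] if v in pmap and np.isfinite(pmap[v])]
        if not vids:
            logger.warning("gene %s has no scored variants; omitted", gene_id)
            continue
        missing = [v for v in sub["id"] if v not in pmap]
        if missing:
            raise KeyError(f"variants {missing} assigned to {gene_id} lack p-values")
        p = np.array([pmap[v] for v in vids])
        k = len(p)
        t_stat = float(np.sum(-2.0 * np.log(np.clip(p, 1e-300, 1.0))))
        mean_t = 2.0 * k
        var_t = 4.0 * k
        if k > 1:
            cols = [panel_ref.column(v) for v in vids]
            for i in range(k):
                for j in range(i + 1, k):
                    ok = np.isfinite(cols[i]) & np.isfinite(cols[j])
                    if ok.sum() < 3:
                        continue
                    sx, sy = np.std(cols[i][ok]), np.std(cols[j][ok])
                    if sx == 0 or sy == 0:
                        continue
                    r = float(np.corrcoef(cols[i][ok], cols[j][ok])[0, 1])
                    var_t += 2.0 * _brown_cov(r * r)
        scale = var_t / (2.0 * mean_t)
        df = 2.0 * mean_t**2 / var_t
        p_gene = float(stats.chi2.sf(t_stat / scale, df))
        rows.append({"gene_id": gene_id, "n_variants": k, "p_gene": p_gene})
    out = pd.DataFrame(rows, columns=["gene_id", "n_variants", "p_gene"])
    if len(out):
        out["q_value"] = bh_fdr(out["p_gene"].to_numpy())
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def stratified_summary(
    cohort: pd.DataFrame,
    dosages: np.ndarray,
    exposure_col: str,
    mediator_col: str = "mediator_pct",
    exposure_levels: Sequence[object] | None = None,
    min_count: int = 5,
    uncertain_bands: tuple[tuple[float, float], ...] = ((0.4, 0.6), (1.4, 1.6)),
) -> pd.DataFrame:
    """Mean mediator by hard-called genotype x exposure category.

    Dosages are rounded to {0, 1, 2}; dosages falling inside the
    ``uncertain_bands`` are excluded as ambiguous calls.  Cells with fewer
    than ``min_count`` observations are suppressed (reported with NaN
    mean).  Unobserved genotype categories are simply absent.
    """
    dos = np.asarray(dosages, dtype=float)
    expo = cohort[exposure_col]
    if exposure_levels is None:
        exposure_levels = sorted(expo.dropna().unique().tolist())
    if len(exposure_levels) == 0:
        raise ParameterError("no exposure categories to stratify on")
    uncertain = np.zeros(len(dos), dtype=bool)
    for lo, hi in uncertain_bands:
        uncertain |= (dos > lo) & (dos < hi)
    ok = np.isfinite(dos) & ~uncertain & expo.notna().to_numpy()
    hard = np.rint(dos).astype(int)
    med = cohort[mediator_col].to_numpy(float)
    rows = []
    for gcall in sorted(np.unique(hard[ok])):
        for lev in exposure_levels:
            cell = ok & (hard == gcall) & (expo == lev).to_numpy()
            n = int(cell.sum())
            if n == 0:
                continue
            mean = float(np.nanmean(med[cell])) if n >= min_count else np.nan
            rows.append(
                {
                    "genotype": int(gcall),
                    "exposure_level": lev,
                    "n": n,
                    "mean_mediator": mean,
                    "suppressed": n < min_count,
                }
            )
    if not rows:
        raise ParameterError("stratification produced no cells")
    return pd.DataFrame(rows)


SensitivityMode = Literal[
    "gpc_exposure_interactions", "genotype_covariate_interactions", "bmi_adjustment"
]


def apply_sensitivity_spec(
    cohort: pd.DataFrame,
    g: np.ndarray,
    exposure_col: str,
    covariates: Sequence[str],
    mode: SensitivityMode,
    pc_cols: Sequence[str] = tuple(f"pc{i}" for i in range(1, 11)),
    bmi_col: str = "bmi",
) -> tuple[pd.DataFrame, list[str]]:
    """Expand the covariate set for one sensitivity model.

    Returns an augmented copy of the cohort plus the expanded covariate
    list; the interaction term of interest is unchanged and can simply be
    re-tested on the expanded design.
    """
    out = cohort.copy()
    cov = list(covariates)
    if mode == "gpc_exposure_interactions":
        missing = [c for c in pc_cols if c not in out]
        if missing:
            raise KeyError(f"missing PC columns: {missing}")
        e = out[exposure_col].to_numpy(float)
        for c in pc_cols:
            name = f"{exposure_col}:{c}"
            out[name] = e * out[c].to_numpy(float)
            cov.append(name)
    elif mode == "genotype_covariate_interactions":
        cmat, cnames = _covariate_matrix(out, covariates)
        for i, name in enumerate(cnames):
            col = f"g:{name}"
            out[col] = np.asarray(g, dtype=float) * cmat[:, i]
            cov.append(col)
    elif mode == "bmi_adjustment":
        if bmi_col not in out:
            raise KeyError(f"missing BMI column {bmi_col!r}")
        if bmi_col not in cov:
            cov.append(bmi_col)
    else:
        raise ParameterError(f"unknown sensitivity mode {mode!r}")
    return out, cov
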