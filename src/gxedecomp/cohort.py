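"""Synthetic biobank-style cohort and variant panel generation.

Emulates the causal structure of a diet -> plasma-biomarker -> inflammation
pathway so that every pipeline stage (derived-exposure construction, the
three-pathway interaction scan, clumping, gene tests, mediation) can be
exercised end to end without restricted data:

- a dosage panel with tunable linkage disequilibrium (latent Gaussian AR(1)
  copula per chromosome, thresholded twice into two haplotypes),
- dietary source variables (two fish-intake frequencies, two binary
  fish-oil indicators with missingness),
- lifestyle/sociodemographic confounders including 10 PC-like columns,
- a plasma mediator (percent-of-total units) driven by a weighted diet
  index, a genotype main effect, and a genotype x diet interaction at a
  designated causal variant,
- a strictly positive, right-skewed outcome generated multiplicatively so
  that its log is linear in the mediator.

Every generated dataset carries a `GroundTruth` record of the parameters
used, enabling parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ParameterError

__all__ = [
    "VariantPanel",
    "GroundTruth",
    "CohortConfig",
    "generate_variant_panel",
    "generate_cohort",
    "write_cohort",
    "write_panel",
]

SOURCE_COLUMNS = (
    "oily_fish",
    "nonoily_fish",
    "fishoil_touchscreen",
    "fishoil_interview",
)

# Servings/day levels for the ordered fish-intake categories, roughly
# "never, <1/wk, 1/wk, 2-4/wk, daily".
_FISH_LEVELS = np.array([0.0, 0.07, 0.14, 0.43, 1.0])


@dataclass
class VariantPanel:
    """Dosage matrix plus per-variant map and the LD generation parameters."""

    dosages: np.ndarray  # samples x variants, values in [0, 2]
    variant_map: pd.DataFrame  # id, chrom, pos, ref, alt, maf
    sample_ids: list[str]
    ld_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_map)):
            raise ValueError("dosage matrix shape does not match sample/variant counts")
        for _, sub in self.variant_map.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        idx = self.variant_map.index[self.variant_map["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in panel")
        return self.dosages[:, int(idx[0])]


@dataclass
class GroundTruth:
    """Generative parameters frozen alongside a synthetic cohort."""

    causal_variant: str
    source_weights: dict[str, float]
    gamma_g: float  # per-dosage mediator main effect
    gamma_d: float  # per-unit diet-index mediator effect
    gamma_gxd: float  # genotype x diet product coefficient
    v_gxd: float  # partial variance fraction of the interaction in the mediator
    delta_m: float  # per-unit mediator effect on the log outcome
    confounder_effect_m: float
    confounder_effect_y: float
    mediator_mean: float
    mediator_sd: float
    extra: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortConfig:
    """Tunable generative parameters; defaults are field-plausible.

    Variance fractions refer to the mediator's total variance
    (``f_*_m``) or the log-outcome's total variance (``f_*_y``);
    ``v_gxd`` is the *partial* fraction of the interaction term, so the
    upstream Wald non-centrality at the causal variant is approximately
    ``n_samples * v_gxd``.
    """

    causal_variant: str | None = None  # default: middle variant of the panel
    source_weights: tuple[float, float, float, float] = (1.6, 0.5, 0.45, 0.4)
    f_g_m: float = 0.02  # genotype main effect on mediator
    f_d_m: float = 0.12  # diet index on mediator
    v_gxd: float = 0.0  # genotype x diet interaction (partial fraction)
    f_conf_m: float = 0.03  # lifestyle confounder on mediator
    f_m_y: float = 0.009  # mediator share of log-outcome variance
    f_conf_y: float = 0.06  # confounder share of log-outcome variance
    mediator_mean: float = 4.5  # percent of total fatty acids
    mediator_sd: float = 1.2
    mediator_range: tuple[float, float] = (0.5, 15.0)
    log_outcome_mean: float = 0.0
    log_outcome_sd: float = 1.1
    fishoil_missing_rate: float = 0.15

    def __post_init__(self) -> None:
        total_m = self.f_g_m + self.f_d_m + self.v_gxd + self.f_conf_m
        if total_m >= 0.9:
            raise ParameterError("mediator variance fractions sum too close to 1")
        if self.f_m_y + self.f_conf_y >= 1.0:
            raise ParameterError("log-outcome variance fractions sum to >= 1")
        if not 0.0 <= self.fishoil_missing_rate < 1.0:
            raise ParameterError("fishoil_missing_rate must lie in [0, 1)")


def _split_counts(total: int, k: int) -> list[int]:
    base, extra = divmod(total, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def generate_variant_panel(
    n_samples: int = 20000,
    n_variants: int = 2000,
    chromosomes: Sequence[str] = ("1", "2", "3"),
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.8,
    seed: int | np.random.Generator = 0,
) -> VariantPanel:
    """Simulate a dosage panel with AR(1) latent-Gaussian LD per chromosome.

    Two independent latent haplotype chains per sample are thresholded at
    the allele-frequency quantile and summed into a hard dosage in
    {0, 1, 2}; adjacent-variant dosage correlation increases with
    ``ld_rho`` and vanishes at ``ld_rho = 0``.  Chromosome changes break
    LD blocks.
    """
    if n_variants < 1:
        raise ParameterError("n_variants must be >= 1")
    lo, hi = maf_range
    if not (0.01 < lo <= hi <= 0.5):
        raise ParameterError("maf_range must lie within (0.01, 0.5]")
    if not 0.0 <= ld_rho < 1.0:
        raise ParameterError("ld_rho must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    counts = _split_counts(n_variants, len(chromosomes))
    dosage_blocks: list[np.ndarray] = []
    map_rows: list[dict[str, object]] = []
    bases = np.array(["A", "C", "G", "T"])
    for chrom, nv in zip(chromosomes, counts):
        if nv == 0:
            continue
        mafs = rng.uniform(lo, hi, size=nv)
        thresholds = stats.norm.ppf(mafs)
        # AR(1) latent chain across variants, vectorized over 2*n haplotypes
        z = np.empty((2 * n_samples, nv))
        z[:, 0] = rng.standard_normal(2 * n_samples)
        if nv > 1:
            innov = rng.standard_normal((2 * n_samples, nv - 1))
            scale = np.sqrt(1.0 - ld_rho**2)
            for j in range(1, nv):
                z[:, j] = ld_rho * z[:, j - 1] + scale * innov[:, j - 1]
        alleles = (z < thresholds[None, :]).astype(np.float64)
        dosage_blocks.append(alleles[:n_samples] + alleles[n_samples:])
        pos = np.cumsum(rng.integers(500, 5000, size=nv))
        refalt = rng.integers(0, 4, size=(nv, 2))
        refalt[:, 1] = (refalt[:, 0] + 1 + rng.integers(0, 3, size=nv)) % 4
        for j in range(nv):
            map_rows.append(
                {
                    "id": f"var{chrom}_{int(pos[j])}",
                    "chrom": str(chrom),
                    "pos": int(pos[j]),
                    "ref": bases[refalt[j, 0]],
                    "alt": bases[refalt[j, 1]],
                    "maf": float(mafs[j]),
                }
            )
    dosages = np.concatenate(dosage_blocks, axis=1)
    variant_map = pd.DataFrame(map_rows)
    sample_ids = [f"S{i:06d}" for i in range(1, n_samples + 1)]
    return VariantPanel(
        dosages=dosages, variant_map=variant_map, sample_ids=sample_ids, ld_rho=ld_rho
    )


def _ordered_fish(score: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Map a latent propensity score to ordered servings/day categories."""
    noisy = score + rng.standard_normal(len(score))
    ranks = stats.rankdata(noisy, method="ordinal") / (len(noisy) + 1)
    # population frequencies of the five intake categories
    cuts = np.cumsum([0.25, 0.30, 0.25, 0.15])
    return _FISH_LEVELS[np.searchsorted(cuts, ranks)]


def _categ(rng: np.random.Generator, n: int, levels: Sequence[str], probs: Sequence[float]) -> np.ndarray:
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=probs)


def generate_cohort(
    panel: VariantPanel,
    config: CohortConfig = CohortConfig(),
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate phenotypes on top of a variant panel.

    Returns the cohort table (one row per panel sample) and the
    `GroundTruth` parameters actually used.  The mediator is built from
    analytically sized components on the realized data: the interaction
    coefficient is scaled against the residual variance of the
    genotype x diet product after orthogonalization on {1, g, diet}, so
    ``config.v_gxd`` is the partial variance fraction the upstream test
    sees.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = panel.n_samples
    cfg = config

    causal = cfg.causal_variant or str(
        panel.variant_map["id"].iloc[panel.n_variants // 2]
    )
    g = panel.column(causal)

    # Latent healthy-lifestyle confounder: raises fish intake, lowers the
    # inflammatory outcome, mildly raises the mediator.
    lifestyle = rng.standard_normal(n)

    oily = _ordered_fish(0.6 * lifestyle, rng)
    nonoily = _ordered_fish(0.3 * lifestyle, rng)
    p_ts = np.clip(0.3 + 0.08 * lifestyle, 0.02, 0.95)
    fishoil_ts = (rng.random(n) < p_ts).astype(float)
    fishoil_iv = (rng.random(n) < np.clip(0.2 + 0.05 * lifestyle, 0.02, 0.9)).astype(float)

    w = dict(zip(SOURCE_COLUMNS, cfg.source_weights))
    diet = (
        w["oily_fish"] * oily
        + w["nonoily_fish"] * nonoily
        + w["fishoil_touchscreen"] * fishoil_ts
        + w["fishoil_interview"] * fishoil_iv
    )

    # Mediator components sized on realized data.
    g_c = g - g.mean()
    d_c = diet - diet.mean()
    prod = g * d_c
    basis = np.column_stack([np.ones(n), g_c, d_c])
    coef, *_ = np.linalg.lstsq(basis, prod, rcond=None)
    prod_resid = prod - basis @ coef
    var_m = cfg.mediator_sd**2

    def _scaled(f: float, component: np.ndarray) -> float:
        v = float(np.var(component, ddof=1))
        return 0.0 if f == 0.0 or v == 0.0 else float(np.sqrt(f * var_m / v))

    gamma_g = _scaled(cfg.f_g_m, g_c)
    gamma_d = _scaled(cfg.f_d_m, d_c)
    gamma_gxd = _scaled(cfg.v_gxd, prod_resid)
    gamma_conf = _scaled(cfg.f_conf_m, lifestyle)
    used = cfg.f_g_m + cfg.f_d_m + cfg.f_conf_m + (
        gamma_gxd**2 * float(np.var(prod, ddof=1)) / var_m
    )
    noise_sd = cfg.mediator_sd * np.sqrt(max(1.0 - used, 0.05))
    mediator = (
        cfg.mediator_mean
        + gamma_g * g_c
        + gamma_d * d_c
        + gamma_gxd * prod
        + gamma_conf * lifestyle
        + rng.normal(0.0, noise_sd, size=n)
    )
    mediator = np.clip(mediator, *cfg.mediator_range)

    m_std = (mediator - mediator.mean()) / mediator.std(ddof=1)
    f_rest = 1.0 - cfg.f_m_y - cfg.f_conf_y
    # mediator lowers the inflammatory outcome; lifestyle lowers it too
    log_y = cfg.log_outcome_mean + cfg.log_outcome_sd * (
        -np.sqrt(cfg.f_m_y) * m_std
        - np.sqrt(cfg.f_conf_y) * lifestyle
        + np.sqrt(f_rest) * rng.standard_normal(n)
    )
    outcome_raw = np.exp(log_y)

    # Covariates
    age = rng.integers(40, 70, size=n).astype(float)
    sex = rng.integers(0, 2, size=n).astype(float)
    smoking = _categ(rng, n, ["never", "past", "current"], [0.55, 0.35, 0.10])
    alcohol = _categ(
        rng, n,
        ["never", "special_occasions", "1-3_per_month", "1-2_per_week",
         "3-4_per_week", "daily"],
        [0.08, 0.11, 0.11, 0.26, 0.23, 0.21],
    )
    income = _categ(
        rng, n, ["<18k", "18-31k", "31-52k", "52-100k", ">100k", "do_not_know"],
        [0.19, 0.25, 0.22, 0.17, 0.05, 0.12],
    )
    education = _categ(
        rng, n,
        ["degree", "a_levels", "o_levels", "cses", "nvq", "none"],
        [0.32, 0.12, 0.21, 0.06, 0.07, 0.22],
    )
    pcs = {f"pc{i}": rng.standard_normal(n) for i in range(1, 11)}
    bmi = np.clip(rng.normal(27.0, 4.5, size=n), 15.0, 55.0)

    cohort = pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "oily_fish": oily,
            "nonoily_fish": nonoily,
            "fishoil_touchscreen": fishoil_ts,
            "fishoil_interview": fishoil_iv,
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "alcohol": alcohol,
            "income": income,
            "education": education,
            "cooked_veg": rng.poisson(2.5, size=n).astype(float),
            "raw_veg": rng.poisson(2.0, size=n).astype(float),
            "fresh_fruit": rng.poisson(2.2, size=n).astype(float),
            "processed_meat": rng.integers(0, 5, size=n).astype(float),
            "bread_wholemeal": rng.integers(0, 2, size=n).astype(float),
            **pcs,
            "bmi": bmi,
            "mediator_pct": mediator,
            "outcome_raw": outcome_raw,
        }
    )
    # MCAR missingness in fish-oil reports only
    for col in ("fishoil_touchscreen", "fishoil_interview"):
        miss = rng.random(n) < cfg.fishoil_missing_rate
        cohort.loc[miss, col] = np.nan

    truth = GroundTruth(
        causal_variant=causal,
        source_weights=w,
        gamma_g=gamma_g,
        gamma_d=gamma_d,
        gamma_gxd=gamma_gxd,
        v_gxd=cfg.v_gxd,
        delta_m=float(
            -cfg.log_outcome_sd * np.sqrt(cfg.f_m_y) / mediator.std(ddof=1)
        ),
        confounder_effect_m=gamma_conf,
        confounder_effect_y=float(-cfg.log_outcome_sd * np.sqrt(cfg.f_conf_y)),
        mediator_mean=float(mediator.mean()),
        mediator_sd=float(mediator.std(ddof=1)),
        extra={"noise_sd_m": float(noise_sd), "f_m_y": cfg.f_m_y},
    )
    return cohort, truth


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    """Write the cohort as tab-delimited text; missing values as empty fields."""
    path = Path(path)
    try:
        cohort.to_csv(path, sep="\t", index=False, na_rep="")
    except OSError as exc:
        raise OSError(f"cannot write cohort to {path}: {exc}") from exc
    return path


def write_panel(panel: VariantPanel, path_prefix: str | Path) -> dict[str, Path]:
    """Write a panel as (a) minimal VCF with DS dosages and (b) TSV pair.

    The VCF carries one FORMAT field (DS, dosage to 4 decimals); records
    are ordered by chromosome then position.  The TSV pair is a dosage
    matrix (samples x variants) plus the variant map.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vcf_path = prefix.with_suffix(".vcf")
    dos_path = Path(f"{prefix}_dosages.tsv")
    map_path = Path(f"{prefix}_variant_map.tsv")

    vm = panel.variant_map
    order = vm.sort_values(["chrom", "pos"], kind="stable").index
    try:
        with open(vcf_path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
            for chrom in vm["chrom"].unique():
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(panel.sample_ids)
                + "\n"
            )
            for idx in order:
                row = vm.loc[idx]
                ds = panel.dosages[:, int(idx)]
                vals = "\t".join(
                    "." if not np.isfinite(d) else f"{d:.4f}" for d in ds
                )
                fh.write(
                    f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                    f"{row['alt']}\t.\t.\t.\tDS\t{vals}\n"
                )
        dos = pd.DataFrame(
            panel.dosages, index=panel.sample_ids, columns=vm["id"].tolist()
        )
        dos.round(4).to_csv(dos_path, sep="\t", index_label="sample_id")
        vm.to_csv(map_path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write panel files at prefix {prefix}: {exc}") from exc
    return {"vcf": vcf_path, "dosages": dos_path, "variant_map": map_path}
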