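"""Configuration parsing and shared format readers/writers.

Config files are YAML with strict key checking: unknown keys are fatal so
a misspelled grid parameter cannot silently fall back to a default.  Every
command writes a resolved copy of its configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .cohort import VariantPanel

__all__ = [
    "StrictConfigError",
    "PowerGridConfig",
    "SynthConfig",
    "MediateConfig",
    "GwisConfig",
    "parse_config",
    "dump_resolved_config",
    "read_vcf_dosages",
    "read_dosage_matrix",
    "write_summary_stats",
    "read_summary_stats",
    "SUMMARY_COLUMNS",
]

logger = logging.getLogger(__name__)


class StrictConfigError(ValueError):
    """Unknown or ill-typed configuration key."""


@dataclass
class PowerGridConfig:
    """Scenario grid: scalar values or lists (lists are crossed)."""

    scenario_kind: Any = "downstream"
    n: Any = 1000
    maf: Any = 0.25
    v_interaction: Any = 0.005
    v_transmit: Any = 0.10
    icc_m: Any = 1.0
    n_reps: int = 500
    alpha: float = 0.05
    seed: int = 0


@dataclass
class SynthConfig:
    n_samples: int = 20000
    n_variants: int = 2000
    chromosomes: list[str] = field(default_factory=lambda: ["1", "2", "3"])
    maf_range: list[float] = field(default_factory=lambda: [0.05, 0.5])
    ld_rho: float = 0.8
    v_gxd: float = 0.0
    seed: int = 0


@dataclass
class MediateConfig:
    data: str = ""
    exposure: str = ""
    mediator: str = ""
    outcome: str = ""
    covariates: list[str] = field(default_factory=list)
    draws: int = 1000
    level: float = 0.95
    seed: int = 0


@dataclass
class GwisConfig:
    cohort: str = ""
    vcf: str = ""
    dosages: str = ""
    variant_map: str = ""
    outcome: str = "outcome_raw"
    mediator: str = "mediator_pct"
    sources: list[str] = field(
        default_factory=lambda: [
            "oily_fish", "nonoily_fish", "fishoil_touchscreen", "fishoil_interview",
        ]
    )
    covariates: list[str] = field(default_factory=list)
    pathways: list[str] = field(
        default_factory=lambda: ["standard", "upstream", "downstream"]
    )
    maf_min: float = 0.01
    seed: int = 0


_SECTION_TYPES = {
    "power_grid": PowerGridConfig,
    "synth": SynthConfig,
    "mediate": MediateConfig,
    "gwis": GwisConfig,
}


def _build(cls, payload: dict[str, Any]):
    names = {f.name for f in fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise StrictConfigError(
            f"unknown key(s) {sorted(unknown)} in {cls.__name__}; "
            f"expected a subset of {sorted(names)}"
        )
    obj = cls(**payload)
    for f in fields(cls):
        v = getattr(obj, f.name)
        if f.type in ("int", "float") and not isinstance(v, (int, float)):
            raise StrictConfigError(
                f"key {f.name!r} expects {f.type}, got {type(v).__name__}"
            )
    return obj


def parse_config(path: str | Path, section: str):
    """Parse one config section from a YAML file, strictly."""
    if section not in _SECTION_TYPES:
        raise StrictConfigError(f"unknown config section {section!r}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise StrictConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    payload = raw.get(section, raw)
    if not isinstance(payload, dict):
        raise StrictConfigError(f"section {section!r} must be a mapping")
    if section in raw:
        other = set(raw) - set(_SECTION_TYPES)
        if other:
            raise StrictConfigError(f"unknown top-level key(s) {sorted(other)}")
    return _build(_SECTION_TYPES[section], payload)


def dump_resolved_config(config, path: str | Path) -> Path:
    """Write the fully resolved config (defaults filled) as YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return path


def read_vcf_dosages(path: str | Path) -> VariantPanel:
    """Read a VCF with per-sample DS (dosage) FORMAT values into a panel.

    Multiallelic records are rejected.  A missing DS (".") propagates as
    NaN, excluding that sample from the variant's regressions downstream.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosage_cols: list[np.ndarray] = []
    rows: list[dict[str, object]] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={','.join(rec.ALT)}) is not supported"
            )
        ds = rec.format("DS")
        if ds is None:
            raise ValueError(f"record at {rec.CHROM}:{rec.POS} lacks the DS FORMAT field")
        col = np.asarray(ds, dtype=float).reshape(-1)
        col = np.where(np.isfinite(col) & (col >= 0), col, np.nan)
        dosage_cols.append(col)
        af = float(np.nanmean(col)) / 2.0
        rows.append(
            {
                "id": rec.ID or f"var{rec.CHROM}_{rec.POS}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "maf": min(af, 1.0 - af),
            }
        )
    if not rows:
        raise ValueError(f"no records in {path}")
    return VariantPanel(
        dosages=np.column_stack(dosage_cols),
        variant_map=pd.DataFrame(rows),
        sample_ids=samples,
    )


def read_dosage_matrix(dosage_path: str | Path, map_path: str | Path) -> VariantPanel:
    """Read a dosage matrix TSV (samples x variants) plus a variant-map TSV."""
    dos = pd.read_csv(dosage_path, sep="\t", index_col="sample_id")
    vm = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    if list(dos.columns) != list(vm["id"]):
        raise ValueError("dosage columns and variant map ids disagree")
    return VariantPanel(
        dosages=dos.to_numpy(float),
        variant_map=vm,
        sample_ids=[str(s) for s in dos.index],
    )


SUMMARY_COLUMNS = [
    "SNPID", "CHR", "POS", "Non_Effect_Allele", "Effect_Allele", "AF", "N",
    "Beta_Int", "robust_SE_Int", "robust_Z_Int", "robust_P_Int", "pathway",
]


def write_summary_stats(records: pd.DataFrame, path: str | Path) -> Path:
    """Write per-variant interaction records in a GWIS summary dialect.

    Tab-delimited, fixed column order, p-values in scientific notation
    with 6 significant digits, rows ordered by (chromosome, position,
    pathway).  An empty record set yields a header-only file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if records.empty:
        out = pd.DataFrame(columns=SUMMARY_COLUMNS)
    else:
        rec = records.sort_values(["chrom", "pos", "pathway"], kind="stable")
        out = pd.DataFrame(
            {
                "SNPID": rec["id"],
                "CHR": rec["chrom"],
                "POS": rec["pos"],
                "Non_Effect_Allele": rec["ref"],
                "Effect_Allele": rec["alt"],
                "AF": rec["af"].map(lambda v: f"{v:.6g}"),
                "N": rec["n_used"],
                "Beta_Int": rec["beta_int"].map(lambda v: f"{v:.6g}"),
                "robust_SE_Int": rec["se_robust"].map(lambda v: f"{v:.6g}"),
                "robust_Z_Int": rec["z"].map(lambda v: f"{v:.6g}"),
                "robust_P_Int": rec["p_int"].map(lambda v: f"{v:.6e}"),
                "pathway": rec["pathway"],
            }
        )
    try:
        out.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write summary stats to {path}: {exc}") from exc
    return path


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a summary-stats file back into the internal record schema."""
    raw = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    return pd.DataFrame(
        {
            "id": raw["SNPID"],
            "chrom": raw["CHR"],
            "pos": raw["POS"],
            "ref": raw["Non_Effect_Allele"],
            "alt": raw["Effect_Allele"],
            "af": raw["AF"].astype(float),
            "n_used": raw["N"],
            "beta_int": raw["Beta_Int"].astype(float),
            "se_robust": raw["robust_SE_Int"].astype(float),
            "z": raw["robust_Z_Int"].astype(float),
            "p_int": raw["robust_P_Int"].astype(float),
            "pathway": raw["pathway"],
        }
    )
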