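"""OLS with heteroscedasticity-robust (sandwich) covariance and pathway designs.

The interaction tests throughout the package are Wald z-tests of a
product-term coefficient from an ordinary least-squares fit with an
HC-type sandwich covariance,

    cov = (X'X)^-1 X' diag(r_i^2 w_i) X (X'X)^-1,

with w_i = 1 (HC0, default), n/(n-k) (HC1) or 1/(1-h_i)^2 (HC3).  The
reference distribution is standard normal, the large-sample convention of
genome-wide interaction tools.  The linear algebra is done directly in
numpy so that per-variant scans stay cheap; tests cross-check the
estimator against statsmodels' HC implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FitResult",
    "PathwaySpec",
    "PATHWAYS",
    "fit_ols_robust",
    "interaction_wald_test",
    "build_pathway_design",
    "SingularDesignError",
    "InsufficientDataError",
]

SeType = Literal["HC0", "HC1", "HC3"]
Pathway = Literal["standard", "upstream", "downstream"]


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; the message names the collinear terms."""


class InsufficientDataError(ValueError):
    """Fewer usable rows than design columns."""


@dataclass
class FitResult:
    """One fitted regression with robust inference per term."""

    term_names: list[str]
    beta: np.ndarray
    cov_robust: np.ndarray
    se_robust: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n_used: int
    se_type: str = "HC0"

    def term(self, name: str) -> int:
        try:
            return self.term_names.index(name)
        except ValueError:
            raise KeyError(
                f"term {name!r} not in fit; available: {self.term_names}"
            ) from None

    def to_series(self) -> pd.Series:
        """Flatten to one row (term:stat keys) for delimited-text export."""
        out: dict[str, float] = {"n_used": self.n_used}
        for i, t in enumerate(self.term_names):
            out[f"beta[{t}]"] = self.beta[i]
            out[f"se[{t}]"] = self.se_robust[i]
            out[f"z[{t}]"] = self.z[i]
            out[f"p[{t}]"] = self.p[i]
        return pd.Series(out)


# Pathway -> (outcome column role, exposure/modifier column role).  The
# standard test regresses the outcome on the raw exposure, the upstream test
# regresses the measured mediator on the exposure, and the downstream test
# regresses the outcome on the measured mediator.
_PATHWAY_ROLES: dict[Pathway, tuple[str, str]] = {
    "standard": ("y", "e"),
    "upstream": ("m_measured", "e"),
    "downstream": ("y", "m_measured"),
}
PATHWAYS: tuple[Pathway, ...] = ("standard", "upstream", "downstream")


@dataclass(frozen=True)
class PathwaySpec:
    """Column roles for one of the three decomposed interaction regressions."""

    pathway: Pathway
    outcome_role: str = ""
    exposure_role: str = ""
    genotype_role: str = "g"
    covariate_roles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pathway not in _PATHWAY_ROLES:
            raise ValueError(f"unknown pathway {self.pathway!r}")
        default_y, default_e = _PATHWAY_ROLES[self.pathway]
        if not self.outcome_role:
            object.__setattr__(self, "outcome_role", default_y)
        if not self.exposure_role:
            object.__setattr__(self, "exposure_role", default_e)


def _find_collinear(x: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name the columns implicated in a rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    return bad or list(names)


def fit_ols_robust(
    design: np.ndarray,
    y: np.ndarray,
    se_type: SeType = "HC0",
    term_names: Sequence[str] | None = None,
) -> FitResult:
    """Least squares with sandwich covariance and per-term Wald z / p.

    Rows with any missing value in the design or response are dropped
    (complete-case); ``n_used`` records the retained count.  A zero robust
    SE yields z=0 / p=1 for a zero coefficient (the perfect-fit limit) and
    infinite z / p=0 otherwise.
    """
    x = np.asarray(design, dtype=np.float64)
    yv = np.asarray(y, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("design must be 2-D")
    if term_names is None:
        term_names = [f"x{i}" for i in range(x.shape[1])]
    term_names = list(term_names)
    if len(term_names) != x.shape[1]:
        raise ValueError("term_names length mismatch")
    if se_type not in ("HC0", "HC1", "HC3"):
        raise ValueError(f"se_type must be HC0/HC1/HC3, got {se_type!r}")

    keep = np.isfinite(x).all(axis=1) & np.isfinite(yv)
    x, yv = x[keep], yv[keep]
    n, k = x.shape
    if n <= k:
        raise InsufficientDataError(f"{n} usable rows for {k} design columns")

    xtx = x.T @ x
    rank = np.linalg.matrix_rank(xtx)
    if rank < k:
        bad = _find_collinear(x, term_names)
        raise SingularDesignError(
            f"design is rank deficient (rank {rank} < {k}); collinear terms: {bad}"
        )
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (x.T @ yv)
    resid = yv - x @ beta

    if se_type == "HC0":
        w = np.ones(n)
    elif se_type == "HC1":
        w = np.full(n, n / (n - k))
    else:  # HC3
        h = np.einsum("ij,jk,ik->i", x, xtx_inv, x)
        w = 1.0 / (1.0 - h) ** 2
    meat = (x * (resid**2 * w)[:, None]).T @ x
    cov = xtx_inv @ meat @ xtx_inv
    cov = (cov + cov.T) / 2.0

    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.where(np.abs(beta) > 0, np.inf, 0.0))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return FitResult(
        term_names=term_names,
        beta=beta,
        cov_robust=cov,
        se_robust=se,
        z=z,
        p=p,
        n_used=n,
        se_type=se_type,
    )


def interaction_wald_test(fit: FitResult, term: str) -> tuple[float, float]:
    """Return (z, p) for one term; two-sided p = 2*(1 - Phi(|z|))."""
    i = fit.term(term)
    return float(fit.z[i]), float(fit.p[i])


def build_pathway_design(
    data: Mapping[str, np.ndarray] | pd.DataFrame,
    spec: PathwaySpec,
    covariates: np.ndarray | pd.DataFrame | None = None,
    covariate_names: Sequence[str] | None = None,
    center_product: bool = False,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Assemble (design, term labels, response) for one pathway regression.

    Columns are intercept, genotype, exposure, genotype×exposure product
    (elementwise, no re-centering unless ``center_product``), then any
    covariates.  The interaction label is ``"g:<exposure role>"``.
    """
    for role in (spec.outcome_role, spec.exposure_role, spec.genotype_role):
        if role not in data:
            raise KeyError(f"required column role {role!r} missing from data")
    g = np.asarray(data[spec.genotype_role], dtype=np.float64)
    e = np.asarray(data[spec.exposure_role], dtype=np.float64)
    yv = np.asarray(data[spec.outcome_role], dtype=np.float64)
    gp = g - np.nanmean(g) if center_product else g
    ep = e - np.nanmean(e) if center_product else e
    cols = [np.ones_like(g), g, e, gp * ep]
    labels = [
        "intercept",
        spec.genotype_role,
        spec.exposure_role,
        f"{spec.genotype_role}:{spec.exposure_role}",
    ]
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            covariate_names = covariate_names or list(covariates.columns)
            cmat = covariates.to_numpy(dtype=np.float64)
        else:
            cmat = np.asarray(covariates, dtype=np.float64)
            if cmat.ndim == 1:
                cmat = cmat[:, None]
            covariate_names = list(
                covariate_names or [f"cov{i}" for i in range(cmat.shape[1])]
            )
        cols.extend(cmat.T)
        labels.extend(covariate_names)
    design = np.column_stack(cols)
    return design, labels, yv


def expand_categorical(
    series: pd.Series, name: str, keep_na: bool = False
) -> pd.DataFrame:
    """Expand a categorical column to indicators, most frequent level as reference.

    Explicit sentinel levels (e.g. "do not know" / "prefer not to answer")
    are ordinary levels and get their own indicator; with ``keep_na`` a
    missing-value indicator is added instead of dropping rows here.
    """
    s = series.astype("object")
    counts = s.value_counts(dropna=True)
    if counts.empty:
        raise ValueError(f"column {name!r} has no observed levels")
    reference = counts.index[0]
    levels = [lv for lv in counts.index if lv != reference]
    out = pd.DataFrame(index=series.index)
    for lv in levels:
        out[f"{name}[{lv}]"] = (s == lv).astype(float)
    if keep_na and s.isna().any():
        out[f"{name}[missing]"] = s.isna().astype(float)
    return out
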