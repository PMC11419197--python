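"""Linear-structural-equation mediation with quasi-Bayesian intervals.

For continuous exposure, mediator and outcome the causal-mediation
estimands reduce to the classical product-of-coefficients decomposition:
with

    M = a*X + covariates + err1
    Y = c'*X + b*M + covariates + err2

the average causal mediation effect (ACME) is ``a*b``, the direct effect
is ``c'`` and the total effect is ``c' + a*b`` (exact additivity on point
estimates).  Exposure and outcome are standardized internally so effects
are comparable across exposures.  Confidence intervals come from
quasi-Bayesian simulation: coefficient vectors are drawn from normal
approximations centered at the estimates with heteroscedasticity-robust
(HC0) covariance, the estimands are formed per draw, and percentile
intervals are taken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regression import FitResult, fit_ols_robust
from .simulate import ParameterError

__all__ = [
    "MediationResult",
    "standardize",
    "fit_mediation",
    "flag_inconsistent_mediation",
    "compare_mediators",
    "DegenerateScaleError",
]

logger = logging.getLogger(__name__)


class DegenerateScaleError(ValueError):
    """A vector with zero sample standard deviation cannot be standardized."""


@dataclass
class MediationResult:
    """Point estimates and quasi-Bayesian percentile CIs for one decomposition."""

    total_effect: float
    acme: float
    direct_effect: float
    prop_mediated: float  # NaN when |total| is below tolerance
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    level: float = 0.95
    n_draws: int = 20
    n_used: int = 0
    inconsistent: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, est in [
            ("total", self.total_effect),
            ("acme", self.acme),
            ("direct", self.direct_effect),
            ("prop_mediated", self.prop_mediated),
        ]:
            lo, hi = self.ci.get(name, (np.nan, np.nan))
            rows.append(
                {
                    "estimand": name,
                    "estimate": est,
                    "ci_low": lo,
                    "ci_high": hi,
                    "level": self.level,
                    "n_draws": self.n_draws,
                }
            )
        return pd.DataFrame(rows)


def standardize(v: np.ndarray) -> np.ndarray:
    """Scale to mean 0, SD 1 (n-1 denominator)."""
    v = np.asarray(v, dtype=np.float64)
    sd = float(np.std(v, ddof=1))
    if not np.isfinite(sd) or sd <= 0.0:
        raise DegenerateScaleError("vector has zero sample standard deviation")
    return (v - v.mean()) / sd


def flag_inconsistent_mediation(
    result: "MediationResult | float", total: float | None = None, tol: float = 1e-6
) -> bool:
    """True iff |ACME| exceeds |total| by more than ``tol``.

    A mediated effect larger in magnitude than the total effect is
    *inconsistent mediation*: the direct and indirect paths (or residual
    confounding) work in opposite directions.  Accepts either a
    ``MediationResult`` or the ``(acme, total)`` pair directly.
    """
    if isinstance(result, MediationResult):
        acme, tot = result.acme, result.total_effect
    else:
        if total is None:
            raise TypeError("total is required when acme is given as a float")
        acme, tot = float(result), float(total)
    return bool(abs(acme) > abs(tot) + tol)


def fit_mediation(
    exposure: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    n_draws: int = 20,
    level: float = 0.95,
    seed: int | np.random.Generator | None = 0,
    total_tol: float = 1e-10,
) -> MediationResult:
    """Baron–Kenny decomposition with robust-covariance quasi-Bayesian CIs.

    Complete cases only.  Point estimates are closed-form; ``n_draws``
    affects intervals only.  The default of 20 draws gives very unstable
    percentile endpoints; >= 1000 is recommended for reportable intervals.
    """
    if n_draws < 2:
        raise ParameterError("n_draws must be >= 2")
    if not 0.0 < level < 1.0:
        raise ParameterError("level must lie in (0, 1)")
    if n_draws < 1000:
        logger.warning(
            "n_draws=%d gives unstable percentile intervals; >=1000 recommended",
            n_draws,
        )

    x = np.asarray(exposure, dtype=np.float64)
    m = np.asarray(mediator, dtype=np.float64)
    y = np.asarray(outcome, dtype=np.float64)
    if covariates is None:
        cmat = np.empty((len(x), 0))
        cov_names: list[str] = []
    elif isinstance(covariates, pd.DataFrame):
        cmat = covariates.to_numpy(dtype=np.float64)
        cov_names = [str(c) for c in covariates.columns]
    else:
        cmat = np.asarray(covariates, dtype=np.float64)
        if cmat.ndim == 1:
            cmat = cmat[:, None]
        cov_names = [f"cov{i}" for i in range(cmat.shape[1])]

    keep = (
        np.isfinite(x)
        & np.isfinite(m)
        & np.isfinite(y)
        & np.isfinite(cmat).all(axis=1)
    )
    x, m, y, cmat = x[keep], m[keep], y[keep], cmat[keep]
    x = standardize(x)
    y = standardize(y)
    if np.std(m, ddof=1) <= 0.0:
        raise DegenerateScaleError("mediator has zero sample standard deviation")

    ones = np.ones_like(x)
    design_m = np.column_stack([ones, x, cmat])
    names_m = ["intercept", "exposure", *cov_names]
    fit_a: FitResult = fit_ols_robust(design_m, m, se_type="HC0", term_names=names_m)

    design_y = np.column_stack([ones, x, m, cmat])
    names_y = ["intercept", "exposure", "mediator", *cov_names]
    fit_bc: FitResult = fit_ols_robust(design_y, y, se_type="HC0", term_names=names_y)

    ia = fit_a.term("exposure")
    ib = fit_bc.term("mediator")
    ic = fit_bc.term("exposure")
    a = float(fit_a.beta[ia])
    b = float(fit_bc.beta[ib])
    c_prime = float(fit_bc.beta[ic])

    acme = a * b
    direct = c_prime
    total = acme + direct

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a_draws = rng.normal(a, np.sqrt(fit_a.cov_robust[ia, ia]), size=n_draws)
    mean_bc = fit_bc.beta[[ic, ib]]
    cov_bc = fit_bc.cov_robust[np.ix_([ic, ib], [ic, ib])]
    bc_draws = rng.multivariate_normal(mean_bc, cov_bc, size=n_draws)
    acme_d = a_draws * bc_draws[:, 1]
    direct_d = bc_draws[:, 0]
    total_d = acme_d + direct_d

    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    ci = {
        "acme": _pctile(acme_d, lo_q, hi_q),
        "direct": _pctile(direct_d, lo_q, hi_q),
        "total": _pctile(total_d, lo_q, hi_q),
    }
    if abs(total) > total_tol:
        prop = acme / total
        with np.errstate(divide="ignore", invalid="ignore"):
            prop_d = np.where(np.abs(total_d) > total_tol, acme_d / total_d, np.nan)
        ci["prop_mediated"] = _pctile(prop_d[np.isfinite(prop_d)], lo_q, hi_q)
    else:
        prop = float("nan")

    return MediationResult(
        total_effect=total,
        acme=acme,
        direct_effect=direct,
        prop_mediated=prop,
        ci=ci,
        level=level,
        n_draws=n_draws,
        n_used=int(keep.sum()),
        inconsistent=flag_inconsistent_mediation(acme, total),
    )


def _pctile(v: np.ndarray, lo: float, hi: float) -> tuple[float, float]:
    if v.size == 0:
        return (float("nan"), float("nan"))
    return (float(np.quantile(v, lo)), float(np.quantile(v, hi)))


def compare_mediators(
    exposure: np.ndarray,
    mediator_components: dict[str, np.ndarray] | pd.DataFrame,
    outcome: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    n_draws: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    remainder_of: tuple[str, str] | None = None,
) -> dict[str, MediationResult]:
    """Run one decomposition per named mediator component, independently.

    Components share sample alignment.  ``remainder_of=(total, part)``
    adds a derived component ``total-minus-part`` by subtraction, the way
    a non-DHA fraction is derived from a total omega-3 percentage.  Each
    component is fit with the same seed, so a component identical to a
    previously analyzed mediator reproduces its result exactly.
    """
    if isinstance(mediator_components, pd.DataFrame):
        comps = {str(c): mediator_components[c].to_numpy() for c in mediator_components}
    else:
        comps = dict(mediator_components)
    if remainder_of is not None:
        tot, part = remainder_of
        name = f"{tot}-minus-{part}"
        if name in comps:
            raise ValueError(f"derived component name {name!r} collides")
        comps[name] = np.asarray(comps[tot], dtype=float) - np.asarray(
            comps[part], dtype=float
        )
    out: dict[str, MediationResult] = {}
    for name, med in comps.items():
        out[name] = fit_mediation(
            exposure,
            med,
            outcome,
            covariates=covariates,
            n_draws=n_draws,
            level=level,
            seed=seed,
        )
    return out
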