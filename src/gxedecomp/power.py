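"""Monte-Carlo power estimation for the decomposed interaction tests.

For each scenario the relevant pathway regressions are refit on repeated
simulated replicates and power is the fraction of replicates whose
product-term p-value falls below the significance threshold.  A closed-form
non-central chi-square oracle (`scenario_ncp` + `analytic_power`)
approximates the same quantity analytically and anchors the Monte-Carlo
engine in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regression import PathwaySpec, Pathway, build_pathway_design, fit_ols_robust
from .simulate import ParameterError, SimScenario, genotype_moments, simulate_scenario

__all__ = [
    "PowerConfig",
    "PowerEstimate",
    "estimate_power",
    "analytic_power",
    "scenario_ncp",
    "run_power_grid",
    "pathways_for_scenario",
]


@dataclass(frozen=True)
class PowerConfig:
    """Replicate count, significance threshold and master seed for one run."""

    n_reps: int = 500
    alpha: float = 0.05
    seed: int = 0
    se_type: str = "HC0"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ParameterError("n_reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            # alpha=1 is handled by callers wanting the always-reject limit
            if self.alpha != 1.0:
                raise ParameterError(f"alpha must lie in (0, 1], got {self.alpha}")


@dataclass
class PowerEstimate:
    """Estimated rejection rate for one (scenario, pathway) pair."""

    scenario: SimScenario
    pathway: Pathway
    power: float
    mc_se: float
    n_reps: int
    n_reject: int


def pathways_for_scenario(scenario: SimScenario) -> tuple[Pathway, ...]:
    """The two pathway tests evaluated per scenario kind.

    Upstream scenarios are tested with the standard and upstream
    regressions; downstream scenarios with the standard and downstream
    regressions (the third regression has no defined signal in each case).
    """
    if scenario.scenario_kind == "upstream":
        return ("standard", "upstream")
    return ("standard", "downstream")


def _validate_pathways(scenario: SimScenario, pathways: Sequence[Pathway]) -> None:
    allowed = set(pathways_for_scenario(scenario))
    bad = set(pathways) - allowed
    if bad:
        raise ParameterError(
            f"pathways {sorted(bad)} are not admissible for a "
            f"{scenario.scenario_kind} scenario (allowed: {sorted(allowed)})"
        )


def estimate_power(
    scenario: SimScenario,
    pathways: Sequence[Pathway] | None = None,
    config: PowerConfig = PowerConfig(),
    rng: np.random.Generator | None = None,
) -> dict[Pathway, PowerEstimate]:
    """Monte-Carlo rejection rate of each pathway's interaction test.

    Each replicate draws a fresh dataset from a child stream of the master
    seed, fits the requested pathway regressions with robust SEs, and
    records whether the product-term p-value is below ``config.alpha``.
    Deterministic given ``config.seed``.
    """
    if pathways is None:
        pathways = pathways_for_scenario(scenario)
    _validate_pathways(scenario, pathways)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    specs = {pw: PathwaySpec(pathway=pw) for pw in pathways}
    rejections = {pw: 0 for pw in pathways}
    for _ in range(config.n_reps):
        data = simulate_scenario(scenario, rng)
        frame = {
            "g": data.g,
            "e": data.e,
            "m_measured": data.m_measured,
            "y": data.y,
        }
        for pw, spec in specs.items():
            design, labels, yv = build_pathway_design(frame, spec)
            fit = fit_ols_robust(design, yv, se_type=config.se_type, term_names=labels)
            p_int = fit.p[fit.term(f"g:{spec.exposure_role}")]
            if p_int < config.alpha:
                rejections[pw] += 1
    out: dict[Pathway, PowerEstimate] = {}
    for pw in pathways:
        p_hat = rejections[pw] / config.n_reps
        out[pw] = PowerEstimate(
            scenario=scenario,
            pathway=pw,
            power=p_hat,
            mc_se=float(np.sqrt(p_hat * (1.0 - p_hat) / config.n_reps)),
            n_reps=config.n_reps,
            n_reject=rejections[pw],
        )
    return out


def analytic_power(ncp: float, alpha: float, df: int = 1) -> float:
    """Power of a chi-square test with non-centrality ``ncp``.

    ``P(chi2_df(ncp) > q_{1-alpha})``; monotone increasing in ncp and equal
    to alpha at ncp=0.
    """
    if ncp < 0:
        raise ParameterError("ncp must be >= 0")
    if df < 1:
        raise ParameterError("df must be >= 1")
    if alpha >= 1.0:
        return 1.0
    crit = stats.chi2.ppf(1.0 - alpha, df)
    if ncp == 0.0:
        return float(stats.chi2.sf(crit, df))
    return float(stats.ncx2.sf(crit, df, ncp))


def scenario_ncp(scenario: SimScenario, pathway: Pathway) -> float:
    """Closed-form non-centrality of the Wald interaction test.

    The product term G·X (X the standard-normal modifier, independent of G)
    has marginal variance E[G_prod^2] and, after orthogonalization against
    {1, G, X}, residual variance Var(G).  The partial variance fraction of
    the interaction signal is therefore ``v_interaction * Var(G)/E[G_prod^2]``
    (equal to ``v_interaction`` under the centered convention), attenuated by

    - the transmission fraction ``v_transmit`` for the standard test (the
      signal reaches the tested outcome only through the mediating path), and
    - ``icc_m`` whenever the measured mediator enters the tested regression.

    ncp = n * partial fraction / (1 - marginal signal fraction of the
    tested outcome).
    """
    _validate_pathways(scenario, [pathway])
    var_g, var_prod = genotype_moments(scenario.maf, scenario.product_centering)
    partial = scenario.v_interaction * var_g / var_prod
    explained = scenario.v_interaction
    if pathway == "standard":
        partial *= scenario.v_transmit
        explained *= scenario.v_transmit
    elif pathway in ("upstream", "downstream"):
        # upstream: measurement noise inflates the tested outcome (M_measured);
        # downstream: errors-in-variables attenuation of the G*M_measured term.
        partial *= scenario.icc_m
        explained *= scenario.icc_m
    return scenario.n * partial / (1.0 - explained)


def _scenario_columns(scenario: SimScenario) -> dict[str, object]:
    return {
        "scenario_kind": scenario.scenario_kind,
        "n": scenario.n,
        "maf": scenario.maf,
        "v_interaction": scenario.v_interaction,
        "v_transmit": scenario.v_transmit,
        "icc_m": scenario.icc_m,
    }


def run_power_grid(
    grid: Iterable[SimScenario], config: PowerConfig = PowerConfig()
) -> pd.DataFrame:
    """Estimate power over a scenario grid; long-format table, one row per
    (scenario, pathway).

    Each cell runs from its own spawned substream of the master seed, so the
    table is invariant to execution order.  A cell that raises is recorded
    with NaN power and the error message rather than aborting the grid.
    """
    grid = list(grid)
    if not grid:
        raise ParameterError("empty scenario grid")
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(len(grid))
    rows: list[dict[str, object]] = []
    for scenario, child in zip(grid, children):
        base = _scenario_columns(scenario)
        try:
            estimates = estimate_power(
                scenario, config=config, rng=np.random.default_rng(child)
            )
        except Exception as exc:  # recorded, not fatal
            rows.append(
                {
                    **base,
                    "pathway": None,
                    "power": np.nan,
                    "mc_se": np.nan,
                    "n_reps": config.n_reps,
                    "alpha": config.alpha,
                    "seed": config.seed,
                    "error": str(exc),
                }
            )
            continue
        for pw, est in estimates.items():
            rows.append(
                {
                    **base,
                    "pathway": pw,
                    "power": est.power,
                    "mc_se": est.mc_se,
                    "n_reps": est.n_reps,
                    "alpha": config.alpha,
                    "seed": config.seed,
                    "error": "",
                }
            )
    return pd.DataFrame(rows)


def expand_grid(**params: Sequence[object]) -> list[SimScenario]:
    """Cartesian product of per-parameter value lists into scenarios.

    Scalar values may be given directly; list values are crossed.
    """
    norm = {
        k: (v if isinstance(v, (list, tuple)) else [v]) for k, v in params.items()
    }
    keys = list(norm)
    return [
        SimScenario(**dict(zip(keys, combo)))
        for combo in itertools.product(*(norm[k] for k in keys))
    ]
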