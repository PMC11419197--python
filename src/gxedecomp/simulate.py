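"""Data-generating processes for decomposed gene-environment interaction power studies.

The generative model follows the mediated-pathway setting: a biallelic
genotype G ~ Binomial(2, MAF), a standard-normal exposure E, a mediator M
carrying either a G×E product-term signal (*upstream* scenarios) or an E
main effect (*downstream* scenarios), a measured mediator tracking M with
noise controlled by an intraclass correlation coefficient (ICC), and an
outcome Y carrying either an M main effect (upstream) or a G×M product
term (downstream).

Signal strengths are parameterized as fractions of trait variance.  By
default the interaction coefficient is sized against the *marginal*
variance of the uncentered-dosage product, ``beta**2 * Var(G*X) = v``,
with ``Var(G*X) = E[G^2] = 2*maf*(1-maf) + (2*maf)**2`` for an
independent standard-normal modifier X.  A ``product_centering``
switch selects the mean-centered convention instead, under which the
product is orthogonal to its parents and the whole fraction is partial.
All traits are normalized to unit total variance so fractions are
directly interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SimScenario",
    "SimDataset",
    "simulate_genotypes",
    "add_measurement_noise",
    "simulate_upstream",
    "simulate_downstream",
    "simulate_scenario",
    "genotype_moments",
]

ScenarioKind = Literal["upstream", "downstream"]
Centering = Literal["none", "centered"]


class ParameterError(ValueError):
    """Raised when a scenario or operation parameter is inadmissible."""


def genotype_moments(maf: float, centering: Centering = "none") -> tuple[float, float]:
    """Return ``(Var(G), Var(G_prod * X))`` for dosage G and N(0,1) modifier X.

    ``G_prod`` is the dosage as entered into the product term: raw in the
    uncentered convention, mean-centered otherwise.  For independent X with
    unit variance, ``Var(G_prod * X) = E[G_prod^2]``.
    """
    var_g = 2.0 * maf * (1.0 - maf)
    if centering == "none":
        e_g2 = var_g + (2.0 * maf) ** 2
    else:
        e_g2 = var_g
    return var_g, e_g2


@dataclass(frozen=True)
class SimScenario:
    """One cell of a power grid.

    Parameters
    ----------
    scenario_kind:
        ``"upstream"`` (G×E signal in M, M main effect in Y) or
        ``"downstream"`` (E main effect in M, G×M signal in Y).
    n:
        Sample size per replicate.
    maf:
        Minor allele frequency in (0, 0.5].
    v_interaction:
        Variance fraction of the interaction-bearing trait explained by the
        product term (M for upstream, Y for downstream).
    v_transmit:
        Variance fraction along the mediating main-effect path
        (M→Y for upstream, E→M for downstream).
    icc_m:
        Intraclass correlation of the measured mediator, in (0, 1];
        1 means error-free measurement.
    beta_g_main, beta_e_main:
        Optional genotype/exposure main-effect variance fractions in the
        interaction-bearing trait (default 0).
    product_centering:
        Product-term convention, ``"none"`` (uncentered dosage, default)
        or ``"centered"``.
    """

    scenario_kind: ScenarioKind
    n: int = 1000
    maf: float = 0.25
    v_interaction: float = 0.0
    v_transmit: float = 0.0
    icc_m: float = 1.0
    beta_g_main: float = 0.0
    beta_e_main: float = 0.0
    product_centering: Centering = "none"

    def __post_init__(self) -> None:
        if self.scenario_kind not in ("upstream", "downstream"):
            raise ParameterError(f"unknown scenario_kind {self.scenario_kind!r}")
        if self.n < 1:
            raise ParameterError("n must be >= 1")
        if not 0.0 < self.maf <= 0.5:
            raise ParameterError(f"maf must lie in (0, 0.5], got {self.maf}")
        for name in ("v_interaction", "beta_g_main", "beta_e_main"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ParameterError(f"{name} must lie in [0, 1), got {v}")
        # v_transmit = 1 is the full-determination limit (M == sqrt(v)*E or
        # Y == sqrt(v)*M exactly); admissible because it owns its whole
        # trait equation.
        if not 0.0 <= self.v_transmit <= 1.0:
            raise ParameterError(f"v_transmit must lie in [0, 1], got {self.v_transmit}")
        if not 0.0 < self.icc_m <= 1.0:
            raise ParameterError(f"icc_m must lie in (0, 1], got {self.icc_m}")
        if self.product_centering not in ("none", "centered"):
            raise ParameterError(
                f"product_centering must be 'none' or 'centered', got {self.product_centering!r}"
            )
        # Variance budget of the interaction-bearing trait equation.
        total = self.v_interaction + self.beta_g_main + self.beta_e_main
        if total >= 1.0:
            raise ParameterError(
                f"variance fractions sum to {total} >= 1; residual variance would be negative"
            )


@dataclass
class SimDataset:
    """One simulated replicate: genotype, exposure, mediator (true and measured), outcome."""

    g: np.ndarray
    e: np.ndarray
    m_true: np.ndarray
    m_measured: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.g)
        for name in ("e", "m_true", "m_measured", "y"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} has length != {n}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "g": self.g,
                "e": self.e,
                "m_true": self.m_true,
                "m_measured": self.m_measured,
                "y": self.y,
            }
        )


def simulate_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n additively coded genotypes from Binomial(2, maf)."""
    if not 0.0 < maf <= 0.5:
        raise ParameterError(f"maf must lie in (0, 0.5], got {maf}")
    if n < 1:
        raise ParameterError("n must be >= 1")
    return rng.binomial(2, maf, size=n).astype(np.float64)


def add_measurement_noise(
    m_true: np.ndarray, icc_m: float, rng: np.random.Generator
) -> np.ndarray:
    """Add independent Gaussian noise so that cor(M, M_measured)^2 ≈ icc_m.

    The noise variance is ``Var(m_true) * (1 - icc) / icc`` using the sample
    variance of the realized mediator, so the ICC holds conditionally on the
    generated data.  ``icc_m=1`` returns the input unchanged (exact copy).
    """
    if not 0.0 < icc_m <= 1.0:
        raise ParameterError(f"icc_m must lie in (0, 1], got {icc_m}")
    m_true = np.asarray(m_true, dtype=np.float64)
    if icc_m == 1.0:
        return m_true.copy()
    var_m = float(np.var(m_true, ddof=1))
    noise_sd = np.sqrt(var_m * (1.0 - icc_m) / icc_m)
    return m_true + rng.normal(0.0, noise_sd, size=m_true.shape)


def _product_dosage(g: np.ndarray, maf: float, centering: Centering) -> np.ndarray:
    return g - 2.0 * maf if centering == "centered" else g


def simulate_upstream(scenario: SimScenario, rng: np.random.Generator) -> SimDataset:
    """Generate one upstream-scenario replicate.

    M carries the G×E product signal (plus optional G/E main effects); Y
    carries an M main effect.  Both traits have unit total variance by
    construction (using analytic moments, so realized variances fluctuate
    around 1 at finite n).
    """
    if scenario.scenario_kind != "upstream":
        raise ParameterError("scenario_kind must be 'upstream'")
    g = simulate_genotypes(scenario.n, scenario.maf, rng)
    e = rng.standard_normal(scenario.n)
    var_g, var_prod = genotype_moments(scenario.maf, scenario.product_centering)
    gp = _product_dosage(g, scenario.maf, scenario.product_centering)

    beta_ge = np.sqrt(scenario.v_interaction / var_prod)
    beta_g = np.sqrt(scenario.beta_g_main / var_g)
    beta_e = np.sqrt(scenario.beta_e_main)
    resid_var = 1.0 - scenario.v_interaction - scenario.beta_g_main - scenario.beta_e_main
    m_true = (
        beta_ge * gp * e
        + beta_g * (g - 2.0 * scenario.maf)
        + beta_e * e
        + rng.normal(0.0, np.sqrt(resid_var), size=scenario.n)
    )
    m_measured = add_measurement_noise(m_true, scenario.icc_m, rng)

    beta_m = np.sqrt(scenario.v_transmit)
    y = beta_m * m_true + rng.normal(0.0, np.sqrt(1.0 - scenario.v_transmit), size=scenario.n)
    return SimDataset(g=g, e=e, m_true=m_true, m_measured=m_measured, y=y)


def simulate_downstream(scenario: SimScenario, rng: np.random.Generator) -> SimDataset:
    """Generate one downstream-scenario replicate.

    M carries an E main effect; Y carries the G×M product signal computed
    on the *true* mediator (measurement noise enters only through the
    analyst-visible ``m_measured``).
    """
    if scenario.scenario_kind != "downstream":
        raise ParameterError("scenario_kind must be 'downstream'")
    g = simulate_genotypes(scenario.n, scenario.maf, rng)
    e = rng.standard_normal(scenario.n)
    var_g, var_prod = genotype_moments(scenario.maf, scenario.product_centering)
    gp = _product_dosage(g, scenario.maf, scenario.product_centering)

    beta_e = np.sqrt(scenario.v_transmit)
    m_true = beta_e * e + rng.normal(0.0, np.sqrt(1.0 - scenario.v_transmit), size=scenario.n)
    m_measured = add_measurement_noise(m_true, scenario.icc_m, rng)

    beta_gm = np.sqrt(scenario.v_interaction / var_prod)
    beta_g = np.sqrt(scenario.beta_g_main / var_g)
    resid_var = 1.0 - scenario.v_interaction - scenario.beta_g_main
    y = (
        beta_gm * gp * m_true
        + beta_g * (g - 2.0 * scenario.maf)
        + rng.normal(0.0, np.sqrt(resid_var), size=scenario.n)
    )
    return SimDataset(g=g, e=e, m_true=m_true, m_measured=m_measured, y=y)


def simulate_scenario(scenario: SimScenario, rng: np.random.Generator) -> SimDataset:
    """Dispatch to the upstream or downstream generator."""
    if scenario.scenario_kind == "upstream":
        return simulate_upstream(scenario, rng)
    return simulate_downstream(scenario, rng)
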