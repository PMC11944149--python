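"""Boltzmann distribution of elementary-mode usage and its calibration.

At the constrained maximum of the entropy production rate, the usage
probability of mode j follows a Boltzmann-type law

    p_j = exp(−ξ̂·x_j / (b·Q·R)) / Z,      Z = Σ_j exp(−ξ̂·x_j/(b·Q·R)),

where ``x_j`` is the per-mode reaction entropy Δs_j [J/(K·mol glucose)]
(type 2, "entropy" variant) or the affinity over temperature A_j/T
(type 1, "affinity" variant), ξ̂ the specific glucose uptake rate
[mol/(h·gCDW)], R the gas constant, Q = 1 [1/(h·gCDW)] a unit-carrying
constant, and ``b = ξ̂/ξ̂_max`` the fraction of the evolutionarily attainable
maximum uptake rate the strain has realized. The Lagrange constant is
``c = −ln Z``.

``b`` is calibrated so the distribution's expected reaction entropy matches
the measured overall growth reaction: Σ p_j(b)·Δs_j = ΔS_R. The expectation
is strictly monotone in b (increasing toward the uniform mean), so the
scalar root is unique; a full (n+2)-equation Levenberg–Marquardt formulation
is retained as a cross-check. From b follow μ_max = μ/b, q_s,max = q_s/b and
the minimum doubling time τ_min = ln 2/μ_max.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.special import logsumexp

from .thermo import R, ModeThermo

logger = logging.getLogger(__name__)

#: Unit-carrying normalization constant Q = 1 [1/(h·gCDW)].
Q_CONST = 1.0

VARIANTS = ("entropy", "affinity")


def load_strain_table():
    """Published growth parameters and fitted constants of the reference
    E. coli wildtype + six adaptively evolved strains (DataFrame)."""
    import importlib.resources

    import pandas as pd

    ref = importlib.resources.files("maxentflux.data") / "strains_ecoli_ale.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


class InfeasibleTarget(ValueError):
    """Observed reaction property outside the attainable open interval."""


class AtUniformLimit(RuntimeError):
    """The fit ran into the b → ∞ (uniform-distribution) limit."""


@dataclass
class StrainObservation:
    """Measured macroscopic growth data for one strain.

    ``qs`` is the specific glucose uptake rate stored as a positive
    magnitude in mmol/(h·gCDW); ``external_stoich`` holds the overall
    growth-equation coefficients per mole glucose (glucose = −1).
    """

    name: str
    mu: float  # 1/h
    qs: float  # mmol/(h·gCDW), positive magnitude
    yield_bg: float  # g biomass / g glucose
    external_stoich: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.qs <= 0:
            raise ValueError("mu and qs must be positive")
        if not 0 < self.yield_bg <= 1:
            raise ValueError("mass-basis yield must lie in (0, 1]")

    @property
    def xi_hat(self) -> float:
        """Specific glucose uptake in mol/(h·gCDW) (the exponent's unit)."""
        return self.qs / 1000.0


@dataclass
class MaxEntFit:
    variant: str
    xi_hat: float  # mol/(h·gCDW)
    b: float
    c: float  # Lagrange constant, −ln Z
    Z: float
    p: np.ndarray
    x: np.ndarray  # per-mode values the fit used (Δs_j or A_j/T)
    at_uniform_limit: bool = False

    @property
    def expectation(self) -> float:
        return float(self.p @ self.x)


# ---------------------------------------------------------------------------
# core distribution
# ---------------------------------------------------------------------------


def boltzmann_probabilities(
    x: Sequence[float], xi_hat: float, b: float, *, Q: float = Q_CONST
) -> tuple[np.ndarray, float, float]:
    """Mode usage probabilities, partition function and Lagrange constant.

    Returns ``(p, Z, c)`` with log-sum-exp stabilization; ξ̂ = 0 yields the
    uniform distribution with Z = n. ``Z`` is reported on the unshifted
    scale and ``c = −ln Z``.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty mode set")
    if b <= 0:
        raise ValueError("b must be positive")
    if xi_hat < 0:
        raise ValueError("xi_hat must be nonnegative")
    expo = -xi_hat * x / (b * Q * R)
    ln_z = float(logsumexp(expo))
    p = np.exp(expo - ln_z)
    return p, math.exp(ln_z), -ln_z


def _expectation(x: np.ndarray, xi_hat: float, b: float) -> float:
    p, _, _ = boltzmann_probabilities(x, xi_hat, b)
    return float(p @ x)


# ---------------------------------------------------------------------------
# calibration of b
# ---------------------------------------------------------------------------


def fit_b(
    x: Sequence[float],
    xi_hat: float,
    observed: float,
    *,
    variant: str = "entropy",
    b_bounds: tuple[float, float] = (1e-4, 1e4),
    xtol: float = 1e-10,
) -> MaxEntFit:
    """Solve for the fraction b such that ``Σ p_j(b)·x_j = observed``.

    ``x`` holds Δs_j (entropy variant) or A_j/T (affinity variant) per mode;
    ``observed`` is the corresponding property of the measured overall
    growth reaction. The expectation is strictly increasing in b on mode
    sets with distinct x values, from min x (b → 0) to the uniform mean
    (b → ∞); the bracketed root on ln b is unique.

    Raises
    ------
    InfeasibleTarget
        If ``observed`` is at or below min(x) or at or above the uniform
        mean (naming the violated bound).
    AtUniformLimit
        If the root exceeds the upper b bound (target within rounding of
        the uniform mean).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    x = np.asarray(x, dtype=float)
    if xi_hat <= 0:
        raise ValueError("xi_hat must be positive for calibration")
    x_min = float(x.min())
    uniform_mean = float(x.mean())
    if observed <= x_min:
        raise InfeasibleTarget(
            f"observed value {observed:.6g} ≤ attainable minimum {x_min:.6g}"
        )
    if observed >= uniform_mean:
        raise InfeasibleTarget(
            f"observed value {observed:.6g} ≥ uniform-mean bound {uniform_mean:.6g}"
        )

    lo, hi = b_bounds

    def g(ln_b: float) -> float:
        return _expectation(x, xi_hat, math.exp(ln_b)) - observed

    g_lo, g_hi = g(math.log(lo)), g(math.log(hi))
    if g_hi < 0:
        raise AtUniformLimit(
            f"target {observed:.6g} not reached at b = {hi:g}: "
            "observed property at the uniform limit"
        )
    if g_lo > 0:
        # target lies below the expectation at the smallest allowed b
        raise InfeasibleTarget(
            f"observed value {observed:.6g} below expectation at b = {lo:g}"
        )
    ln_b = brentq(g, math.log(lo), math.log(hi), xtol=xtol)
    b = math.exp(ln_b)
    p, Z, c = boltzmann_probabilities(x, xi_hat, b)
    return MaxEntFit(variant=variant, xi_hat=xi_hat, b=b, c=c, Z=Z, p=p, x=x)


def fit_b_least_squares(
    x: Sequence[float],
    xi_hat: float,
    observed: float,
    *,
    b0: float = 0.5,
) -> tuple[float, np.ndarray]:
    """Cross-check: the full (n+2)-unknown nonlinear least-squares fit.

    Unknowns are (ln p_1..ln p_n, b, c); residuals are the n linearized
    Boltzmann relations, the normalization Σp − 1 and the expectation
    constraint Σp·x − observed, solved with Levenberg–Marquardt. Intended
    for small n; returns ``(b, p)``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    p0, _, c0 = boltzmann_probabilities(x, xi_hat, b0)
    theta0 = np.concatenate([np.log(p0), [math.log(b0), c0]])

    def residuals(theta: np.ndarray) -> np.ndarray:
        ln_p = theta[:n]
        b = math.exp(theta[n])
        c = theta[n + 1]
        p = np.exp(ln_p)
        res_modes = ln_p + xi_hat * x / (b * Q_CONST * R) - c
        return np.concatenate([res_modes, [p.sum() - 1.0, p @ x - observed]])

    sol = least_squares(residuals, theta0, method="lm", xtol=1e-14, ftol=1e-14)
    return math.exp(sol.x[n]), np.exp(sol.x[:n])


def fit_strain(
    mode_thermos: Sequence[ModeThermo],
    obs: StrainObservation,
    observed_thermo: ModeThermo,
    *,
    variant: str = "entropy",
) -> MaxEntFit:
    """Calibrate b for one strain against its measured overall reaction.

    ``observed_thermo`` is the overall growth reaction's properties computed
    from the strain's measured external stoichiometry; the variant selects
    whether Δs or A/T carries the distribution.
    """
    if variant == "entropy":
        x = [mt.ds for mt in mode_thermos]
        target = observed_thermo.ds
    else:
        # A/T has entropy units; recover T from the Gibbs relation members
        T_ref = 310.15
        for mt in mode_thermos:
            if mt.ds:
                T_ref = (mt.dh - mt.dg) / mt.ds
                break
        x = [mt.affinity / T_ref for mt in mode_thermos]
        target = (-observed_thermo.dg) / T_ref
    return fit_b(x, obs.xi_hat, target, variant=variant)


# ---------------------------------------------------------------------------
# derived maximum rates
# ---------------------------------------------------------------------------


def predict_max_rates(
    obs: StrainObservation, fit_or_b: "MaxEntFit | float"
) -> dict[str, float]:
    """Maximum rates implied by the attained fraction b.

    Returns μ_max = μ/b [1/h], q_s,max = q_s/b [mmol/(h·gCDW), positive
    magnitude; the uptake sign convention makes it negative as a flux] and
    τ_min = ln2/μ_max [min].
    """
    b = fit_or_b.b if isinstance(fit_or_b, MaxEntFit) else float(fit_or_b)
    if b <= 0:
        raise ValueError("b must be positive")
    mu_max = obs.mu / b
    return {
        "b": b,
        "mu_max_per_h": mu_max,
        "qs_max_mmol_per_h_gCDW": obs.qs / b,
        "qs_max_signed": -obs.qs / b,
        "tau_min_minutes": math.log(2.0) / mu_max * 60.0,
    }


def compare_variants(
    mode_thermos: Sequence[ModeThermo],
    obs: StrainObservation,
    observed_thermo: ModeThermo,
) -> dict[str, dict[str, float]]:
    """Side-by-side entropy- vs affinity-variant fit report for one strain.

    Each entry carries b, c, Z, the predicted maxima and τ_min, plus a flag
    for whether that variant predicts a doubling time shorter than the
    currently measured one (ln2/μ).
    """
    report: dict[str, dict[str, float]] = {}
    tau_now = math.log(2.0) / obs.mu * 60.0
    for variant in VARIANTS:
        fit = fit_strain(mode_thermos, obs, observed_thermo, variant=variant)
        rates = predict_max_rates(obs, fit)
        report[variant] = {
            "b": fit.b,
            "c": fit.c,
            "Z": fit.Z,
            **rates,
            "tau_now_minutes": tau_now,
            "predicts_shorter_doubling": rates["tau_min_minutes"] < tau_now,
        }
    return report
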