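"""Steady-state CSTR balances: outlet concentrations, gas–liquid split,
system entropy/Gibbs content, and the two entropy production rates.

The serial-transfer batch culture is approximated as a continuously stirred
tank reactor at steady state with dilution rate equal to the specific growth
rate. At steady state the entropy content of the system is the feed term plus
the reaction contribution, ``S_sys = Σ s_i·c_i,in + τ·ξ̇·ΔS_R``, and likewise
``G_sys = Σ g_i·c_i,in + τ·ξ̇·ΔG_R = Σ g_i·c_i,in − τ·T·σ̇_rxn`` with the
volumetric entropy production rate ``σ̇_rxn = ξ̇·A/T`` (affinity A = −ΔG_R).

Two biomass-specific entropy production rates are distinguished:

* type 1 — affinity-based, ``ξ̂·Σ p_j·(−Δg_j)/T``; includes the enthalpic
  heat exported to the surroundings;
* type 2 — reaction-entropy-based, ``ξ̂·Σ p_j·Δs_j``; the part that remains
  in the system's entropy content.

They coincide exactly when every mode has zero reaction enthalpy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .thermo import ModeThermo

logger = logging.getLogger(__name__)

#: Antoine constants for water (log10 P[mmHg], T in °C), 1–100 °C range.
_ANTOINE_WATER = (8.07131, 1730.63, 233.426)
_MMHG_PER_BAR = 750.062

#: Molar concentration of liquid water, mol/L.
WATER_MOLARITY = 55.34

#: Species that participate effectively as pure gas-phase reactants.
GAS_PHASE_SPECIES = frozenset({"o2", "co2"})


class InfeasibleOperatingPoint(ValueError):
    """Requested extent of reaction drives a concentration negative."""


@dataclass
class CSTRState:
    """Operating point of the steady-state reactor.

    ``gas_flow`` is the aeration (headspace exchange) rate used for the
    water gas–liquid split; the default reproduces the ~4 mol% water vapor
    fraction at the stated culture scale (15 mL, D ≈ 0.9 1/h, 37 °C).
    """

    feed_concentrations: dict[str, float]  # mol/L
    space_time: float  # h (τ = V/F)
    temperature: float = 310.15  # K
    extent: float = 0.0  # ξ̇, mol/(L·h)
    volume: float = 0.015  # L
    gas_flow: float = 12.8  # L/h

    def __post_init__(self) -> None:
        if self.space_time <= 0:
            raise ValueError("space time must be positive")
        for met, c in self.feed_concentrations.items():
            if c < 0:
                raise ValueError(f"negative feed concentration for {met!r}")


@dataclass
class SystemThermo:
    """System-level balance outputs (per unit reactor volume)."""

    S_sys: float  # J/(K·L)
    G_sys: float  # J/L
    sigma_rxn: float  # type 1, J/(K·L·h)
    S_dot_type2: float | None = None  # J/(K·h·gCDW), when ξ̂ known


def outlet_concentrations(
    state: CSTRState,
    nu: Mapping[str, float],
    *,
    atol: float = 1e-9,
) -> dict[str, float]:
    """Steady-state outlet concentrations ``c_i = c_i,in + τ·ξ̇·ν_i``.

    Small negative results (within ``atol``) are floored at zero with a
    warning; larger ones raise :class:`InfeasibleOperatingPoint`.
    """
    out: dict[str, float] = {}
    mets = set(state.feed_concentrations) | set(nu)
    for met in mets:
        c = state.feed_concentrations.get(met, 0.0) + state.space_time * state.extent * float(
            nu.get(met, 0.0)
        )
        if c < -atol:
            raise InfeasibleOperatingPoint(
                f"outlet concentration of {met!r} would be {c:.3e} mol/L"
            )
        if c < 0:
            logger.warning("flooring tiny negative outlet concentration of %s", met)
            c = 0.0
        out[met] = c
    return out


def gas_liquid_partition(species: str, state: CSTRState) -> float:
    """Equilibrium gas-phase mole fraction of a species' throughput.

    O2 and CO2 are treated as pure gas-phase reactants (well-mixed, fully
    aerated culture); water splits between the liquid outflow and the
    water-vapor-saturated aeration stream via its vapor pressure; all other
    (nonvolatile) species return 0.
    """
    base = species[:-4] if species.endswith(".Ext") else species
    if base in GAS_PHASE_SPECIES:
        return 1.0
    if base != "h2o":
        return 0.0
    t_celsius = state.temperature - 273.15
    a, b, c = _ANTOINE_WATER
    p_vap_bar = 10 ** (a - b / (c + t_celsius)) / _MMHG_PER_BAR
    # vapor leaving with the saturated gas stream, mol/h (ideal gas,
    # P in Pa, V in m³)
    n_gas = state.gas_flow * (p_vap_bar * 1e5) * 1e-3 / (8.31446 * state.temperature)
    n_liq = (state.volume / state.space_time) * WATER_MOLARITY
    return n_gas / (n_gas + n_liq)


def default_gas_fractions(state: CSTRState) -> dict[str, float]:
    """Gas mole fractions for the standard aerobic culture: O2 and CO2 as
    gas-phase reactants, water split by the aeration balance."""
    return {
        "o2": 1.0,
        "co2": 1.0,
        "h2o": gas_liquid_partition("h2o", state),
    }


def system_entropy(
    state: CSTRState,
    s_in: Mapping[str, float],
    dS_R: float,
) -> float:
    """System entropy content ``Σ s_i·c_i,in + τ·ξ̇·ΔS_R`` [J/(K·L)].

    ``s_in`` gives molar entropies [J/(K·mol)] of the feed species evaluated
    at system conditions; ``dS_R`` is the overall reaction entropy per mole
    glucose [J/(K·mol)].
    """
    feed = sum(
        s_in[met] * c for met, c in state.feed_concentrations.items() if met in s_in
    )
    return feed + state.space_time * state.extent * dS_R


def system_gibbs(
    state: CSTRState,
    g_in: Mapping[str, float],
    dG_R: float,
) -> tuple[float, float]:
    """System Gibbs content and type 1 volumetric entropy production rate.

    Returns ``(G_sys, σ̇_rxn)`` with ``G_sys = Σ g_i·c_i,in + τ·ξ̇·ΔG_R``
    [J/L] and ``σ̇_rxn = ξ̇·A/T`` [J/(K·L·h)], A = −ΔG_R. The equivalent form
    ``G_sys = Σ g_i·c_i,in − τ·T·σ̇_rxn`` is verified internally.
    """
    feed = sum(
        g_in[met] * c for met, c in state.feed_concentrations.items() if met in g_in
    )
    g_sys = feed + state.space_time * state.extent * dG_R
    sigma = state.extent * (-dG_R) / state.temperature
    alt = feed - state.space_time * state.temperature * sigma
    assert abs(alt - g_sys) <= 1e-9 * max(1.0, abs(g_sys)), "Gibbs identity violated"
    return g_sys, sigma


def entropy_production_rates(
    p: Sequence[float],
    mode_thermos: Iterable[ModeThermo],
    xi_hat: float,
    T: float,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Biomass-specific type 1 and type 2 entropy production rates.

    Returns ``(type1, type2, per_mode_type1, per_mode_type2)`` with
    ``type1 = ξ̂·Σ p_j·(−Δg_j)/T`` and ``type2 = ξ̂·Σ p_j·Δs_j``
    [J/(K·h·gCDW)]; ξ̂ in mol glucose/(h·gCDW).
    """
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError(f"mode probabilities sum to {p.sum()}, not 1")
    thermos = list(mode_thermos)
    dg = np.array([mt.dg for mt in thermos])
    ds = np.array([mt.ds for mt in thermos])
    per_mode_1 = xi_hat * p * (-dg) / T
    per_mode_2 = xi_hat * p * ds
    return float(per_mode_1.sum()), float(per_mode_2.sum()), per_mode_1, per_mode_2
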