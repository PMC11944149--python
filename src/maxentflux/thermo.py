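"""Condition-adjusted biochemical thermodynamics of external metabolites.

Formation properties of each metabolite are represented as a *pseudoisomer
group*: the set of its ionic/protonation (and phase) forms, combined by
Boltzmann weighting of chemical potentials in Alberty's transformed
convention. Per-species adjustment at culture conditions applies

* an extended Debye–Hückel ionic-strength term
  ``− RT·α(T)·(z² − nH)·√I / (1 + 1.6·√I)``,
* the pH term ``+ nH·RT·ln10·pH``,
* the concentration term ``+ RT·ln(c/c°)`` (aqueous; partial pressure in bar
  for gas species),

with ``α(T) = 1.10708 − 1.54508e−3·T + 5.95584e−6·T²`` (kg½·mol⁻½, valid near
physiological temperatures). The enthalpy picks up the Gibbs–Helmholtz-
consistent ionic-strength term ``+ RT²·α'(T)·(z² − nH)·√I/(1 + 1.6·√I)``.

Per-mode reaction properties follow from linearity: ``Δg_j = Σ ν_ij·g_i``
(likewise Δh, and Δs via ``s_i = (h_i − g_i)/T``), so the Gibbs relation
``Δg = Δh − T·Δs`` holds by construction. Protons are the thermodynamic
reference at pH 7 (zero formation enthalpy and free energy) and contribute
only a bookkeeping count.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp

#: Universal gas constant, J/(K·mol).
R = 8.31446
R_KJ = R / 1000.0

#: Debye–Hückel denominator constant B, L^1/2 mol^−1/2.
DH_B = 1.6

#: Ids treated as the proton species (zero formation properties at pH 7).
PROTON_IDS = frozenset({"h", "h+", "h.Ext", "h+.Ext"})


def debye_huckel_alpha(T: float) -> float:
    """Alberty's α(T) polynomial; α(298.15) ≈ 1.17585."""
    return 1.10708 - 1.54508e-3 * T + 5.95584e-6 * T * T


def _debye_huckel_alpha_prime(T: float) -> float:
    return -1.54508e-3 + 2 * 5.95584e-6 * T


@dataclass
class PseudoisomerSpecies:
    """One ionic/phase form: standard formation properties at I = 0."""

    dfG0: float  # kJ/mol
    dfH0: float  # kJ/mol
    charge: int = 0
    nH: float = 0.0
    phase: str = "aqueous"  # aqueous | gas

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dfG0) and math.isfinite(self.dfH0)):
            raise ValueError("formation properties must be finite")
        if self.nH < 0:
            raise ValueError("nH must be nonnegative")


@dataclass
class PseudoisomerGroup:
    metabolite_id: str
    species: list[PseudoisomerSpecies]
    gas_fraction: float | None = None  # mole fraction in gas phase, if mixed

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError(f"group {self.metabolite_id!r} has no species")

    def phases(self) -> set[str]:
        return {sp.phase for sp in self.species}


@dataclass
class Conditions:
    """Culture conditions for thermodynamic adjustment.

    ``concentrations`` maps metabolite id to mol/L (aqueous) or partial
    pressure in bar (gas); unlisted species sit at the reference state.
    """

    T: float = 310.15  # K
    pH: float = 7.0
    ionic_strength: float = 0.25  # mol/L
    concentrations: dict[str, float] = field(default_factory=dict)
    reference_concentration: float = 1.0  # mol/L (and 1 bar for gases)

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be nonnegative")
        for met, c in self.concentrations.items():
            if c <= 0:
                raise ValueError(f"nonpositive concentration for {met!r}")

    def concentration(self, met_id: str) -> float:
        key = met_id[:-4] if met_id.endswith(".Ext") else met_id
        return self.concentrations.get(
            met_id, self.concentrations.get(key, self.reference_concentration)
        )


@dataclass
class AdjustedProperties:
    """Condition-adjusted effective formation properties of one metabolite."""

    g: float  # kJ/mol (transformed chemical potential)
    h: float  # kJ/mol
    mean_charge: float
    mean_nH: float
    weights: np.ndarray | None = None

    def entropy(self, T: float) -> float:
        """Molar formation entropy (h − g)/T, kJ/(K·mol)."""
        return (self.h - self.g) / T


@dataclass
class ModeThermo:
    """Reaction properties of one elementary mode, per mole glucose."""

    ds: float  # J/(K·mol glucose)
    dh: float  # J/mol glucose
    dg: float  # J/mol glucose
    protons_balanced: float = 0.0

    @property
    def affinity(self) -> float:
        """A = −Δg, J/mol glucose."""
        return -self.dg


# ---------------------------------------------------------------------------
# species adjustment and pseudoisomer averaging
# ---------------------------------------------------------------------------


def adjust_species(
    sp: PseudoisomerSpecies, cond: Conditions, concentration: float | None = None
) -> tuple[float, float]:
    """Chemical potential and enthalpy (kJ/mol) of one species at conditions."""
    c = cond.reference_concentration if concentration is None else concentration
    if c <= 0:
        raise ValueError("nonpositive concentration")
    RT = R_KJ * cond.T
    sqrt_i = math.sqrt(cond.ionic_strength)
    dh_factor = sqrt_i / (1.0 + DH_B * sqrt_i)
    znh = sp.charge**2 - sp.nH
    mu = (
        sp.dfG0
        - RT * debye_huckel_alpha(cond.T) * znh * dh_factor
        + sp.nH * RT * math.log(10.0) * cond.pH
        + RT * math.log(c / cond.reference_concentration)
    )
    h = sp.dfH0 + R_KJ * cond.T**2 * _debye_huckel_alpha_prime(cond.T) * znh * dh_factor
    return mu, h


def pseudoisomer_average(
    group: PseudoisomerGroup,
    cond: Conditions,
    concentration: float | None = None,
    species: Iterable[PseudoisomerSpecies] | None = None,
) -> AdjustedProperties:
    """Boltzmann-weighted average over the (aqueous) pseudoisomer forms.

    Weights are ``p_i = exp((μ_iso − μ_i)/RT)`` with the group potential
    ``μ_iso = −RT·ln Σ_i exp(−μ_i/RT)``; they sum to one and are invariant to
    a constant shift of all μ_i. The effective enthalpy, mean charge and mean
    hydrogen count are p_i-weighted means.
    """
    members = list(group.species if species is None else species)
    if not members:
        raise ValueError(f"group {group.metabolite_id!r}: no species to average")
    if concentration is None:
        concentration = cond.concentration(group.metabolite_id)
    RT = R_KJ * cond.T
    mus, hs = zip(*(adjust_species(sp, cond, concentration) for sp in members))
    mus = np.asarray(mus)
    hs = np.asarray(hs)
    log_w = -mus / RT
    mu_iso = -RT * logsumexp(log_w)
    weights = np.exp(log_w - logsumexp(log_w))
    return AdjustedProperties(
        g=mu_iso,
        h=float(weights @ hs),
        mean_charge=float(weights @ np.array([sp.charge for sp in members])),
        mean_nH=float(weights @ np.array([sp.nH for sp in members])),
        weights=weights,
    )


def phase_average(
    liquid: AdjustedProperties, gas: AdjustedProperties, gas_fraction: float
) -> AdjustedProperties:
    """Molar average of liquid- and gas-phase effective properties."""
    if not 0.0 <= gas_fraction <= 1.0:
        raise ValueError(f"gas fraction {gas_fraction} outside [0, 1]")
    x = gas_fraction
    return AdjustedProperties(
        g=(1 - x) * liquid.g + x * gas.g,
        h=(1 - x) * liquid.h + x * gas.h,
        mean_charge=(1 - x) * liquid.mean_charge + x * gas.mean_charge,
        mean_nH=(1 - x) * liquid.mean_nH + x * gas.mean_nH,
    )


# ---------------------------------------------------------------------------
# thermodynamic table
# ---------------------------------------------------------------------------


class ThermoTable:
    """Lookup of pseudoisomer groups, with condition-adjusted averaging.

    The TSV schema is ``metabolite, species, dfG0_kJ_mol, dfH0_kJ_mol,
    charge, nH, phase`` with one row per pseudoisomer form.
    """

    def __init__(self, groups: Iterable[PseudoisomerGroup]) -> None:
        self.groups = {g.metabolite_id: g for g in groups}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ThermoTable":
        groups = []
        for met, sub in df.groupby("metabolite", sort=False):
            species = [
                PseudoisomerSpecies(
                    dfG0=row.dfG0_kJ_mol,
                    dfH0=row.dfH0_kJ_mol,
                    charge=int(row.charge),
                    nH=float(row.nH),
                    phase=str(row.phase),
                )
                for row in sub.itertuples()
            ]
            groups.append(PseudoisomerGroup(metabolite_id=str(met), species=species))
        return cls(groups)

    @classmethod
    def from_tsv(cls, path) -> "ThermoTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"))

    @classmethod
    def curated(cls) -> "ThermoTable":
        """The small built-in table (standard Alberty/Atkins-style values)."""
        ref = importlib.resources.files("maxentflux.data") / "species_thermo.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def group(self, met_id: str) -> PseudoisomerGroup:
        if met_id in self.groups:
            return self.groups[met_id]
        if met_id.endswith(".Ext") and met_id[:-4] in self.groups:
            return self.groups[met_id[:-4]]
        raise KeyError(f"no thermodynamic data for metabolite {met_id!r}")

    def adjusted(
        self,
        met_id: str,
        cond: Conditions,
        gas_fractions: Mapping[str, float] | None = None,
    ) -> AdjustedProperties:
        """Effective formation properties of one metabolite at conditions.

        Groups containing both aqueous and gas forms are combined with the
        metabolite's gas mole fraction (from ``gas_fractions``, the group's
        own ``gas_fraction``, else 1.0 for all-gas groups / 0.0 otherwise).
        """
        group = self.group(met_id)
        aq = [sp for sp in group.species if sp.phase != "gas"]
        gas = [sp for sp in group.species if sp.phase == "gas"]
        conc = cond.concentration(met_id)
        if not gas:
            return pseudoisomer_average(group, cond, conc)
        if not aq:
            return pseudoisomer_average(group, cond, conc, species=gas)
        x = None
        if gas_fractions is not None:
            base = met_id[:-4] if met_id.endswith(".Ext") else met_id
            x = gas_fractions.get(met_id, gas_fractions.get(base))
        if x is None:
            x = group.gas_fraction if group.gas_fraction is not None else 0.0
        liq_props = pseudoisomer_average(group, cond, conc, species=aq)
        gas_props = pseudoisomer_average(group, cond, conc, species=gas)
        return phase_average(liq_props, gas_props, x)


# ---------------------------------------------------------------------------
# proton balance and reaction properties
# ---------------------------------------------------------------------------


def proton_balance(
    external_stoich: Mapping[str, float],
    mean_charges: Mapping[str, float],
) -> float:
    """Protons to add to a mode's stoichiometry for charge neutrality.

    Returns the h⁺ coefficient ``−Σ ν_i·z̄_i`` over the charged external
    metabolites (mean charges from pseudoisomer averaging).

    Raises
    ------
    KeyError
        If a charged metabolite lacks mean-charge data.
    """
    total = 0.0
    for met, coeff in external_stoich.items():
        if met in PROTON_IDS:
            continue
        if met not in mean_charges:
            raise KeyError(f"no mean charge for metabolite {met!r}")
        total += float(coeff) * float(mean_charges[met])
    return -total


def mode_reaction_properties(
    external_stoich: Mapping[str, float],
    table: ThermoTable,
    cond: Conditions,
    gas_fractions: Mapping[str, float] | None = None,
) -> ModeThermo:
    """Δs, Δh, Δg (J basis) of one mode's external reaction equation.

    Sums ν_i-weighted adjusted formation properties over the external
    metabolites; molar entropies are ``s_i = (h_i − g_i)/T`` so the Gibbs
    relation is exact. Proton species contribute only to the proton count.
    """
    dg = 0.0
    dh = 0.0
    protons = 0.0
    for met, coeff in external_stoich.items():
        nu = float(coeff)
        if met in PROTON_IDS:
            protons += nu
            continue
        props = table.adjusted(met, cond, gas_fractions)
        dg += nu * props.g
        dh += nu * props.h
    dg *= 1000.0  # kJ -> J
    dh *= 1000.0
    return ModeThermo(
        ds=(dh - dg) / cond.T, dh=dh, dg=dg, protons_balanced=protons
    )


#: The overall growth reaction obeys the same linear combination rule.
overall_reaction_properties = mode_reaction_properties


def mode_thermo_frame(mode_thermos: Iterable[ModeThermo]) -> pd.DataFrame:
    """Tabulate per-mode properties for TSV export (explicit unit headers)."""
    rows = [
        {
            "mode": j + 1,
            "ds_J_per_K_mol_glc": mt.ds,
            "dh_J_per_mol_glc": mt.dh,
            "dg_J_per_mol_glc": mt.dg,
            "affinity_J_per_mol_glc": mt.affinity,
            "protons_balanced": mt.protons_balanced,
        }
        for j, mt in enumerate(mode_thermos)
    ]
    return pd.DataFrame(rows)
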