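"""Metabolic reaction networks as plain-text reaction lists.

A network is a set of metabolites (internal or external, i.e. crossing the
system boundary) and an ordered list of reactions with signed rational
stoichiometry. External metabolites are excluded from the steady-state
constraint; the stoichiometric matrix ``S_int`` spans internal metabolites
only. Coefficients are kept as exact :class:`fractions.Fraction` so that
downstream elementary-mode elementarity tests can use exact ranks.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ELEMENTS = ("C", "H", "N", "O", "P", "S")

#: Default suffix marking a species as external (boundary) in the text dialect.
EXTERNAL_SUFFIX = ".Ext"

#: Conventional ids for the proton species and the proton-balance reaction.
PROTON_ID = "h"
PROTON_BALANCE_REACTION = "v74"


class NetworkError(ValueError):
    """Raised for malformed or inconsistent network definitions."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: dict[str, float] = field(default_factory=dict)
    charge: int = 0
    phase: str = "aqueous"  # aqueous | gas | biomass | mixed
    external: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id
        for elem, count in self.formula.items():
            if count < 0:
                raise NetworkError(
                    f"metabolite {self.id!r}: negative {elem} count {count}"
                )


@dataclass
class Reaction:
    id: str
    stoich: dict[str, Fraction]
    reversible: bool = False

    def __post_init__(self) -> None:
        self.stoich = {m: Fraction(c) for m, c in self.stoich.items() if c != 0}
        if not self.stoich:
            raise NetworkError(f"reaction {self.id!r} has empty stoichiometry")

    @property
    def reactants(self) -> dict[str, Fraction]:
        return {m: -c for m, c in self.stoich.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {m: c for m, c in self.stoich.items() if c > 0}


class ReactionNetwork:
    """Validated reaction network with deterministic metabolite/reaction order.

    Parameters
    ----------
    metabolites :
        Metabolite records; order fixes the row order of ``S_int``.
    reactions :
        Reaction records; order fixes the column order of ``S_int``.
    balance_exempt :
        Internal metabolite ids excluded from the steady-state constraint
        (e.g. the proton species when an explicit proton-balance reaction
        closes its balance).
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        balance_exempt: Iterable[str] = (),
    ) -> None:
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.balance_exempt: set[str] = set(balance_exempt)
        self._met_index = {m.id: m for m in self.metabolites}
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise NetworkError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
            for met in rxn.stoich:
                if met not in self._met_index:
                    raise NetworkError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                    )
        mids = [m.id for m in self.metabolites]
        if len(mids) != len(set(mids)):
            raise NetworkError("duplicate metabolite id")

    # -- accessors -----------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_ids(self) -> list[str]:
        """Internal metabolites subject to the steady-state constraint."""
        return [
            m.id
            for m in self.metabolites
            if not m.external and m.id not in self.balance_exempt
        ]

    @property
    def external_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.external]

    # -- matrices ------------------------------------------------------------

    def stoichiometric_matrix(self, *, exact: bool = False) -> np.ndarray:
        """Internal stoichiometric matrix ``S_int``.

        Rows follow metabolite input order (internal only), columns follow
        reaction input order. ``exact=True`` returns an object array of
        Fractions; otherwise float64.
        """
        rows = self.internal_ids
        ridx = {m: i for i, m in enumerate(rows)}
        if exact:
            S = np.full((len(rows), len(self.reactions)), Fraction(0), dtype=object)
        else:
            S = np.zeros((len(rows), len(self.reactions)))
        for k, rxn in enumerate(self.reactions):
            for met, coeff in rxn.stoich.items():
                i = ridx.get(met)
                if i is not None:
                    S[i, k] = coeff if exact else float(coeff)
        return S

    def external_matrix(self, *, exact: bool = False) -> np.ndarray:
        """Like ``stoichiometric_matrix`` but over external metabolites."""
        rows = self.external_ids
        ridx = {m: i for i, m in enumerate(rows)}
        if exact:
            S = np.full((len(rows), len(self.reactions)), Fraction(0), dtype=object)
        else:
            S = np.zeros((len(rows), len(self.reactions)))
        for k, rxn in enumerate(self.reactions):
            for met, coeff in rxn.stoich.items():
                i = ridx.get(met)
                if i is not None:
                    S[i, k] = coeff if exact else float(coeff)
        return S

    def s_int_frame(self) -> pd.DataFrame:
        """``S_int`` as a labelled DataFrame (floats), for TSV export."""
        return pd.DataFrame(
            self.stoichiometric_matrix(),
            index=self.internal_ids,
            columns=self.reaction_ids,
        )

    def to_tsv(self, path) -> None:
        self.s_int_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Text dialect:  "id: c1 A + c2 B => c3 C"  /  "<=>" for reversible
# ---------------------------------------------------------------------------

_ARROW_RE = re.compile(r"<=>|=>")
_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?|\d+/\d+)\s+)?(\S+)$")


def _parse_side(side: str, line_no: int) -> list[tuple[Fraction, str]]:
    terms: list[tuple[Fraction, str]] = []
    side = side.strip()
    if not side:
        return terms
    for chunk in side.split("+"):
        chunk = chunk.strip()
        if not chunk:
            raise NetworkError(f"line {line_no}: empty term")
        m = _TERM_RE.match(chunk)
        if m is None:
            raise NetworkError(f"line {line_no}: cannot parse term {chunk!r}")
        coeff_s, species = m.groups()
        coeff = Fraction(coeff_s) if coeff_s else Fraction(1)
        terms.append((coeff, species))
    return terms


def parse_reaction_list(
    text: str,
    *,
    external_suffix: str = EXTERNAL_SUFFIX,
    external_ids: Iterable[str] = (),
    proton_id: str = PROTON_ID,
    proton_balance_reaction: str = PROTON_BALANCE_REACTION,
) -> ReactionNetwork:
    """Parse the plain-text reaction-list dialect into a network.

    Each non-empty, non-comment line reads ``id: reactants <arrow> products``
    with arrow ``=>`` (irreversible) or ``<=>`` (reversible); omitted
    coefficients default to 1. Species carrying ``external_suffix`` (or listed
    in ``external_ids``) are external. If a reaction named
    ``proton_balance_reaction`` exists, ``proton_id`` is exempted from the
    steady-state constraint.

    Raises
    ------
    NetworkError
        On duplicate reaction ids or unparseable lines (with line number).
    """
    external_ids = set(external_ids)
    reactions: list[Reaction] = []
    met_ids: list[str] = []
    seen_mets: set[str] = set()
    seen_rxns: set[str] = set()

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise NetworkError(f"line {line_no}: missing 'id:' prefix in {line!r}")
        rxn_id, body = line.split(":", 1)
        rxn_id = rxn_id.strip()
        if rxn_id in seen_rxns:
            raise NetworkError(f"line {line_no}: duplicate reaction id {rxn_id!r}")
        arrows = _ARROW_RE.findall(body)
        if len(arrows) != 1:
            raise NetworkError(f"line {line_no}: expected one '=>' or '<=>' arrow")
        lhs, rhs = _ARROW_RE.split(body)
        stoich: dict[str, Fraction] = {}
        for coeff, species in _parse_side(lhs, line_no):
            stoich[species] = stoich.get(species, Fraction(0)) - coeff
        for coeff, species in _parse_side(rhs, line_no):
            stoich[species] = stoich.get(species, Fraction(0)) + coeff
        for species in stoich:
            if species not in seen_mets:
                seen_mets.add(species)
                met_ids.append(species)
        reactions.append(
            Reaction(id=rxn_id, stoich=stoich, reversible=arrows[0] == "<=>")
        )
        seen_rxns.add(rxn_id)

    # suffix-and-bare pairs (glc.Ext / glc) are kept as two distinct species
    bare = {m for m in met_ids if not m.endswith(external_suffix)}
    pairs = [
        m
        for m in met_ids
        if m.endswith(external_suffix) and m[: -len(external_suffix)] in bare
    ]
    if pairs:
        logger.info(
            "species occurring both with and without %r treated as distinct "
            "external/internal pairs: %s",
            external_suffix,
            ", ".join(pairs),
        )

    balance_exempt: set[str] = set()
    if proton_balance_reaction in seen_rxns and proton_id in seen_mets:
        balance_exempt.add(proton_id)

    metabolites = [
        Metabolite(
            id=m,
            external=m.endswith(external_suffix) or m in external_ids,
        )
        for m in met_ids
    ]
    return ReactionNetwork(metabolites, reactions, balance_exempt=balance_exempt)


def serialize_reaction_list(network: ReactionNetwork) -> str:
    """Inverse of :func:`parse_reaction_list` on the canonical dialect."""

    def fmt(coeff: Fraction, species: str) -> str:
        if coeff == 1:
            return species
        c = str(coeff) if coeff.denominator != 1 else str(coeff.numerator)
        return f"{c} {species}"

    lines = []
    for rxn in network.reactions:
        lhs = " + ".join(fmt(-c, m) for m, c in rxn.stoich.items() if c < 0)
        rhs = " + ".join(fmt(c, m) for m, c in rxn.stoich.items() if c > 0)
        arrow = "<=>" if rxn.reversible else "=>"
        lines.append(f"{rxn.id}: {lhs} {arrow} {rhs}".strip())
    return "\n".join(lines) + "\n"


def elemental_balance_report(
    network: ReactionNetwork,
    formulas: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Per-reaction elemental imbalance over C, H, N, O, P, S.

    ``formulas`` maps metabolite id to element→count; metabolites absent from
    it fall back to the network's own formula fields. A reaction touching any
    species with no formula at all is flagged ``uncheckable`` rather than
    raising. A zero row means the reaction is balanced.
    """
    formulas = dict(formulas or {})
    rows = []
    for rxn in network.reactions:
        imbalance = {e: 0.0 for e in ELEMENTS}
        checkable = True
        for met, coeff in rxn.stoich.items():
            formula = formulas.get(met)
            if formula is None:
                formula = network.metabolite(met).formula or None
            if formula is None:
                checkable = False
                break
            for e in ELEMENTS:
                imbalance[e] += float(coeff) * float(formula.get(e, 0))
        row = {"reaction": rxn.id, "checkable": checkable}
        row.update(imbalance if checkable else {e: np.nan for e in ELEMENTS})
        rows.append(row)
    df = pd.DataFrame(rows).set_index("reaction")
    df["balanced"] = df["checkable"] & (
        df[list(ELEMENTS)].abs().le(1e-9).all(axis=1)
    )
    return df


def stoichiometric_matrix(network: ReactionNetwork, *, exact: bool = False) -> np.ndarray:
    """Module-level convenience alias for ``network.stoichiometric_matrix``."""
    return network.stoichiometric_matrix(exact=exact)


def from_sbml(path) -> ReactionNetwork:
    """Import an SBML model, mapping boundary condition to ``external``.

    Requires cobra (installs python-libsbml). Exchange/boundary species and
    cobra boundary metabolites become external; reversibility comes from the
    flux bounds.
    """
    import cobra  # deferred: optional dependency

    model = cobra.io.read_sbml_model(str(path))
    mets = []
    for m in model.metabolites:
        formula = {}
        if m.elements:
            formula = {e: float(c) for e, c in m.elements.items() if e in ELEMENTS}
        mets.append(
            Metabolite(
                id=m.id,
                name=m.name or m.id,
                formula=formula,
                charge=int(m.charge or 0),
                external=bool(getattr(m, "boundary_condition", False))
                or m.compartment in ("e", "extracellular"),
            )
        )
    rxns = []
    for r in model.reactions:
        stoich = {m.id: Fraction(c).limit_denominator(10**6) for m, c in r.metabolites.items()}
        rxns.append(Reaction(id=r.id, stoich=stoich, reversible=r.reversibility))
    return ReactionNetwork(mets, rxns)
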