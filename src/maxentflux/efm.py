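"""Elementary flux mode enumeration, import, and glucose normalization.

An elementary flux mode (EFM) is a support-minimal flux vector satisfying the
steady-state constraint ``S_int · v = 0`` with nonnegative flux on every
irreversible reaction. Enumeration uses the classical tableau (double
description) scheme over exact rational arithmetic: reversible reactions are
split into forward/backward nonnegative pairs, internal metabolites are
eliminated one at a time by pairwise combination of candidate rays, and
non-minimal candidates are pruned by the support-subset test. The trivial
forward+backward two-cycles created by splitting are discarded and split
pairs recombined to signed net fluxes.

Modes are reported up to positive scaling; :func:`normalize_to_glucose`
rescales each mode so its external glucose coefficient is exactly −1 (the
per-mole-glucose convention used throughout the statistics), segregating
zero-glucose (futile or glucose-independent) modes into a separate subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd
from typing import Sequence

import numpy as np
import pandas as pd

from .network import ReactionNetwork

ZERO = Fraction(0)


class EnumerationCapExceeded(RuntimeError):
    """Candidate count exceeded the configured combinatorial guard."""


class ModeValidationError(ValueError):
    """An imported mode row violates steady state or irreversibility."""


@dataclass
class ElementaryMode:
    """One elementary mode: net fluxes per reaction and its net external
    stoichiometry (per the current scaling)."""

    flux: dict[str, Fraction]
    external_stoich: dict[str, Fraction] = field(default_factory=dict)

    @property
    def support(self) -> frozenset[str]:
        return frozenset(r for r, v in self.flux.items() if v != 0)

    def scaled(self, factor: Fraction) -> "ElementaryMode":
        return ElementaryMode(
            flux={r: v * factor for r, v in self.flux.items()},
            external_stoich={m: c * factor for m, c in self.external_stoich.items()},
        )


@dataclass
class ElementaryModeSet:
    modes: list[ElementaryMode]
    reaction_ids: list[str]
    network_ref: str = ""
    non_glucose: list[ElementaryMode] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.modes)

    def __iter__(self):
        return iter(self.modes)

    def __len__(self) -> int:
        return len(self.modes)

    def flux_matrix(self) -> np.ndarray:
        """Modes × reactions float matrix in ``reaction_ids`` column order."""
        M = np.zeros((len(self.modes), len(self.reaction_ids)))
        for j, mode in enumerate(self.modes):
            for k, rid in enumerate(self.reaction_ids):
                M[j, k] = float(mode.flux.get(rid, ZERO))
        return M

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.flux_matrix(),
            columns=self.reaction_ids,
            index=[f"em{j + 1}" for j in range(len(self.modes))],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def _normalize_ray(flux: tuple[Fraction, ...]) -> tuple[Fraction, ...]:
    """Scale a nonnegative rational ray to coprime integers."""
    denom_lcm = 1
    for v in flux:
        if v != 0:
            denom_lcm = denom_lcm * v.denominator // gcd(denom_lcm, v.denominator)
    ints = [int(v * denom_lcm) for v in flux]
    g = 0
    for x in ints:
        g = gcd(g, abs(x))
    if g == 0:
        return flux
    return tuple(Fraction(x, g) for x in ints)


def _external_stoich(
    network: ReactionNetwork, flux: dict[str, Fraction]
) -> dict[str, Fraction]:
    out: dict[str, Fraction] = {}
    ext = set(network.external_ids)
    for rxn in network.reactions:
        v = flux.get(rxn.id, ZERO)
        if v == 0:
            continue
        for met, coeff in rxn.stoich.items():
            if met in ext:
                out[met] = out.get(met, ZERO) + coeff * v
    return {m: c for m, c in out.items() if c != 0}


def enumerate_modes(
    network: ReactionNetwork, *, max_candidates: int = 2_000_000
) -> ElementaryModeSet:
    """Enumerate all elementary flux modes of ``network``.

    Returns modes ordered lexicographically by reaction support, each scaled
    to coprime integer fluxes. An empty nullspace yields an empty set.

    Raises
    ------
    EnumerationCapExceeded
        If intermediate candidate counts exceed ``max_candidates``.
    """
    if not network.reactions:
        raise ValueError("network has no reactions")

    # split reversible reactions into nonnegative forward/backward columns
    cols: list[tuple[str, int]] = []  # (reaction id, direction ±1)
    for rxn in network.reactions:
        cols.append((rxn.id, +1))
        if rxn.reversible:
            cols.append((rxn.id, -1))
    q = len(cols)

    S = network.stoichiometric_matrix(exact=True)
    m = S.shape[0]
    # column of split matrix = direction * original column
    rxn_index = {r.id: k for k, r in enumerate(network.reactions)}

    # tableau rows: (flux tuple over split cols, metabolite tuple)
    rows: list[tuple[tuple[Fraction, ...], tuple[Fraction, ...]]] = []
    for j, (rid, direction) in enumerate(cols):
        flux = tuple(Fraction(int(i == j)) for i in range(q))
        k = rxn_index[rid]
        met = tuple(direction * S[i, k] for i in range(m))
        rows.append((flux, met))

    for i in range(m):
        zero = [r for r in rows if r[1][i] == 0]
        pos = [r for r in rows if r[1][i] > 0]
        neg = [r for r in rows if r[1][i] < 0]
        combos: list[tuple[tuple[Fraction, ...], tuple[Fraction, ...]]] = []
        if len(zero) + len(pos) * len(neg) > max_candidates:
            raise EnumerationCapExceeded(
                f"metabolite {i}: {len(pos) * len(neg)} pair combinations exceed "
                f"cap {max_candidates}"
            )
        for fp, mp in pos:
            a = mp[i]
            for fn, mn in neg:
                b = mn[i]  # b < 0
                new_flux = tuple(a * x - b * y for x, y in zip(fn, fp))
                new_met = tuple(a * x - b * y for x, y in zip(mn, mp))
                combos.append((new_flux, new_met))

        # prune: keep combos whose support has no strict superset relation
        # with any kept candidate; dedupe identical supports
        supports_zero = [frozenset(j for j, v in enumerate(f) if v != 0) for f, _ in zero]
        kept: list[tuple[tuple[Fraction, ...], tuple[Fraction, ...]]] = list(zero)
        kept_supports = list(supports_zero)
        seen: set[frozenset[int]] = set(supports_zero)
        all_supports = supports_zero + [
            frozenset(j for j, v in enumerate(f) if v != 0) for f, _ in combos
        ]
        for (f, mt), supp in zip(combos, all_supports[len(zero):]):
            if supp in seen:
                continue
            if any(other < supp for other in all_supports if other != supp):
                continue
            kept.append((f, mt))
            kept_supports.append(supp)
            seen.add(supp)
        rows = kept

    # collapse split columns to signed net fluxes; drop splitting two-cycles
    modes: list[ElementaryMode] = []
    seen_support: set[frozenset[str]] = set()
    for flux, _ in rows:
        net: dict[str, Fraction] = {}
        for j, (rid, direction) in enumerate(cols):
            if flux[j] != 0:
                net[rid] = net.get(rid, ZERO) + direction * flux[j]
        net = {r: v for r, v in net.items() if v != 0}
        if not net:  # pure forward+backward two-cycle
            continue
        support = frozenset(net)
        if support in seen_support:
            continue
        seen_support.add(support)
        vec = _normalize_ray(tuple(net.get(r.id, ZERO) for r in network.reactions))
        net = {r.id: v for r, v in zip(network.reactions, vec) if v != 0}
        modes.append(
            ElementaryMode(flux=net, external_stoich=_external_stoich(network, net))
        )

    # final global minimality pass (cheap; guards pruning edge cases)
    supports = [mo.support for mo in modes]
    modes = [
        mo
        for mo, supp in zip(modes, supports)
        if not any(other < supp for other in supports)
    ]

    order = {r: k for k, r in enumerate(network.reaction_ids)}
    modes.sort(key=lambda mo: tuple(sorted(order[r] for r in mo.support)))
    return ElementaryModeSet(
        modes=modes, reaction_ids=list(network.reaction_ids), network_ref="enumerated"
    )


# ---------------------------------------------------------------------------
# import / export
# ---------------------------------------------------------------------------


def import_modes(
    table, network: ReactionNetwork, *, atol: float = 1e-9
) -> ElementaryModeSet:
    """Validate and load a precomputed mode matrix (one row per mode).

    ``table`` is a DataFrame or a TSV path with reaction ids as columns (any
    column order; extra columns rejected). Every row must satisfy
    ``S_int · v = 0`` within ``atol`` and the irreversibility sign pattern.

    Raises
    ------
    ModeValidationError
        Naming the offending row index and constraint.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    missing = set(table.columns) - set(network.reaction_ids)
    if missing:
        raise ModeValidationError(f"columns not in network: {sorted(missing)}")
    # align to network reaction order, absent reactions carry zero flux
    aligned = table.reindex(columns=network.reaction_ids, fill_value=0.0)
    V = aligned.to_numpy(dtype=float)
    S = network.stoichiometric_matrix()
    residual = S @ V.T
    irreversible = np.array([not r.reversible for r in network.reactions])
    modes = []
    for j in range(V.shape[0]):
        scale = max(1.0, float(np.abs(V[j]).max()))
        if np.abs(residual[:, j]).max() > atol * scale:
            raise ModeValidationError(f"row {j}: violates steady state S_int·v=0")
        if np.any(V[j, irreversible] < -atol * scale):
            raise ModeValidationError(
                f"row {j}: negative flux on irreversible reaction"
            )
        flux = {
            rid: Fraction(V[j, k]).limit_denominator(10**9)
            for k, rid in enumerate(network.reaction_ids)
            if V[j, k] != 0
        }
        modes.append(
            ElementaryMode(flux=flux, external_stoich=_external_stoich(network, flux))
        )
    return ElementaryModeSet(
        modes=modes, reaction_ids=list(network.reaction_ids), network_ref="imported"
    )


def normalize_to_glucose(
    modes: ElementaryModeSet, glucose_id: str
) -> ElementaryModeSet:
    """Rescale each mode so its external glucose coefficient is exactly −1.

    Modes with zero glucose exchange (futile cycles, glucose-independent
    paths) are moved to the returned set's ``non_glucose`` list and excluded
    from the main set — they carry no glucose-uptake fraction and never enter
    the Boltzmann partition function.

    Raises
    ------
    ValueError
        If any mode *produces* external glucose.
    """
    main: list[ElementaryMode] = []
    non_glucose: list[ElementaryMode] = []
    for j, mode in enumerate(modes):
        coeff = mode.external_stoich.get(glucose_id, ZERO)
        if coeff == 0:
            non_glucose.append(mode)
            continue
        if coeff > 0:
            raise ValueError(f"mode {j} produces external glucose ({coeff})")
        main.append(mode.scaled(Fraction(-1, 1) / coeff))
    return ElementaryModeSet(
        modes=main,
        reaction_ids=list(modes.reaction_ids),
        network_ref=modes.network_ref,
        non_glucose=non_glucose,
    )


def external_stoichiometry(
    network: ReactionNetwork, flux: dict[str, Fraction]
) -> dict[str, Fraction]:
    """Net external-metabolite stoichiometry of an arbitrary flux vector."""
    return _external_stoich(network, flux)
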