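"""Independent oracles used by the test suite.

Deliberately simple and slow: brute-force support-subset enumeration of
elementary modes (exact rational arithmetic via sympy), an arbitrary-
precision Boltzmann evaluation (mpmath), and an independent transcription of
the transformed-potential formulas for pseudoisomer groups. None of these
share code paths with the package.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import mpmath
import sympy


def brute_force_efms(network) -> set[tuple]:
    """All elementary modes by support-subset enumeration.

    A reaction subset is an EFM support iff the kernel of S_int restricted
    to those columns is one-dimensional, its basis vector has no zero entry,
    and it (or its negation) is nonnegative on every irreversible reaction.
    Returns normalized flux tuples over the full reaction list.
    """
    S = sympy.Matrix(
        [[sympy.Rational(x) for x in row]
         for row in network.stoichiometric_matrix(exact=True).tolist()]
    )
    q = len(network.reactions)
    irreversible = [not r.reversible for r in network.reactions]
    result: set[tuple] = set()
    for r in range(1, q + 1):
        for subset in itertools.combinations(range(q), r):
            sub = S[:, list(subset)]
            null = sub.nullspace()
            if len(null) != 1:
                continue
            u = null[0]
            if any(x == 0 for x in u):
                continue  # support smaller than subset
            # orient to satisfy irreversibility
            for sign in (1, -1):
                v = sign * u
                if all(
                    v[i] >= 0
                    for i, k in enumerate(subset)
                    if irreversible[k]
                ):
                    full = [sympy.Integer(0)] * q
                    for i, k in enumerate(subset):
                        full[k] = v[i]
                    result.add(_normalize(full))
                    break
    return result


def _normalize(vec) -> tuple:
    fracs = [Fraction(int(x.p), int(x.q)) for x in [sympy.Rational(v) for v in vec]]
    denom_lcm = 1
    for f in fracs:
        if f != 0:
            denom_lcm = sympy.ilcm(denom_lcm, f.denominator)
    ints = [int(f * denom_lcm) for f in fracs]
    g = 0
    for x in ints:
        g = sympy.igcd(g, abs(x))
    return tuple(Fraction(x, g) for x in ints) if g else tuple(fracs)


def mode_set_as_tuples(modes, reaction_ids) -> set[tuple]:
    """Normalize a package mode set for comparison with the oracle."""
    out = set()
    for mode in modes:
        vec = [mode.flux.get(rid, Fraction(0)) for rid in reaction_ids]
        out.add(_normalize([sympy.Rational(f.numerator, f.denominator) for f in vec]))
    return out


def boltzmann_highprec(x, xi_hat, b, R="8.31446", dps=60):
    """Arbitrary-precision Boltzmann probabilities (independent formula)."""
    with mpmath.workdps(dps):
        R = mpmath.mpf(R)
        expo = [-mpmath.mpf(repr(xi_hat)) * mpmath.mpf(repr(xj)) / (mpmath.mpf(repr(b)) * R) for xj in x]
        zs = [mpmath.e**e for e in expo]
        Z = sum(zs)
        return [float(z / Z) for z in zs], float(Z)


def alberty_group_potential(species, T, pH, ionic_strength, conc=1.0):
    """Independent transcription of the isomer-group transformed potential.

    ``species`` is a list of (dfG0_kJ, z, nH). Returns the group potential
    in kJ/mol, using the standard extended Debye-Hueckel coefficient
    evaluated via its own temperature polynomial.
    """
    with mpmath.workdps(40):
        T = mpmath.mpf(repr(T))
        RT = mpmath.mpf("0.00831446") * T
        alpha = (
            mpmath.mpf("1.10708")
            - mpmath.mpf("1.54508e-3") * T
            + mpmath.mpf("5.95584e-6") * T**2
        )
        sqrt_i = mpmath.sqrt(mpmath.mpf(repr(ionic_strength)))
        f = sqrt_i / (1 + mpmath.mpf("1.6") * sqrt_i)
        terms = []
        for dfG0, z, nH in species:
            mu = (
                mpmath.mpf(repr(dfG0))
                - RT * alpha * (z * z - nH) * f
                + nH * RT * mpmath.log(10) * mpmath.mpf(repr(pH))
                + RT * mpmath.log(mpmath.mpf(repr(conc)))
            )
            terms.append(mpmath.e ** (-mu / RT))
        return float(-RT * mpmath.log(sum(terms)))
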