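"""Synthetic test worlds: toy networks, mode thermodynamics and strains.

The toy networks have analytically known elementary-mode sets:

* ``chain``     — linear glucose→pyruvate path, exactly 1 mode;
* ``diamond``   — two parallel branches, exactly 2 modes;
* ``branched8`` — 8 reactions with 2 branch points, exactly 4 modes;
* ``cycle``     — a path plus a futile loop, 3 modes of which 1 carries no
  glucose.

Synthetic mode thermodynamics emulate the qualitative structure of aerobic
glucose metabolism: every mode has positive reaction entropy and negative
Gibbs energy, and (in the default ``correlated`` enthalpy model) reaction
enthalpy is strongly correlated with Gibbs energy (exothermic modes). They
make no attempt to mimic actual E. coli magnitudes beyond order of
magnitude: Δs_j is drawn uniformly from 200–1500 J/(K·mol glucose), which at
ξ̂ ≈ 0.012 mol/(h·gCDW) and b ≈ 0.4 puts the Boltzmann exponents in the
experimentally relevant range.

Synthetic strains invert the fitting problem: given a ground-truth
``b_true``, the generator computes the exact Boltzmann probabilities, the
implied overall reaction entropy and growth observables, optionally
perturbed by multiplicative Gaussian noise — so parameter recovery can be
tested against known truth. A single seeded generator threads through every
draw; identical seeds give identical worlds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import fluxes
from .efm import ElementaryModeSet, enumerate_modes, normalize_to_glucose
from .maxent import StrainObservation, boltzmann_probabilities
from .network import ReactionNetwork, parse_reaction_list, serialize_reaction_list
from .thermo import ModeThermo, mode_thermo_frame

#: Documented exact elementary-mode counts per toy network
#: (total, of which non-glucose).
TOY_EM_COUNTS = {
    "chain": (1, 0),
    "diamond": (2, 0),
    "branched8": (4, 0),
    "cycle": (3, 1),
}

_TOY_DEFS = {
    "chain": """
        v1: glc.Ext => glc
        v2: glc => pyr
        v3: pyr => pyr.Ext
    """,
    "diamond": """
        v1: s.Ext => s
        v2: s => a
        v3: a => p
        v4: s => b
        v5: b => p
        v6: p => p.Ext
    """,
    "branched8": """
        v1: s.Ext => s
        v2: s => a
        v3: s => b
        v4: a => c
        v5: b => c
        v6: c => p
        v7: p => p.Ext
        v8: c => q.Ext
    """,
    "cycle": """
        v1: glc.Ext => glc
        v2: glc => x
        v3: x => p
        v4: y => p
        v5: p => p.Ext
        v6: x => y
        v7: y => x
    """,
}

#: Glucose-role metabolite per toy network (the normalized −1 substrate).
TOY_GLUCOSE = {
    "chain": "glc.Ext",
    "diamond": "s.Ext",
    "branched8": "s.Ext",
    "cycle": "glc.Ext",
}


def toy_network(name: str) -> ReactionNetwork:
    """Build one of the documented toy networks by name."""
    try:
        text = _TOY_DEFS[name]
    except KeyError:
        raise ValueError(
            f"unknown toy network {name!r}; choose from {sorted(_TOY_DEFS)}"
        ) from None
    return parse_reaction_list(text)


def toy_modes(name: str) -> ElementaryModeSet:
    """Enumerated, glucose-normalized mode set of a toy network."""
    return normalize_to_glucose(
        enumerate_modes(toy_network(name)), TOY_GLUCOSE[name]
    )


# ---------------------------------------------------------------------------
# synthetic thermodynamics and strains
# ---------------------------------------------------------------------------


def synthetic_thermo(
    n_modes: int,
    *,
    ds_range: tuple[float, float] = (200.0, 1500.0),
    dh_model: str = "correlated",
    dh_scale: float = 2.0,
    noise_sd: float = 0.05,
    T: float = 310.15,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[ModeThermo]:
    """Sample per-mode reaction properties with the stated structure.

    Δs_j ~ U(ds_range) [J/(K·mol glucose)]; the enthalpy model is either
    ``"zero"`` (Δh_j = 0, making A_j/T = Δs_j exactly) or ``"correlated"``
    (Δh_j = −dh_scale·T·Δs_j·(1 + ε), ε ~ N(0, noise_sd)); Δg_j follows from
    the Gibbs relation and is negative by construction for dh_scale ≥ 0.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = ds_range
    if not 0 < lo < hi:
        raise ValueError("ds_range must be positive and increasing")
    ds = rng.uniform(lo, hi, size=n_modes)
    if dh_model == "zero":
        dh = np.zeros(n_modes)
    elif dh_model == "correlated":
        dh = -dh_scale * T * ds * (1.0 + noise_sd * rng.standard_normal(n_modes))
        dh = np.minimum(dh, 0.0)  # keep every mode exothermic
    else:
        raise ValueError(f"unknown dh_model {dh_model!r}")
    dg = dh - T * ds
    return [ModeThermo(ds=s, dh=h, dg=g) for s, h, g in zip(ds, dh, dg)]


@dataclass
class SyntheticStrain:
    """A strain generated from known ground truth."""

    b_true: float
    xi_hat: float  # mol/(h·gCDW)
    noise_sd: float
    seed: int | None
    observation: StrainObservation
    ds_observed: float  # the (possibly noisy) overall reaction entropy
    p_true: np.ndarray


def synthetic_strain(
    mode_thermos: list[ModeThermo],
    b_true: float,
    *,
    xi_hat: float = 0.012,
    yield_bg: float = 0.42,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    modes: ElementaryModeSet | None = None,
    name: str = "synthetic",
) -> SyntheticStrain:
    """Generate a strain observation from a known Boltzmann distribution.

    The exact probabilities at ``b_true`` give the noiseless overall
    reaction entropy Σ p*_j·Δs_j; multiplicative Gaussian noise (sd
    ``noise_sd``) on the per-mode external contributions perturbs it. μ
    follows from the yield and ξ̂ (μ = Y·ξ̂ with Y converted to g/mol via
    the 180.16 g/mol glucose mass). If ``modes`` is supplied, the overall
    external stoichiometry is also synthesized via the mixing rule.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ds = np.array([mt.ds for mt in mode_thermos])
    p_star, _, _ = boltzmann_probabilities(ds, xi_hat, b_true)
    contrib = ds.copy()
    if noise_sd > 0:
        contrib = ds * (1.0 + noise_sd * rng.standard_normal(ds.size))
    ds_obs = float(p_star @ contrib)

    external: dict[str, float] = {}
    if modes is not None:
        external = fluxes.overall_stoichiometry(p_star, modes)

    mu = yield_bg * 180.16 * xi_hat  # g/g * g glc/mol * mol/(h·g) = 1/h
    obs = StrainObservation(
        name=name,
        mu=mu,
        qs=xi_hat * 1000.0,
        yield_bg=yield_bg,
        external_stoich=external,
    )
    return SyntheticStrain(
        b_true=b_true,
        xi_hat=xi_hat,
        noise_sd=noise_sd,
        seed=seed,
        observation=obs,
        ds_observed=ds_obs,
        p_true=p_star,
    )


def write_fixture_bundle(
    out_dir, name: str = "diamond", *, seed: int = 0, n_modes: int | None = None
) -> dict[str, Path]:
    """Write network, modes, mode-thermo and strain files for a toy world.

    Produces the package's standard TSV formats under ``out_dir`` and
    returns the paths. Deterministic for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = toy_network(name)
    modes = toy_modes(name)
    thermos = synthetic_thermo(len(modes), seed=seed)
    strain = synthetic_strain(thermos, 0.4, seed=seed, modes=modes)

    paths = {
        "network": out / f"{name}.reactions.txt",
        "modes": out / f"{name}.modes.tsv",
        "thermo": out / f"{name}.mode_thermo.tsv",
        "strain": out / f"{name}.strain.tsv",
    }
    paths["network"].write_text(serialize_reaction_list(net))
    modes.to_tsv(paths["modes"])
    mode_thermo_frame(thermos).to_csv(paths["thermo"], sep="\t", index=False)
    obs = strain.observation
    with open(paths["strain"], "w") as fh:
        fh.write("name\tmu_per_h\tqs_mmol_per_h_gCDW\tyield_g_per_g\tds_observed_J_per_K_mol\n")
        fh.write(
            f"{obs.name}\t{obs.mu:.6f}\t{obs.qs:.6f}\t{obs.yield_bg:.6f}\t"
            f"{strain.ds_observed:.6f}\n"
        )
    return paths
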