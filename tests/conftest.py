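import numpy as np
import pytest

from maxentflux import fixtures
from maxentflux.network import Metabolite, Reaction, ReactionNetwork
from fractions import Fraction


@pytest.fixture(params=["chain", "diamond", "branched8", "cycle"])
def toy_name(request):
    return request.param


@pytest.fixture
def diamond():
    return fixtures.toy_network("diamond")


@pytest.fixture
def diamond_modes():
    return fixtures.toy_modes("diamond")


def random_network(rng: np.random.Generator, n_reactions=6, n_internal=3):
    """Small random network for oracle cross-checks (≤8 reactions)."""
    mets = [Metabolite(id=f"m{i}") for i in range(n_internal)]
    mets += [Metabolite(id="xin", external=True), Metabolite(id="xout", external=True)]
    reactions = []
    for k in range(n_reactions):
        stoich = {}
        for i in range(n_internal):
            c = int(rng.integers(-2, 3))
            if c:
                stoich[f"m{i}"] = Fraction(c)
        if not stoich:
            stoich[f"m{int(rng.integers(n_internal))}"] = Fraction(1)
        # couple some reactions to the boundary
        if k == 0:
            stoich["xin"] = Fraction(-1)
        elif k == n_reactions - 1:
            stoich["xout"] = Fraction(1)
        reactions.append(
            Reaction(id=f"v{k + 1}", stoich=stoich, reversible=bool(rng.random() < 0.3))
        )
    return ReactionNetwork(mets, reactions)
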