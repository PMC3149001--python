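"""Shared fixtures: toy networks with closed-form behavior and cached
pathway-model time courses (model building pre-equilibrates the resting
cell, so session-scoped caching keeps the suite fast)."""

import numpy as np
import pytest

from mlcpath.experiments import make_fixture
from mlcpath.pathway import StimulusConfig, build_model
from mlcpath.simulate import run


@pytest.fixture
def decay_net():
    return make_fixture("decay", {"k": 0.01, "a0": 1.0})


@pytest.fixture
def binding_net():
    return make_fixture("binding", {"kf": 1.0, "kb": 0.1, "a0": 1.0,
                                    "b0": 0.8})


@pytest.fixture
def mm_net():
    # Km = (k1r + k2) / k1 = 0.011 uM >> [S] not required here; the QSSA
    # test configures its own regime
    return make_fixture("mm_cycle", {"k1": 10.0, "k1r": 1.0, "k2": 0.1,
                                     "e0": 0.05, "s0": 1.0})


@pytest.fixture(scope="session")
def thrombin_net():
    return build_model(StimulusConfig(thrombin=0.05))


@pytest.fixture(scope="session")
def thrombin_tc(thrombin_net):
    """Thrombin 0.05 uM, 100 min, default (Dormand-Prince) solver."""
    return run(thrombin_net, 6000.0)


@pytest.fixture(scope="session")
def vegf_tc():
    net = build_model(StimulusConfig(vegf=0.02))
    return run(net, 3600.0)


@pytest.fixture(scope="session")
def histamine_tc():
    net = build_model(StimulusConfig(histamine=0.005))
    return run(net, 4800.0)


def random_mass_action_network(rng, n_species=10, n_reactions=20):
    """Random small mass-action network for structural oracles."""
    from mlcpath.network import (
        MASS_ACTION_IRREVERSIBLE,
        MASS_ACTION_REVERSIBLE,
        RateLaw,
        Reaction,
        ReactionNetwork,
        Species,
    )

    species = [
        Species(f"S{i}", initial_concentration=float(rng.uniform(0.1, 2.0)))
        for i in range(n_species)
    ]
    reactions = []
    for j in range(n_reactions):
        ids = rng.choice(n_species, size=rng.integers(1, 4), replace=False)
        k = rng.integers(1, len(ids) + 1)
        reactants = [(f"S{i}", int(rng.integers(1, 3))) for i in ids[:k]]
        products = [(f"S{i}", int(rng.integers(1, 3))) for i in ids[k:]]
        reversible = bool(rng.random() < 0.5) and products
        rl = RateLaw(
            form=(MASS_ACTION_REVERSIBLE if reversible
                  else MASS_ACTION_IRREVERSIBLE),
            kf=float(rng.uniform(0.01, 1.0)),
            kb=float(rng.uniform(0.01, 1.0)) if reversible else 0.0,
        )
        reactions.append(
            Reaction(f"R{j}", reactants, list(products), rate_law=rl)
        )
    return ReactionNetwork(species, reactions)
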