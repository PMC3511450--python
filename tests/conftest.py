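import numpy as np
import pytest

import cflfit as cf
from cflfit.network_model import Pathway, Reaction, Species


@pytest.fixture(scope="session")
def toy_truth() -> cf.GroundTruth:
    return cf.make_toy_ground_truth()


@pytest.fixture(scope="session")
def toy_pathway(toy_truth) -> cf.Pathway:
    return toy_truth.pathway


@pytest.fixture(scope="session")
def toy_design(toy_truth) -> cf.ExperimentDesign:
    return toy_truth.design


@pytest.fixture()
def toy_config() -> cf.FitConfig:
    return cf.FitConfig.toy()


@pytest.fixture()
def diamond_fixture():
    """Single stimulus feeding two mutually-activating latent nodes and one
    readout: the latent pair responds identically under every condition."""
    species = [Species("A", "stimulus"), Species("B1"), Species("B2"),
               Species("OUT", "measured")]
    reactions = [
        Reaction(0, frozenset(["A"]), frozenset(), frozenset(["B1"])),
        Reaction(1, frozenset(["A"]), frozenset(), frozenset(["B2"])),
        Reaction(2, frozenset(["B1"]), frozenset(), frozenset(["B2"])),
        Reaction(3, frozenset(["B2"]), frozenset(), frozenset(["B1"])),
        Reaction(4, frozenset(["B1"]), frozenset(), frozenset(["OUT"])),
    ]
    pathway = Pathway(species, reactions)
    design = cf.ExperimentDesign.from_treatments(
        [(set(), set()), ({"A"}, set())]
    )
    return pathway, design


@pytest.fixture()
def crossing_fixture():
    """Two stimuli crossing through two latent nodes to two readouts, with
    data distinguishing the latents — compartmentalization over-groups it."""
    species = [Species("A1", "stimulus"), Species("A2", "stimulus"),
               Species("B1"), Species("B2"),
               Species("OUT1", "measured"), Species("OUT2", "measured")]
    reactions = [
        Reaction(0, frozenset(["A1"]), frozenset(), frozenset(["B1"])),
        Reaction(1, frozenset(["A1"]), frozenset(), frozenset(["B2"])),
        Reaction(2, frozenset(["A2"]), frozenset(), frozenset(["B1"])),
        Reaction(3, frozenset(["A2"]), frozenset(), frozenset(["B2"])),
        Reaction(4, frozenset(["B1"]), frozenset(), frozenset(["OUT1"])),
        Reaction(5, frozenset(["B2"]), frozenset(), frozenset(["OUT2"])),
    ]
    pathway = Pathway(species, reactions)
    design = cf.ExperimentDesign.from_treatments(
        [({"A1"}, set()), ({"A2"}, set())]
    )
    # OUT1 responds only to A1 and OUT2 only to A2
    measurements = cf.MeasurementSet(
        ["OUT1", "OUT2"], np.array([[1.0, 0.0], [0.0, 1.0]])
    )
    return pathway, design, measurements


def boolean_fixed_point(pathway, active_clamps):
    """Independent Boolean oracle: iterate AND/OR/NOT truth propagation.

    Treatment species are clamped (True when in ``active_clamps``); every
    other species starts False and is updated synchronously until stable.
    """
    roles = pathway.roles()
    clamped = {s.name for s in pathway.species
               if roles[s.name] in ("stimulus", "inhibitor-node")}
    clamped |= set(active_clamps)
    state = {s.name: (s.name in active_clamps) if s.name in clamped else False
             for s in pathway.species}
    for _ in range(len(pathway.species) + 1):
        new = dict(state)
        for s in pathway.species:
            if s.name in clamped:
                continue
            outputs = [
                all(state[x] for x in r.reactants)
                and not any(state[x] for x in r.inhibitors)
                for r in pathway.reactions if s.name in r.products
            ]
            new[s.name] = any(outputs)
        if new == state:
            return state
        state = new
    return state
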