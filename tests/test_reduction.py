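import numpy as np
import pytest

import cflfit as cf
from cflfit.fit import FitConfig, multistart
from cflfit.midas_io import ExperimentDesign, MeasurementSet
from cflfit.network_model import Pathway, Reaction, Species
from cflfit.reduction import (
    compartmentalization_report,
    compartmentalize,
    map_back,
    null_mae,
    prune,
)
from cflfit.simulation import simulate
from cflfit.synthetic import all_binary_design, random_pathway


def test_compartmentalize_groups_equivalent_latents(diamond_fixture):
    pathway, design = diamond_fixture
    reduced, cmap = compartmentalize(pathway, design)
    # B1 and B2 respond identically under both conditions: one compartment
    assert len(cmap.compartments) == 1
    (members,) = cmap.compartments.values()
    assert members == ["B1", "B2"]
    assert set(cmap.ungrouped) == {"A", "OUT"}
    # surviving reactions: A -> C, C -> OUT; the B1 <-> B2 pair collapses
    assert reduced.n_reactions == 2
    assert reduced.n_species == 3


def test_compartmentalize_reaction_image(diamond_fixture):
    pathway, design = diamond_fixture
    _, cmap = compartmentalize(pathway, design)
    # reactions 2 and 3 (B1 <-> B2) fall inside the compartment
    assert cmap.reaction_image[2] is None
    assert cmap.reaction_image[3] is None
    # reactions 0 and 1 become the same rewritten reaction; survivor id 0
    assert cmap.reaction_image[0] == 0
    assert cmap.reaction_image[1] == 0
    assert cmap.reaction_image[4] == 4


def test_compartmentalize_keeps_distinct_latents():
    pathway = Pathway(
        [Species("A", "stimulus"), Species("B", "stimulus"),
         Species("X"), Species("Y"), Species("OUT", "measured")],
        [Reaction(0, frozenset(["A"]), frozenset(), frozenset(["X"])),
         Reaction(1, frozenset(["B"]), frozenset(), frozenset(["Y"])),
         Reaction(2, frozenset(["X"]), frozenset(), frozenset(["OUT"])),
         Reaction(3, frozenset(["Y"]), frozenset(), frozenset(["OUT"]))],
    )
    design = ExperimentDesign.from_treatments([({"A"}, set()), ({"B"}, set())])
    reduced, cmap = compartmentalize(pathway, design)
    # X and Y respond differently: two singleton compartments, nothing merges
    assert len(cmap.compartments) == 2
    assert reduced.n_reactions == 4


def test_compartmentalize_excludes_measured_and_treatments(toy_truth):
    reduced, cmap = compartmentalize(toy_truth.pathway, toy_truth.design)
    grouped = set(cmap.mapping)
    assert grouped == {"PI3K"}  # the only eligible latent species
    assert set(cmap.ungrouped) >= set(cf.TOY_SIGNALS)
    assert set(cmap.ungrouped) >= set(cf.TOY_STIMULI) | set(cf.TOY_INHIBITORS)
    assert reduced.n_reactions == toy_truth.pathway.n_reactions


def test_compartment_names_avoid_collision(diamond_fixture):
    pathway, design = diamond_fixture
    renamed = Pathway(
        [Species("C1", s.role) if s.name == "B1" else s for s in pathway.species],
        [Reaction(r.id,
                  frozenset("C1" if n == "B1" else n for n in r.reactants),
                  frozenset("C1" if n == "B1" else n for n in r.inhibitors),
                  frozenset("C1" if n == "B1" else n for n in r.products))
         for r in pathway.reactions],
    )
    reduced, cmap = compartmentalize(renamed, design)
    (name,) = cmap.compartments
    assert name != "C1"  # must not collide with the existing species


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_compartmentalization_preserves_measured_predictions(seed):
    """Nominal simulation of the reduced network matches the original at
    every measured species and condition."""
    pathway = random_pathway(14, 20, seed=seed, n_stimuli=3)
    design = all_binary_design(
        [s.name for s in pathway.species if s.role == "stimulus"]
    )
    reduced, _ = compartmentalize(pathway, design)
    measured = [s.name for s in pathway.species if s.role == "measured"]
    before = simulate(pathway, None, design).x_for(measured)
    after = simulate(reduced, None, design).x_for(measured)
    np.testing.assert_allclose(after, before, atol=1e-9)


def test_compartmentalization_report_counts(diamond_fixture):
    pathway, design = diamond_fixture
    reduced, cmap = compartmentalize(pathway, design)
    report = compartmentalization_report(pathway, reduced, cmap)
    assert report["species_before"] == 4 and report["species_after"] == 3
    assert report["reactions_before"] == 5 and report["reactions_after"] == 2
    assert report["parameters_before"] == 10 and report["parameters_after"] == 4
    assert report["n_not_interrogated"] == 2
    assert report["warning"] is None


def test_compartmentalization_over_aggressive_warning(crossing_fixture):
    pathway, design, measurements = crossing_fixture
    reduced, cmap = compartmentalize(pathway, design)
    # B1 and B2 merge (identical nominal responses) even though the data
    # distinguish them: the reduced model cannot fit better than 0.25
    fam = multistart(reduced, design, measurements, FitConfig.toy(),
                     n_runs=3, seed=0)
    report = compartmentalization_report(pathway, reduced, cmap,
                                         fitted_mae=fam.best.mae)
    assert fam.best.mae >= 0.2
    assert report["warning"] is not None
    # the unreduced network can fit the data essentially exactly
    full = multistart(pathway, design, measurements, FitConfig.toy(),
                      n_runs=3, seed=0)
    assert full.best.mae < 0.01


def test_map_back_flags_not_interrogated(diamond_fixture, ):
    pathway, design = diamond_fixture
    reduced, cmap = compartmentalize(pathway, design)
    measurements = MeasurementSet(["OUT"], np.array([[0.0], [0.9]]))
    sol = multistart(reduced, design, measurements, FitConfig.toy(),
                     n_runs=2, seed=0).best
    frame = map_back(sol, cmap, pathway)
    assert len(frame) == pathway.n_reactions
    by_id = frame.set_index("reaction")
    assert not by_id.loc[2, "interrogated"]
    assert not by_id.loc[3, "interrogated"]
    assert np.isnan(by_id.loc[2, "max_activity"])
    # merged originals 0 and 1 both inherit the surviving reaction's activity
    assert by_id.loc[0, "max_activity"] == by_id.loc[1, "max_activity"]
    assert by_id.loc[0, "interrogated"] and by_id.loc[4, "interrogated"]


def test_map_back_rejects_foreign_pathway(diamond_fixture, toy_truth, toy_config):
    pathway, design = diamond_fixture
    reduced, cmap = compartmentalize(pathway, design)
    measurements = MeasurementSet(["OUT"], np.array([[0.0], [0.9]]))
    sol = multistart(reduced, design, measurements, toy_config,
                     n_runs=1, seed=0).best
    with pytest.raises(KeyError):
        map_back(sol, cmap, toy_truth.pathway)


def test_null_mae_toy(toy_truth):
    # mean |x_hat| over the 45 cells: 14 cells at 1.0 -> 14/45
    assert null_mae(toy_truth.measurements) == pytest.approx(14 / 45)


def test_prune_recovers_toy_truth(toy_truth, toy_config):
    reduced, trace = prune(toy_truth.pathway, toy_truth.design,
                           toy_truth.measurements, toy_config, seed=0)
    accepted = trace.removed_ids()[:-1] if not trace.exhausted else \
        trace.removed_ids()
    assert set(accepted) == set(toy_truth.inactive_reactions)
    assert reduced.n_reactions == 7
    assert trace.baseline_mae < 1e-6
    # every accepted removal kept the fit within tolerance of baseline
    for _, _, mae_after in trace.steps[:len(accepted)]:
        assert mae_after <= trace.baseline_mae + 0.01
    # the stopping step degraded the fit
    assert not trace.exhausted
    assert trace.steps[-1][2] > trace.baseline_mae + 0.01


def test_prune_removes_lowest_activity_first(toy_truth, toy_config):
    _, trace = prune(toy_truth.pathway, toy_truth.design,
                     toy_truth.measurements, toy_config, seed=0)
    # removed reactions carried (near-)zero activity when removed
    for rid, activity, _ in trace.steps[:-1]:
        assert activity <= 0.05


def test_prune_exhaustion():
    """With an infinite tolerance pruning strips the whole network."""
    pathway = Pathway(
        [Species("A", "stimulus"), Species("B", "measured")],
        [Reaction(0, frozenset(["A"]), frozenset(), frozenset(["B"]))],
    )
    design = ExperimentDesign.from_treatments([({"A"}, set())])
    measurements = MeasurementSet(["B"], np.array([[0.8]]))
    reduced, trace = prune(pathway, design, measurements, FitConfig.toy(),
                           mae_tolerance=np.inf, n_restarts=1)
    assert trace.exhausted
    assert reduced.n_reactions == 0
    assert trace.steps[-1][2] == pytest.approx(null_mae(measurements))


def test_prune_drops_redundant_duplicate_route():
    """Two parallel routes carrying the same signal: one is dispensable."""
    pathway = Pathway(
        [Species("A", "stimulus"), Species("X"), Species("Y"),
         Species("OUT", "measured")],
        [Reaction(0, frozenset(["A"]), frozenset(), frozenset(["X"])),
         Reaction(1, frozenset(["A"]), frozenset(), frozenset(["Y"])),
         Reaction(2, frozenset(["X"]), frozenset(), frozenset(["OUT"])),
         Reaction(3, frozenset(["Y"]), frozenset(), frozenset(["OUT"]))],
    )
    design = ExperimentDesign.from_treatments([(set(), set()), ({"A"}, set())])
    measurements = MeasurementSet(["OUT"], np.array([[0.0], [1.0]]))
    reduced, trace = prune(pathway, design, measurements, FitConfig.toy(),
                           n_restarts=2, seed=0)
    # a single A -> ... -> OUT route suffices to hit the data
    assert reduced.n_reactions == 2
    assert not trace.exhausted


def test_prune_trace_frame(toy_truth, toy_config):
    _, trace = prune(toy_truth.pathway, toy_truth.design,
                     toy_truth.measurements, toy_config, seed=0)
    frame = trace.to_frame()
    assert list(frame.columns) == ["step", "reaction", "max_activity", "mae"]
    assert len(frame) == len(trace.steps)
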