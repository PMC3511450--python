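"""Network reduction: equivalent-class compartmentalization and pruning.

Two complementary routes tackle over-parameterization when the data cannot
constrain every reaction of the prior knowledge network:

* ``compartmentalize`` simulates the network with nominal parameters under
  every experimental condition and groups non-measured, non-treatment
  species whose simulated responses are identical across all conditions
  (equivalent classes): the data cannot distinguish such species, so each
  group is replaced by a single compartment node and duplicate reactions
  are merged. Grouping can be over-aggressive when conditions are few;
  ``compartmentalization_report`` flags a suspiciously high post-fit error.

* ``prune`` iteratively removes the reaction with the lowest maximum
  activity, refitting after each removal, until the fit error rises above
  the baseline by more than a tolerance — at that point only reactions
  vital to fitting the data remain.

``map_back`` projects a solution obtained on the compartmentalized network
back onto the original one; reactions internal to a compartment were never
interrogated by the optimization and are flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network_model import Pathway, Reaction, Species, TransferParams
from .midas_io import ExperimentDesign, MeasurementSet
from .simulation import SimulationSettings, simulate
from .fit import FitConfig, Solution, multistart

__all__ = [
    "CompartmentMap",
    "PruneTrace",
    "compartmentalize",
    "prune",
    "map_back",
    "compartmentalization_report",
    "null_mae",
]

RESPONSE_TOL = 1e-9  # nominal simulation is deterministic; equality is exact


@dataclass
class CompartmentMap:
    """Species -> compartment assignment produced by compartmentalization."""

    compartments: dict[str, list[str]]  # compartment name -> member species
    mapping: dict[str, str]  # species -> compartment (grouped species only)
    ungrouped: list[str]  # measured / stimulus / inhibitor-node species
    reaction_image: dict[int, int | None] = field(default_factory=dict)
    # original reaction id -> surviving reduced reaction id, or None when the
    # reaction fell entirely inside one compartment (not interrogated)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"species": s, "compartment": c} for s, c in self.mapping.items()]
        rows += [{"species": s, "compartment": ""} for s in self.ungrouped]
        return pd.DataFrame(rows)


@dataclass
class PruneTrace:
    """Removal history: (reaction id, its max activity, MAE after refit)."""

    baseline_mae: float
    steps: list[tuple[int, float, float]] = field(default_factory=list)
    exhausted: bool = False

    def removed_ids(self) -> list[int]:
        return [rid for rid, _, _ in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"step": i + 1, "reaction": rid, "max_activity": act, "mae": m}
             for i, (rid, act, m) in enumerate(self.steps)]
        )


# ---------------------------------------------------------------------------
# Compartmentalization


def compartmentalize(
    pathway: Pathway,
    design: ExperimentDesign,
    settings: SimulationSettings | None = None,
):
    """Group equivalently-responding latent species into compartments.

    The pathway is simulated with nominal parameters (a = 1.0, p = 0.5,
    n = 4) under every experiment; eligible species (neither measured nor
    clamped as a treatment) whose response rows agree within ``RESPONSE_TOL``
    are merged into one compartment node, and reactions rewritten over
    compartments are deduplicated (the survivor keeps the smallest original
    id). Every eligible species lands in a compartment, singletons included.
    """
    settings = settings or SimulationSettings()
    if design.n_experiments == 0:
        raise ValueError("design must contain at least one experiment")
    prediction = simulate(pathway, None, design, settings)

    roles = pathway.roles()
    treatments = design.treatment_species
    eligible = [
        s.name for s in pathway.species
        if roles[s.name] == "latent" and s.name not in treatments
    ]

    groups: dict[tuple, list[str]] = {}
    for name in eligible:
        row = prediction.x_for([name])[:, 0]
        key = tuple(np.round(row / RESPONSE_TOL).astype(np.int64))
        groups.setdefault(key, []).append(name)

    # name compartments in order of first-member appearance, skipping any
    # C<N> token already used as a species name
    order = {name: i for i, name in enumerate(pathway.species_names())}
    members_list = sorted(groups.values(), key=lambda ms: min(order[m] for m in ms))
    taken = set(order)
    compartments = {}
    counter = 1
    for ms in members_list:
        while f"C{counter}" in taken:
            counter += 1
        compartments[f"C{counter}"] = sorted(ms, key=order.get)
        counter += 1
    mapping = {m: c for c, ms in compartments.items() for m in ms}
    ungrouped = [s.name for s in pathway.species if s.name not in mapping]

    new_species = [Species(s.name, s.role) for s in pathway.species
                   if s.name not in mapping]
    new_species += [Species(c, "latent") for c in compartments]

    def _img(name: str) -> str:
        return mapping.get(name, name)

    kept: dict[tuple, Reaction] = {}
    reaction_image: dict[int, int | None] = {}
    for r in sorted(pathway.reactions, key=lambda r: r.id):
        reactants = frozenset(_img(n) for n in r.reactants)
        inhibitors = frozenset(_img(n) for n in r.inhibitors)
        products = frozenset(_img(n) for n in r.products)
        inputs = reactants | inhibitors
        if products <= inputs or (reactants & inhibitors):
            # self-loop after rewriting: the reaction lies inside a
            # compartment and cannot be interrogated
            reaction_image[r.id] = None
            continue
        key = (reactants, inhibitors, products)
        if key not in kept:
            kept[key] = Reaction(r.id, reactants, inhibitors, products)
        reaction_image[r.id] = kept[key].id

    reduced = Pathway(new_species, sorted(kept.values(), key=lambda r: r.id))
    cmap = CompartmentMap(compartments, mapping, ungrouped, reaction_image)
    return reduced, cmap


def compartmentalization_report(
    original: Pathway,
    reduced: Pathway,
    cmap: CompartmentMap,
    fitted_mae: float | None = None,
    mae_threshold: float = 0.1,
) -> dict:
    """Before/after size accounting plus an over-aggressiveness warning.

    A post-fit MAE above ``mae_threshold`` suggests the grouping merged
    species the data could actually distinguish; the solution should then
    be compared against an unreduced fit.
    """
    sizes = {c: len(ms) for c, ms in cmap.compartments.items()}
    report = {
        "species_before": original.n_species,
        "species_after": reduced.n_species,
        "reactions_before": original.n_reactions,
        "reactions_after": reduced.n_reactions,
        "parameters_before": 2 * original.n_reactions,
        "parameters_after": 2 * reduced.n_reactions,
        "compartment_sizes": sizes,
        "n_not_interrogated": sum(
            1 for v in cmap.reaction_image.values() if v is None
        ),
        "fitted_mae": fitted_mae,
        "warning": None,
    }
    if fitted_mae is not None and fitted_mae > mae_threshold:
        report["warning"] = (
            f"post-fit MAE {fitted_mae:.3f} exceeds {mae_threshold}: the "
            "compartmentalization may be over-aggressive; compare against "
            "an unreduced fit"
        )
    return report


def map_back(
    solution_on_reduced: Solution,
    cmap: CompartmentMap,
    original: Pathway,
) -> pd.DataFrame:
    """Project a compartment-level solution onto the original network.

    Every original reaction crossing a compartment boundary inherits the
    fitted maximum activity of its compartment-level image; reactions that
    stayed inside one compartment are flagged not interrogated.
    """
    known = set(cmap.mapping) | set(cmap.ungrouped)
    missing = set(original.species_names()) - known
    if missing:
        raise KeyError(f"species missing from compartment map: {sorted(missing)}")
    activity = dict(zip(solution_on_reduced.prediction.reaction_ids,
                        solution_on_reduced.max_activity))
    rows = []
    for r in sorted(original.reactions, key=lambda r: r.id):
        image = cmap.reaction_image.get(r.id)
        rows.append({
            "reaction": r.id,
            "reactants": "+".join(sorted(r.reactants)),
            "inhibitors": "+".join(sorted(r.inhibitors)),
            "products": "+".join(sorted(r.products)),
            "interrogated": image is not None,
            "max_activity": activity[image] if image is not None else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pruning


def null_mae(measurements: MeasurementSet) -> float:
    """MAE of the null solution (all gains zero: nothing propagates)."""
    return float(np.abs(measurements.values[measurements.mask]).mean())


def prune(
    pathway: Pathway,
    design: ExperimentDesign,
    measurements: MeasurementSet,
    config: FitConfig | None = None,
    mae_tolerance: float = 0.01,
    n_restarts: int = 5,
    seed: int = 0,
):
    """Iteratively remove the lowest-activity reaction until the fit degrades.

    Each iteration refits with a small multistart (guarding against a local
    minimum mimicking an MAE increase), removes the reaction with the
    smallest max_k z_i^k (ties: smallest id), and stops — restoring the
    last removal — once the refit MAE exceeds the baseline MAE by more than
    ``mae_tolerance``.
    """
    config = config or FitConfig()
    current = pathway
    best = multistart(pathway, design, measurements, config,
                      n_runs=n_restarts, seed=seed).best
    baseline_mae = best.mae
    trace = PruneTrace(baseline_mae=baseline_mae)

    step = 0
    while current.n_reactions > 0:
        step += 1
        ids = np.asarray(best.prediction.reaction_ids)
        acts = np.asarray(best.max_activity)
        pos = np.lexsort((ids, acts))[0]  # min activity, ties by smallest id
        rid, activity = int(ids[pos]), float(acts[pos])
        candidate = current.without_reactions({rid})

        if candidate.n_reactions == 0:
            new_mae = null_mae(measurements)
            new_best = None
        else:
            new_best = multistart(candidate, design, measurements, config,
                                  n_runs=n_restarts, seed=seed + step).best
            new_mae = new_best.mae

        trace.steps.append((rid, activity, new_mae))
        if new_mae > baseline_mae + mae_tolerance:
            return current, trace  # restore: keep the pathway before removal
        current = candidate
        if new_best is None:
            trace.exhausted = True
            return current, trace
        best = new_best
    trace.exhausted = True
    return current, trace
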