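"""Fixtures and synthetic-data generation.

Provides the ten-reaction toy signalling model (two stimuli, two explicit
inhibitor nodes, one latent kinase, five measured phosphoproteins), its
3 x 3 combinatorial treatment design, random acyclic logic networks for
property tests, and ground-truth dataset generation (noiseless simulation
plus optional truncated-Gaussian noise) for parameter-recovery and
network-reduction studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .network_model import Pathway, Reaction, Species, TransferParams, read_sif
from .midas_io import Experiment, ExperimentDesign, MeasurementSet
from .simulation import SimulationSettings, simulate

__all__ = [
    "GroundTruth",
    "TOY_STIMULI",
    "TOY_INHIBITORS",
    "TOY_SIGNALS",
    "build_toy_model",
    "build_toy_design",
    "toy_inactive_reaction_ids",
    "make_toy_ground_truth",
    "generate_dataset",
    "random_pathway",
    "all_binary_design",
]

TOY_STIMULI = ("TGFa", "TNFa")
TOY_INHIBITORS = ("MEK12i", "PI3Ki")
TOY_SIGNALS = ("MEK12", "ERK12", "AKT", "JNK", "P38")

# reactions absent from the data-generating truth: PI3K AND NOT MEK12i ->
# MEK12, PI3K -> JNK and PI3K -> P38 (JNK/P38 respond to TNFa alone, and
# neither stimulus reaches MEK12 through PI3K)
_TOY_INACTIVE_KEYS = (
    (frozenset(["PI3K"]), frozenset(["MEK12i"]), frozenset(["MEK12"])),
    (frozenset(["PI3K"]), frozenset(), frozenset(["JNK"])),
    (frozenset(["PI3K"]), frozenset(), frozenset(["P38"])),
)


@dataclass
class GroundTruth:
    """A data-generating model: pathway, true parameters, design, data."""

    pathway: Pathway
    params: TransferParams
    design: ExperimentDesign
    measurements: MeasurementSet  # noiseless
    sigma: float = 0.0
    inactive_reactions: frozenset[int] = frozenset()


def build_toy_model() -> Pathway:
    """The fixed toy pathway, read from its versioned SIF fixture.

    Ten reactions over ten species; with the Hill coefficient fixed the
    model has 20 free parameters. Roles are pre-assigned from the toy
    design and signal list.
    """
    ref = resources.files("cflfit").joinpath("fixtures/toy_model.sif")
    with resources.as_file(ref) as path:
        pathway = read_sif(path)
    return pathway.assign_roles(
        stimuli=set(TOY_STIMULI),
        inhibitor_nodes=set(TOY_INHIBITORS),
        measured=set(TOY_SIGNALS),
    )


def build_toy_design() -> ExperimentDesign:
    """3 stimulus x 3 inhibitor combinatorial treatments (9 experiments).

    Stimulus conditions: no-treatment, TGFa, TNFa; inhibitor conditions:
    no-inhibitor, MEK12i, PI3Ki. With the five measured signals this gives
    45 measurement cells.
    """
    experiments = []
    for stim in (frozenset(), frozenset(["TGFa"]), frozenset(["TNFa"])):
        for inh in (frozenset(), frozenset(["MEK12i"]), frozenset(["PI3Ki"])):
            experiments.append(Experiment(stimuli=stim, inhibitors=inh))
    return ExperimentDesign(experiments)


def toy_inactive_reaction_ids(pathway: Pathway) -> frozenset[int]:
    """Ids (in the given pathway) of the three reactions the truth disables."""
    ids = set()
    for r in pathway.reactions:
        if r.key() in _TOY_INACTIVE_KEYS:
            ids.add(r.id)
    if len(ids) != 3:
        raise ValueError("pathway does not contain the three toy gate keys")
    return frozenset(ids)


def make_toy_ground_truth(sigma: float = 0.0, seed: int = 0) -> GroundTruth:
    """The toy study conditions: active reactions at a = 1, p = 0.5, n = 4,
    the three disabled reactions at a = 0."""
    pathway = build_toy_model()
    design = build_toy_design()
    inactive = toy_inactive_reaction_ids(pathway)
    params = TransferParams.nominal(pathway.n_reactions)
    order = sorted(r.id for r in pathway.reactions)
    for pos, rid in enumerate(order):
        if rid in inactive:
            params.a[pos] = 0.0
    noiseless = generate_dataset(params, pathway, design, sigma=0.0, seed=seed)
    return GroundTruth(pathway, params, design, noiseless, sigma, inactive)


def generate_dataset(
    ground_truth_params: TransferParams,
    pathway: Pathway,
    design: ExperimentDesign,
    sigma: float = 0.0,
    seed: int = 0,
    signals=None,
) -> MeasurementSet:
    """Simulate the model and emit measurements at the measured species.

    With sigma > 0, additive Gaussian noise (sd sigma) is applied and the
    result clipped back into [0, 1] (truncated-Gaussian noise keeps the
    activation domain intact).
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if signals is None:
        signals = [s.name for s in pathway.species if s.role == "measured"]
    if not signals:
        raise ValueError("no measured species: assign roles or pass signals")
    prediction = simulate(pathway, ground_truth_params, design,
                          SimulationSettings())
    values = prediction.x_for(signals)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        values = np.clip(values + rng.normal(0.0, sigma, values.shape), 0.0, 1.0)
    return MeasurementSet(list(signals), values)


def all_binary_design(stimuli, inhibitors=()) -> ExperimentDesign:
    """Every stimulus combination crossed with no-inhibitor and each
    single inhibitor."""
    stimuli = list(stimuli)
    inhibitor_conditions = [frozenset()] + [frozenset([i]) for i in inhibitors]
    experiments = []
    for bits in range(2 ** len(stimuli)):
        stim = frozenset(s for b, s in enumerate(stimuli) if bits >> b & 1)
        for inh in inhibitor_conditions:
            experiments.append(Experiment(stimuli=stim, inhibitors=inh))
    return ExperimentDesign(experiments)


def random_pathway(
    n_species: int,
    n_reactions: int,
    and_fraction: float = 0.25,
    not_fraction: float = 0.25,
    seed: int = 0,
    n_stimuli: int = 2,
    inject_cycle: bool = False,
) -> Pathway:
    """A random acyclic logic network with guaranteed reachability.

    Species are laid out in a topological order with the stimuli first;
    every non-stimulus species receives one activating backbone reaction
    from an earlier species, and the remaining reactions are random
    earlier-to-later gates, a fraction of which gain a second (AND) input
    and a fraction of which turn an input inhibitory. ``inject_cycle``
    adds a back-edge reaction (plus its forward complement when missing),
    guaranteeing a directed cycle between two latent species.
    """
    if not 0 <= and_fraction <= 1 or not 0 <= not_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if n_stimuli < 1 or n_stimuli >= n_species:
        raise ValueError("need at least one stimulus and one downstream species")
    n_latent = n_species - n_stimuli
    if n_reactions < n_latent:
        raise ValueError(
            f"need at least {n_latent} reactions to reach every species"
        )
    rng = np.random.default_rng(seed)
    names = [f"STIM{i + 1}" for i in range(n_stimuli)] + [
        f"N{i + 1}" for i in range(n_latent)
    ]

    reactions: list[Reaction] = []
    keys: set = set()
    rid = 0

    def _add(reactants, inhibitors, product) -> bool:
        nonlocal rid
        key = (frozenset(reactants), frozenset(inhibitors), frozenset([product]))
        if key in keys or not (key[0] | key[1]):
            return False
        keys.add(key)
        reactions.append(Reaction(rid, key[0], key[1], key[2]))
        rid += 1
        return True

    for j in range(n_stimuli, n_species):
        src = int(rng.integers(0, j))
        _add([names[src]], [], names[j])

    attempts = 0
    while rid < n_reactions:
        attempts += 1
        if attempts > 200 * n_reactions:
            raise RuntimeError("could not place the requested reaction count")
        dst = int(rng.integers(n_stimuli, n_species))
        src = int(rng.integers(0, dst))
        inputs = [src]
        if rng.random() < and_fraction and dst > 1:
            other = int(rng.integers(0, dst))
            if other != src:
                inputs.append(other)
        flags = [rng.random() < not_fraction for _ in inputs]
        if all(flags):  # keep at least one activating input per gate
            flags[0] = False
        reactants = [names[i] for i, f in zip(inputs, flags) if not f]
        inhibitors = [names[i] for i, f in zip(inputs, flags) if f]
        _add(reactants, inhibitors, dst := names[dst])

    if inject_cycle:
        hi = n_species - 1
        lo = n_stimuli
        if hi <= lo:
            raise ValueError("network too small to inject a cycle")
        # guarantee the cycle lo -> hi -> lo: the forward reaction may already
        # exist (the _add dedup makes it a no-op then), the back edge closes it
        _add([names[lo]], [], names[hi])
        _add([names[hi]], [], names[lo])

    pathway = Pathway([Species(n) for n in names], reactions)
    produced = set()
    for r in reactions:
        produced |= r.products
    measured = {n for n in names[n_stimuli:]
                if not any(n in r.inputs for r in reactions)} or {names[-1]}
    return pathway.assign_roles(
        stimuli=set(names[:n_stimuli]),
        measured=measured & produced or {names[-1]},
    )
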