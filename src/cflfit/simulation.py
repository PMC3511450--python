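"""Constrained-fuzzy-logic network simulation.

Signal propagates through a reaction via a normalized Hill transfer
function

    f(x) = a * H(x) / H(1),    H(x) = x^n / (p^n + x^n),

so that f(0) = 0 and f(1) = a: the gain ``a`` caps how much signal a
reaction transmits, ``p`` sets the midpoint and ``n`` the steepness. AND
gates take the bilinear product of their inputs, with inhibitory (NOT)
inputs entering as the complement (1 - x); this reproduces Boolean
AND/AND-NOT behaviour at {0, 1} while staying differentiable. When several
reactions produce the same species their activities are OR-combined by the
recursive probabilistic sum u_m = u_{m-1} + z_m - u_{m-1} * z_m.

The network operates at pseudo steady state: each experiment clamps the
applied stimuli and inhibitor nodes to 1 (absent treatments to 0) and the
remaining species are driven to the fixed point of the gate equations.
Acyclic networks are evaluated in one topological pass; cyclic networks by
synchronous fixed-point iteration from the all-zero state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_model import Pathway, StructureError, TransferParams
from .midas_io import ExperimentDesign, Prediction

__all__ = [
    "SimulationSettings",
    "DomainError",
    "ConvergenceError",
    "hill_transfer",
    "reaction_activity",
    "or_combine",
    "simulate",
    "CompiledPathway",
    "compile_pathway",
]


class DomainError(ValueError):
    """An activation value fell outside [0, 1]."""


class ConvergenceError(RuntimeError):
    """Fixed-point iteration did not converge (cyclic network)."""


@dataclass
class SimulationSettings:
    """Fixed-point iteration controls.

    ``nominal_params`` replaces whatever parameters are passed with the
    initial-guess values a = 1.0, p = 0.5, n = 4 (the parameter-free
    simulation used for network compression).
    """

    tolerance: float = 1e-9
    max_iterations: int = 100
    nominal_params: bool = False

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


# ---------------------------------------------------------------------------
# Elementary operations


def hill_transfer(x, a: float, p: float, n: int = 4):
    """Normalized Hill transfer function f(x) = a * H(x)/H(1) on [0, 1]."""
    x = np.asarray(x, dtype=float)
    if ((x < -1e-9) | (x > 1 + 1e-9)).any():
        raise DomainError("activation outside [0, 1]")
    x = np.clip(x, 0.0, 1.0)
    out = _hill(x, float(a), float(p), int(n))
    return float(out) if out.ndim == 0 else out


def _hill(u, a, p, n):
    pn = p ** n
    un = u ** n
    return a * un * (pn + 1.0) / (pn + un)


def reaction_activity(reactant_values, inhibitor_values, params) -> float:
    """Activity z of one gated reaction.

    The effective input is the bilinear product of reactant activations and
    inhibitor complements; the result is the transfer function applied to
    it. ``params`` is an (a, p, n) triple.
    """
    reactant_values = list(reactant_values)
    inhibitor_values = list(inhibitor_values)
    if not reactant_values and not inhibitor_values:
        raise StructureError("reaction has no inputs")
    a, p, n = params
    u = 1.0
    for v in reactant_values:
        u *= v
    for v in inhibitor_values:
        u *= 1.0 - v
    return hill_transfer(u, a, p, n)


def or_combine(activities) -> float:
    """OR-combination of reaction activities by the recursive probabilistic sum.

    An empty list yields 0: a species with no producing reaction and no
    clamp stays inactive.
    """
    u = 0.0
    first = True
    for z in activities:
        if first:
            u = float(z)
            first = False
        else:
            u = u + float(z) - u * float(z)
    return u


# ---------------------------------------------------------------------------
# Compiled network evaluation


class CompiledPathway:
    """Index arrays for fast repeated simulation of one (pathway, design) pair.

    Gate inputs are flattened to at most two per reaction (the cardinality
    invariant), stored as species indices with an inhibitor flag, so the
    per-iteration work is pure numpy over an (n_reactions, n_experiments)
    array.
    """

    def __init__(self, pathway: Pathway, clamped: set[str]):
        self.pathway = pathway
        self.species = pathway.species_names()
        self.index = {n: i for i, n in enumerate(self.species)}
        self.reactions = sorted(pathway.reactions, key=lambda r: r.id)
        self.reaction_ids = [r.id for r in self.reactions]
        n_r = len(self.reactions)

        self.in1 = np.zeros(n_r, dtype=int)
        self.inh1 = np.zeros(n_r, dtype=bool)
        self.in2 = np.full(n_r, -1, dtype=int)
        self.inh2 = np.zeros(n_r, dtype=bool)
        for pos, r in enumerate(self.reactions):
            inputs = [(self.index[s], False) for s in sorted(r.reactants)]
            inputs += [(self.index[s], True) for s in sorted(r.inhibitors)]
            self.in1[pos], self.inh1[pos] = inputs[0]
            if len(inputs) == 2:
                self.in2[pos], self.inh2[pos] = inputs[1]
        self.has2 = self.in2 >= 0

        self.clamped_idx = np.array(
            sorted(self.index[n] for n in clamped if n in self.index), dtype=int
        )
        is_clamped = np.zeros(len(self.species), dtype=bool)
        is_clamped[self.clamped_idx] = True
        self.is_clamped = is_clamped

        self.producers: list[np.ndarray] = [
            np.array(
                [pos for pos, r in enumerate(self.reactions)
                 if self.species[j] in r.products],
                dtype=int,
            )
            for j in range(len(self.species))
        ]

        self.order = self._topological_order()

    def _topological_order(self):
        """Evaluation order of non-clamped species, or None if cyclic.

        Edges into clamped species are ignored: a clamp breaks any cycle
        through it.
        """
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.species)))
        for r in self.reactions:
            for src in r.inputs:
                for dst in r.products:
                    if not self.is_clamped[self.index[dst]]:
                        g.add_edge(self.index[src], self.index[dst])
        try:
            full = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            return None
        return [j for j in full if not self.is_clamped[j]]

    def cycle_species(self) -> list[str]:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.species)
        for r in self.reactions:
            for src in r.inputs:
                for dst in r.products:
                    if not self.is_clamped[self.index[dst]]:
                        g.add_edge(src, dst)
        nodes: set[str] = set()
        for comp in nx.strongly_connected_components(g):
            if len(comp) > 1 or g.has_edge(next(iter(comp)), next(iter(comp))):
                nodes |= comp
        return sorted(nodes)

    def _activities(self, X: np.ndarray, a, p, n) -> np.ndarray:
        """z for all reactions given species state X of shape (n_s, n_e)."""
        t1 = X[self.in1]
        t1 = np.where(self.inh1[:, None], 1.0 - t1, t1)
        u = t1
        if self.has2.any():
            t2 = X[np.where(self.has2, self.in2, 0)]
            t2 = np.where(self.inh2[:, None], 1.0 - t2, t2)
            u = np.where(self.has2[:, None], u * t2, u)
        return _hill(u, a[:, None], p[:, None], n)

    def run(self, params: TransferParams, clamp_values: np.ndarray,
            settings: SimulationSettings):
        """Simulate all experiments at once.

        ``clamp_values`` has shape (len(clamped_idx), n_e). Returns
        (X, Z) with shapes (n_s, n_e) and (n_r, n_e).
        """
        n_e = clamp_values.shape[1]
        n_s = len(self.species)
        a = np.asarray(params.a, dtype=float)
        p = np.asarray(params.p, dtype=float)
        n = params.n
        X = np.zeros((n_s, n_e))
        if self.clamped_idx.size:
            X[self.clamped_idx] = clamp_values
        Z = np.zeros((len(self.reactions), n_e))

        if self.order is not None:
            done = np.zeros(len(self.reactions), dtype=bool)
            for j in self.order:
                prods = self.producers[j]
                if prods.size == 0:
                    continue
                todo = prods[~done[prods]]
                if todo.size:
                    t1 = X[self.in1[todo]]
                    t1 = np.where(self.inh1[todo][:, None], 1.0 - t1, t1)
                    u = t1
                    h2 = self.has2[todo]
                    if h2.any():
                        t2 = X[np.where(h2, self.in2[todo], 0)]
                        t2 = np.where(self.inh2[todo][:, None], 1.0 - t2, t2)
                        u = np.where(h2[:, None], u * t2, u)
                    Z[todo] = _hill(u, a[todo][:, None], p[todo][:, None], n)
                    done[todo] = True
                X[j] = 1.0 - np.prod(1.0 - Z[prods], axis=0)
            # activities of reactions feeding only clamped species
            if not done.all():
                Z[~done] = self._activities(X, a, p, n)[~done]
            return X, Z

        for _ in range(settings.max_iterations):
            Z = self._activities(X, a, p, n)
            Xnew = np.zeros_like(X)
            for j in range(n_s):
                prods = self.producers[j]
                if prods.size:
                    Xnew[j] = 1.0 - np.prod(1.0 - Z[prods], axis=0)
            if self.clamped_idx.size:
                Xnew[self.clamped_idx] = clamp_values
            delta = np.abs(Xnew - X).max()
            X = Xnew
            if delta < settings.tolerance:
                return X, self._activities(X, a, p, n)
        raise ConvergenceError(
            "fixed-point iteration did not converge; cycle through species "
            f"{self.cycle_species()}"
        )

    def clamp_matrix(self, design: ExperimentDesign) -> np.ndarray:
        C = np.zeros((self.clamped_idx.size, design.n_experiments))
        pos = {int(j): row for row, j in enumerate(self.clamped_idx)}
        for k, e in enumerate(design.experiments):
            for name in e.treatments:
                j = self.index.get(name)
                if j is not None and j in pos:
                    C[pos[j], k] = 1.0
        return C


def _clamped_species(pathway: Pathway, design: ExperimentDesign) -> set[str]:
    clamped = set(design.treatment_species)
    for s in pathway.species:
        if s.role in ("stimulus", "inhibitor-node"):
            clamped.add(s.name)
    return clamped


def compile_pathway(pathway: Pathway, design: ExperimentDesign) -> CompiledPathway:
    return CompiledPathway(pathway, _clamped_species(pathway, design))


def simulate(
    pathway: Pathway,
    params: TransferParams | None,
    design: ExperimentDesign,
    settings: SimulationSettings | None = None,
) -> Prediction:
    """Simulate the pathway under every experiment of the design.

    ``params=None`` (or ``settings.nominal_params``) uses the nominal
    parameters a = 1.0, p = 0.5, n = 4.
    """
    settings = settings or SimulationSettings()
    compiled = compile_pathway(pathway, design)
    if params is None or settings.nominal_params:
        params = TransferParams.nominal(pathway.n_reactions)
    if params.n_reactions != pathway.n_reactions:
        raise ValueError("params do not cover every reaction")
    C = compiled.clamp_matrix(design)
    X, Z = compiled.run(params, C, settings)
    return Prediction(
        species=compiled.species,
        x=X.T.copy(),
        reaction_ids=compiled.reaction_ids,
        z=Z.T.copy(),
    )
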