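"""Prior-knowledge-network representation with logic-gate semantics.

A pathway is a signed directed graph of signalling reactions. Each reaction
``i`` has a set of reactants ``R_i`` (activating inputs), inhibitors ``I_i``
(inputs entering the gate as their complement, i.e. NOT inputs) and products
``P_i``. Gates are restricted to at most two inputs (``|R_i| + |I_i| in
{1, 2}``): a two-input reaction is an AND gate, while OR semantics arise
implicitly whenever several reactions share a product.

Networks are exchanged in a SIF dialect (three whitespace-separated columns
``source relation target`` with relation +1/-1). AND gates are encoded with
reserved ``and<N>`` helper nodes: each gate input points at the and-node
(sign -1 marking a NOT input) and the and-node has exactly one outgoing
edge to the product.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "Species",
    "Reaction",
    "Pathway",
    "TransferParams",
    "ValidationReport",
    "SIFParseError",
    "StructureError",
    "read_sif",
    "write_sif",
    "producing_reactions",
    "validate",
]

ROLES = ("stimulus", "inhibitor-node", "measured", "latent")

_AND_NODE_RE = re.compile(r"^and\d+$", re.IGNORECASE)


class SIFParseError(ValueError):
    """A SIF line could not be parsed."""


class StructureError(ValueError):
    """The network violates a structural invariant."""


@dataclass
class Species:
    """A signalling molecule. Names are case-sensitive and unique."""

    name: str
    role: str = "latent"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for species {self.name!r}")


@dataclass(frozen=True)
class Reaction:
    """One gated reaction: all reactants AND NOT all inhibitors -> products."""

    id: int
    reactants: frozenset[str]
    inhibitors: frozenset[str] = frozenset()
    products: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        n_inputs = len(self.reactants) + len(self.inhibitors)
        if n_inputs not in (1, 2):
            raise StructureError(
                f"reaction {self.id}: |R|+|I| must be 1 or 2, got {n_inputs}"
            )
        if not self.products:
            raise StructureError(f"reaction {self.id}: needs at least one product")
        if self.reactants & self.inhibitors:
            raise StructureError(
                f"reaction {self.id}: reactants and inhibitors overlap"
            )

    @property
    def inputs(self) -> frozenset[str]:
        return self.reactants | self.inhibitors

    def key(self) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
        """Identity of the reaction up to its integer id."""
        return (self.reactants, self.inhibitors, self.products)


@dataclass
class Pathway:
    """A set of species and gated reactions."""

    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise StructureError(f"duplicate species names: {dupes}")
        known = set(names)
        for r in self.reactions:
            missing = (r.inputs | r.products) - known
            if missing:
                raise StructureError(
                    f"reaction {r.id} references unknown species: {sorted(missing)}"
                )

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def get_species(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(f"unknown species {name!r}")

    def roles(self) -> dict[str, str]:
        return {s.name: s.role for s in self.species}

    def assign_roles(
        self,
        stimuli: set[str] = frozenset(),
        inhibitor_nodes: set[str] = frozenset(),
        measured: set[str] = frozenset(),
    ) -> "Pathway":
        """Return a copy with roles set from an experiment design/measurements.

        A species is a stimulus iff it appears as a treatment stimulus,
        an inhibitor-node iff it appears as a treatment inhibitor, measured
        iff it carries data columns; everything else is latent.
        """
        for group in (stimuli, inhibitor_nodes, measured):
            unknown = set(group) - set(self.species_names())
            if unknown:
                raise KeyError(f"unknown species in role assignment: {sorted(unknown)}")
        new_species = []
        for s in self.species:
            if s.name in stimuli:
                role = "stimulus"
            elif s.name in inhibitor_nodes:
                role = "inhibitor-node"
            elif s.name in measured:
                role = "measured"
            else:
                role = "latent"
            new_species.append(Species(s.name, role))
        return Pathway(new_species, list(self.reactions))

    def without_reactions(self, ids: set[int]) -> "Pathway":
        return Pathway(
            [replace(s) for s in self.species],
            [r for r in self.reactions if r.id not in ids],
        )


@dataclass
class TransferParams:
    """Per-reaction normalized-Hill parameters.

    ``a`` is the gain (scaling factor) in [0, 1]: a reaction with a ~ 0
    transmits no signal and is effectively removed. ``p`` is the curve
    midpoint. ``n`` is the Hill coefficient, a positive integer shared by
    all reactions (default 4).
    """

    a: "list[float] | object"
    p: "list[float] | object"
    n: int = 4

    def __post_init__(self) -> None:
        import numpy as np

        self.a = np.asarray(self.a, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.a.shape != self.p.shape:
            raise ValueError("a and p must have identical shapes")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("Hill coefficient n must be a positive integer")
        self.n = int(self.n)
        if ((self.a < 0) | (self.a > 1)).any():
            raise ValueError("gains a must lie in [0, 1]")
        if (self.p <= 0).any():
            raise ValueError("midpoints p must be positive")

    @classmethod
    def nominal(cls, n_reactions: int, n: int = 4) -> "TransferParams":
        """Initial-guess parameters: a = 1.0, p = 0.5 for every reaction."""
        import numpy as np

        return cls(np.ones(n_reactions), np.full(n_reactions, 0.5), n)

    @property
    def n_reactions(self) -> int:
        return int(self.a.shape[0])

    def copy(self) -> "TransferParams":
        return TransferParams(self.a.copy(), self.p.copy(), self.n)


# ---------------------------------------------------------------------------
# SIF exchange


def _parse_sif_lines(lines) -> list[tuple[str, int, str, int]]:
    triples = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise SIFParseError(
                f"line {lineno}: expected 'source relation target', got {line!r}"
            )
        source, rel, target = parts
        if rel not in ("1", "+1", "-1"):
            raise SIFParseError(
                f"line {lineno}: relation must be 1 or -1, got {rel!r}"
            )
        triples.append((source, 1 if rel in ("1", "+1") else -1, target, lineno))
    return triples


def read_sif(path) -> Pathway:
    """Read a pathway from a SIF file (and-node convention for AND gates)."""
    with open(path, "r", encoding="utf-8") as fh:
        triples = _parse_sif_lines(fh)

    and_inputs: dict[str, list[tuple[str, int]]] = {}
    and_outputs: dict[str, list[str]] = {}
    simple_edges: list[tuple[str, int, str]] = []
    species: list[str] = []
    seen: set[str] = set()

    def _note(name: str) -> None:
        if name not in seen and not _AND_NODE_RE.match(name):
            seen.add(name)
            species.append(name)

    for source, sign, target, lineno in triples:
        src_and = bool(_AND_NODE_RE.match(source))
        tgt_and = bool(_AND_NODE_RE.match(target))
        if src_and and tgt_and:
            raise SIFParseError(f"line {lineno}: and-node to and-node edge")
        if tgt_and:
            and_inputs.setdefault(target, []).append((source, sign))
        elif src_and:
            if sign != 1:
                raise SIFParseError(
                    f"line {lineno}: and-node output edge must have relation 1"
                )
            and_outputs.setdefault(source, []).append(target)
        else:
            simple_edges.append((source, sign, target))
        _note(source)
        _note(target)

    dangling = (set(and_inputs) | set(and_outputs)) - (
        set(and_inputs) & set(and_outputs)
    )
    if dangling:
        raise StructureError(f"dangling and-node(s): {sorted(dangling)}")

    reactions: list[Reaction] = []
    rid = 0
    for source, sign, target in simple_edges:
        if sign == 1:
            reactions.append(Reaction(rid, frozenset([source]), frozenset(),
                                      frozenset([target])))
        else:
            reactions.append(Reaction(rid, frozenset(), frozenset([source]),
                                      frozenset([target])))
        rid += 1
    for node in sorted(and_inputs):
        reactants = frozenset(s for s, sign in and_inputs[node] if sign == 1)
        inhibitors = frozenset(s for s, sign in and_inputs[node] if sign == -1)
        for target in and_outputs[node]:
            reactions.append(Reaction(rid, reactants, inhibitors,
                                      frozenset([target])))
            rid += 1

    return Pathway([Species(n) for n in species], reactions)


def write_sif(pathway: Pathway, path) -> None:
    """Write a pathway as SIF; two-input gates use the and-node convention."""
    lines = ["# SIF pathway: source relation target; and<N> nodes encode AND gates"]
    and_counter = 1
    for r in sorted(pathway.reactions, key=lambda r: r.id):
        if len(r.inputs) == 1:
            (name,) = r.inputs
            sign = "1" if name in r.reactants else "-1"
            for product in sorted(r.products):
                lines.append(f"{name}\t{sign}\t{product}")
        else:
            node = f"and{and_counter}"
            and_counter += 1
            for name in sorted(r.reactants):
                lines.append(f"{name}\t1\t{node}")
            for name in sorted(r.inhibitors):
                lines.append(f"{name}\t-1\t{node}")
            for product in sorted(r.products):
                lines.append(f"{node}\t1\t{product}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def producing_reactions(pathway: Pathway, j: str) -> set[int]:
    """The set T_j of ids of reactions having species ``j`` as a product."""
    if j not in set(pathway.species_names()):
        raise KeyError(f"unknown species {j!r}")
    return {r.id for r in pathway.reactions if j in r.products}


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate(pathway: Pathway) -> ValidationReport:
    """Report structural problems; never mutates the pathway.

    Violations: cardinality breaches and self-loops. Warnings: species
    unreachable from any stimulus, non-stimulus sources with no producing
    reaction, and NOT inputs targeting stimuli.
    """
    report = ValidationReport()
    names = set(pathway.species_names())
    roles = pathway.roles()

    for r in pathway.reactions:
        n_inputs = len(r.reactants) + len(r.inhibitors)
        if n_inputs not in (1, 2):
            report.violations.append(
                f"reaction {r.id}: |R|+|I| = {n_inputs} outside {{1, 2}}"
            )
        if r.inputs & r.products:
            report.violations.append(f"reaction {r.id}: self-loop")
        for product in r.products:
            if roles.get(product) == "stimulus" and r.inhibitors:
                report.warnings.append(
                    f"reaction {r.id}: NOT input targets stimulus {product!r}"
                )

    produced = set()
    for r in pathway.reactions:
        produced |= r.products
    for name in sorted(names):
        if roles[name] not in ("stimulus", "inhibitor-node") and name not in produced:
            report.warnings.append(f"species {name!r} has no producing reaction")

    stimuli = {n for n, role in roles.items() if role in ("stimulus", "inhibitor-node")}
    if stimuli:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(names)
        for r in pathway.reactions:
            for src in r.inputs:
                for dst in r.products:
                    g.add_edge(src, dst)
        reachable = set(stimuli)
        for s in stimuli:
            reachable |= nx.descendants(g, s)
        for name in sorted(names - reachable):
            report.warnings.append(f"species {name!r} unreachable from any stimulus")

    return report
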