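"""Perturbation-dataset I/O in a MIDAS-dialect CSV.

The dialect uses ``TR:<name>`` columns for treatments (0/1: the named
species is clamped active), an optional ``DA:<name>`` column carrying the
measurement time (the formalism is single-time-point, so rows that share a
treatment combination are averaged), and ``DV:<name>`` columns for measured
activation values of signal <name>, on [0, 1] after normalization.

Treatment species are resolved against the pathway: a treated species that
appears in any reaction's inhibitor set is an inhibitor node (a small-
molecule inhibitor represented explicitly in the network with NOT edges);
all other treated species are stimuli (ligands).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network_model import Pathway

__all__ = [
    "Experiment",
    "ExperimentDesign",
    "MeasurementSet",
    "Prediction",
    "MidasFormatError",
    "read_midas",
    "write_midas",
    "normalize_measurements",
    "assign_roles_from_data",
]

logger = logging.getLogger(__name__)


class MidasFormatError(ValueError):
    """The MIDAS file cannot be interpreted."""


@dataclass(frozen=True)
class Experiment:
    """One experimental condition: the species clamped active."""

    stimuli: frozenset[str] = frozenset()
    inhibitors: frozenset[str] = frozenset()

    @property
    def treatments(self) -> frozenset[str]:
        return self.stimuli | self.inhibitors


@dataclass
class ExperimentDesign:
    """The ordered list of experimental conditions k = 1..n_e."""

    experiments: list[Experiment] = field(default_factory=list)

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    @property
    def stimulus_species(self) -> set[str]:
        out: set[str] = set()
        for e in self.experiments:
            out |= e.stimuli
        return out

    @property
    def inhibitor_species(self) -> set[str]:
        out: set[str] = set()
        for e in self.experiments:
            out |= e.inhibitors
        return out

    @property
    def treatment_species(self) -> set[str]:
        return self.stimulus_species | self.inhibitor_species

    @classmethod
    def from_treatments(cls, conditions) -> "ExperimentDesign":
        """Build a design from explicit (stimuli, inhibitors) pairs."""
        return cls([Experiment(frozenset(s), frozenset(i)) for s, i in conditions])


@dataclass
class MeasurementSet:
    """Measured activations x̂_j^k for (signal j, experiment k) cells.

    ``values`` is (n_e, n_signals); ``mask`` is True where a measurement
    exists; ``weights`` are the per-cell objective weights (default 1:
    all nodes equally important).
    """

    signals: list[str]
    values: np.ndarray
    mask: np.ndarray = None
    weights: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.signals):
            raise ValueError("values must be (n_experiments, n_signals)")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape mismatch")
        if self.weights is None:
            self.weights = np.ones_like(self.values)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.values.shape:
            raise ValueError("weights shape mismatch")
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")

    @property
    def n_experiments(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_measured_cells(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "MeasurementSet":
        return MeasurementSet(
            list(self.signals), self.values.copy(), self.mask.copy(),
            self.weights.copy(),
        )


@dataclass
class Prediction:
    """Simulated species activations x_j^k and reaction activities z_i^k."""

    species: list[str]
    x: np.ndarray  # (n_e, n_species)
    reaction_ids: list[int]
    z: np.ndarray  # (n_e, n_reactions)

    def x_for(self, names) -> np.ndarray:
        """Activations of the named species, columns in the given order."""
        idx = [self.species.index(n) for n in names]
        return self.x[:, idx]

    def max_activity(self) -> np.ndarray:
        """Per-reaction maximum activity max_k z_i^k (reaction importance)."""
        return self.z.max(axis=0) if self.z.size else np.zeros(0)


# ---------------------------------------------------------------------------
# Reading / writing


def read_midas(path, pathway: Pathway):
    """Read a MIDAS-dialect CSV into (ExperimentDesign, MeasurementSet)."""
    df = pd.read_csv(path)
    tr_cols = [c for c in df.columns if c.startswith("TR:")]
    dv_cols = [c for c in df.columns if c.startswith("DV:")]
    da_cols = [c for c in df.columns if c.startswith("DA:")]
    if not tr_cols or not dv_cols:
        raise MidasFormatError("MIDAS file needs TR: and DV: columns")
    if len(df) == 0:
        raise MidasFormatError("empty data section")

    known = set(pathway.species_names())
    tr_species = [c[3:] for c in tr_cols]
    dv_species = [c[3:] for c in dv_cols]
    offenders = [n for n in tr_species + dv_species if n not in known]
    if offenders:
        raise MidasFormatError(
            f"unresolvable species in MIDAS header: {sorted(set(offenders))}"
        )

    inhibitor_pool: set[str] = set()
    for r in pathway.reactions:
        inhibitor_pool |= r.inhibitors

    # average rows sharing a treatment combination (single-time-point view)
    grouped = df.groupby(tr_cols, sort=False, as_index=False)[dv_cols].mean()
    if len(grouped) < len(df):
        logger.info(
            "averaged %d MIDAS rows into %d unique treatment conditions",
            len(df), len(grouped),
        )
    del da_cols

    experiments = []
    for _, row in grouped.iterrows():
        applied = {sp for sp, col in zip(tr_species, tr_cols) if row[col] > 0}
        experiments.append(Experiment(
            stimuli=frozenset(applied - inhibitor_pool),
            inhibitors=frozenset(applied & inhibitor_pool),
        ))
    design = ExperimentDesign(experiments)

    values = grouped[dv_cols].to_numpy(dtype=float)
    measurements = MeasurementSet(dv_species, values)
    return design, normalize_measurements(measurements)


def write_midas(design: ExperimentDesign, measurements: MeasurementSet, path) -> None:
    """Write a design + measurements as MIDAS-dialect CSV (round-trip stable)."""
    if measurements is not None and measurements.n_experiments != design.n_experiments:
        raise ValueError("design and measurements disagree on n_experiments")
    treatments = sorted(design.stimulus_species) + sorted(design.inhibitor_species)
    data: dict[str, list] = {f"TR:{t}": [] for t in treatments}
    for e in design.experiments:
        for t in treatments:
            data[f"TR:{t}"].append(1 if t in e.treatments else 0)
    include_dv = measurements is not None and measurements.mask.any()
    if include_dv:
        data["DA:ALL"] = [1] * design.n_experiments
        for j, sig in enumerate(measurements.signals):
            col = []
            for k in range(design.n_experiments):
                col.append(measurements.values[k, j]
                           if measurements.mask[k, j] else np.nan)
            data[f"DV:{sig}"] = col
    pd.DataFrame(data).to_csv(path, index=False)


def normalize_measurements(measurements: MeasurementSet) -> MeasurementSet:
    """Scale each signal into [0, 1] by its maximum when any value exceeds 1.

    Raw values must be nonnegative; signals already within [0, 1] are left
    untouched, so the operation is idempotent. Constant-zero signals are a
    no-op (no division by zero).
    """
    values = measurements.values.copy()
    masked = np.where(measurements.mask, values, 0.0)
    if (masked < 0).any():
        raise ValueError(
            "negative measurement values: preprocess raw data before loading"
        )
    for j in range(values.shape[1]):
        col_mask = measurements.mask[:, j]
        if not col_mask.any():
            continue
        col_max = values[col_mask, j].max()
        if col_max > 1.0:
            values[col_mask, j] = values[col_mask, j] / col_max
    return MeasurementSet(
        list(measurements.signals), values, measurements.mask.copy(),
        measurements.weights.copy(),
    )


def assign_roles_from_data(
    pathway: Pathway, design: ExperimentDesign, measurements: MeasurementSet
) -> Pathway:
    """Set species roles from the treatments and measured signals."""
    return pathway.assign_roles(
        stimuli=design.stimulus_species,
        inhibitor_nodes=design.inhibitor_species,
        measured=set(measurements.signals),
    )
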