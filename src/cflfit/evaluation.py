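"""Model evaluation: hold-out cross-validation and family statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_model import Pathway
from .midas_io import ExperimentDesign, MeasurementSet
from .fit import FitConfig, SolutionFamily, optimize, mae
from . import fit as _fit

__all__ = ["CrossValResult", "cross_validate", "family_statistics"]


@dataclass
class CrossValResult:
    """Replicate-averaged fit errors per exclusion fraction.

    ``total_mae`` is the error over all measured cells of a model trained
    on the non-excluded cells; ``excluded_mae`` is the error on the held-out
    cells only (0 when nothing was excluded).
    """

    fractions: np.ndarray
    total_mae: np.ndarray
    excluded_mae: np.ndarray
    replicates: int
    seed: int
    table: pd.DataFrame  # one row per (fraction, replicate)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _excluded_cells(mask: np.ndarray, fraction: float, rng, mode: str):
    """Boolean array marking the held-out cells among measured ones."""
    excluded = np.zeros_like(mask)
    if fraction <= 0:
        return excluded
    if mode == "cell":
        cells = np.argwhere(mask)
        n_out = int(round(fraction * len(cells)))
        pick = rng.choice(len(cells), size=n_out, replace=False)
        for idx in pick:
            k, j = cells[idx]
            excluded[k, j] = True
    elif mode == "condition":
        rows = np.where(mask.any(axis=1))[0]
        n_out = int(round(fraction * len(rows)))
        pick = rng.choice(len(rows), size=n_out, replace=False)
        excluded[rows[pick]] = mask[rows[pick]]
    else:
        raise ValueError("mode must be 'cell' or 'condition'")
    return excluded


def cross_validate(
    pathway: Pathway,
    design: ExperimentDesign,
    measurements: MeasurementSet,
    config: FitConfig | None = None,
    fractions=(0.0, 0.2, 0.4, 0.6, 0.8, 0.95),
    replicates: int = 5,
    seed: int = 0,
    mode: str = "cell",
) -> CrossValResult:
    """Leave out random portions of the data and score the refit model.

    For each exclusion fraction and replicate, a random subset of measured
    cells (or whole conditions with ``mode='condition'``) is removed from
    training; the model fitted on the remainder is then scored on all cells
    and on the excluded cells.
    """
    fractions = [float(f) for f in fractions]
    if fractions != sorted(fractions):
        raise ValueError("fractions must be sorted ascending")
    if any(not 0 <= f < 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1)")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    config = config or FitConfig()

    rows = []
    for fi, frac in enumerate(fractions):
        for rep in range(replicates):
            rng = np.random.default_rng([seed, fi, rep])
            excluded = _excluded_cells(measurements.mask, frac, rng, mode)
            train_mask = measurements.mask & ~excluded
            if not train_mask.any():
                raise ValueError(
                    f"exclusion fraction {frac} leaves no training cells"
                )
            train = MeasurementSet(
                list(measurements.signals), measurements.values.copy(),
                train_mask, measurements.weights.copy(),
            )
            prob_rng = np.random.default_rng([seed, fi, rep, 1])
            theta0 = _fit._Problem(pathway, design, train, config).initial_theta(
                prob_rng
            )
            sol = optimize(pathway, design, train, config, initial_theta=theta0)
            total = mae(sol.prediction, measurements)
            if excluded.any():
                held = MeasurementSet(
                    list(measurements.signals), measurements.values.copy(),
                    excluded, measurements.weights.copy(),
                )
                held_mae = mae(sol.prediction, held)
            else:
                held_mae = 0.0
            rows.append({"fraction": frac, "replicate": rep,
                         "total_mae": total, "excluded_mae": held_mae})

    table = pd.DataFrame(rows)
    means = table.groupby("fraction", sort=True)[["total_mae", "excluded_mae"]].mean()
    return CrossValResult(
        fractions=np.array(fractions),
        total_mae=means["total_mae"].to_numpy(),
        excluded_mae=means["excluded_mae"].to_numpy(),
        replicates=replicates,
        seed=seed,
        table=table,
    )


def family_statistics(family: SolutionFamily, near_zero: float = 0.05) -> dict:
    """Summary statistics of a multistart family.

    Reports the MAE mean and standard deviation (population convention),
    the sd of the first m family members as m grows (sampling-stability
    curve), the per-reaction average maximum activity, and the fraction of
    runs in which each gain ended below ``near_zero`` (candidate reaction
    eliminations).
    """
    if len(family.solutions) < 2:
        raise ValueError("family statistics need at least 2 solutions")
    maes = family.maes
    sd_curve = np.array([maes[:m].std() for m in range(2, len(maes) + 1)])
    a_matrix = np.stack([s.params.a for s in family.solutions])
    return {
        "mae_mean": float(maes.mean()),
        "mae_sd": float(maes.std()),
        "mae_best": float(maes.min()),
        "sd_vs_size": sd_curve,
        "average_activity": family.average_activity(),
        "near_zero_fraction": (a_matrix < near_zero).mean(axis=0),
    }
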