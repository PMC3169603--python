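"""Retinotopic versus head-centric evaluation of fixation-shift performance.

Each of the 32 fixation-shift cells (4 cardinal shifts x 8 target locations on
the 6-degree ring) is mapped to a baseline-ring cell under two candidate
models:

* the *retinotopic* model predicts performance from the baseline ring whose
  radius equals the target's retinal displacement from the shifted fixation
  dot (2, 4.25, 7.21, 9.27 or 10 dva), at the target's retinal direction;
* the *head-centric* model predicts performance from the unchanged location on
  the 6-degree ring, regardless of the shift.

Observed and predicted cells are summarized by a seeded bootstrap of
transformed accuracies, then compared by a paired t test over observer x cell
points and by regressing observed on predicted summaries; the model with the
higher R^2 wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import (
    FIXATION_SHIFT_DEG,
    MAIN_RING_ECC_DEG,
    TABLE_LOCATIONS,
    TABLE_SHIFTS,
    FieldLocation,
    retinal_displacement,
    shift_offset,
    snap_to_canonical,
    table1,
)
from .stats import ContrastResult, arcsine_transform, paired_t

MODELS = ("retinotopic", "head_centric")


def build_prediction_maps(
    snap_rule: str = "nearest",
    ring_ecc_deg: float = MAIN_RING_ECC_DEG,
    shift_deg: float = FIXATION_SHIFT_DEG,
) -> dict[str, pd.DataFrame]:
    """Baseline-cell predictions for every fixation-shift cell, per model.

    Returns ``{"retinotopic": ..., "head_centric": ...}``; each DataFrame has
    one row per (fixation_shift, target_location) with the predicted baseline
    ring eccentricity and direction.  ``snap_rule`` selects how the retinal
    direction of a shifted cell is assigned to a baseline direction:
    ``"nearest"`` snaps to the closest canonical angle, ``"label"`` keeps the
    target's screen label.
    """
    if snap_rule not in ("nearest", "label"):
        raise ValueError("snap_rule must be 'nearest' or 'label'")
    ecc_table = table1(ring_ecc_deg, shift_deg)
    rows_r, rows_h = [], []
    for shift in TABLE_SHIFTS:
        offset = shift_offset(shift, shift_deg)
        for loc in TABLE_LOCATIONS:
            _, angle = retinal_displacement(FieldLocation.compass(loc, ring_ecc_deg), offset)
            direction = snap_to_canonical(angle) if snap_rule == "nearest" else loc
            rows_r.append(
                {
                    "fixation_shift": shift,
                    "target_location": loc,
                    "pred_ring_deg": float(ecc_table.loc[shift, loc]),
                    "pred_location": direction,
                }
            )
            rows_h.append(
                {
                    "fixation_shift": shift,
                    "target_location": loc,
                    "pred_ring_deg": ring_ecc_deg,
                    "pred_location": loc,
                }
            )
    return {
        "retinotopic": pd.DataFrame(rows_r),
        "head_centric": pd.DataFrame(rows_h),
    }


@dataclass(frozen=True)
class BootstrapResult:
    """Seeded bootstrap of transformed cell accuracies.

    ``draws`` has shape (n_observers, n_cells, n_iter): per iteration and
    cell, the arcsine-transformed mean of ``k`` outcomes resampled with
    replacement from that observer's trials.  ``cells`` lists the cell keys
    (tuples over ``cell_cols``) in the row order of ``draws``.
    """

    observers: tuple
    cells: tuple
    cell_cols: tuple[str, ...]
    draws: np.ndarray
    n_iter: int
    k: int
    seed: int

    def observer_cell_means(self) -> np.ndarray:
        """Mean over iterates, shape (n_observers, n_cells)."""
        return self.draws.mean(axis=2)

    def averaged_draws(self) -> np.ndarray:
        """Observer-averaged iterate arrays, shape (n_cells, n_iter)."""
        return self.draws.mean(axis=0)

    def cell_index(self) -> dict[tuple, int]:
        return {cell: i for i, cell in enumerate(self.cells)}

    def summary(self, ci: float = 95.0) -> pd.DataFrame:
        """Per-cell summary of the observer-averaged iterates."""
        avg = self.averaged_draws()
        lo, hi = np.percentile(avg, [(100 - ci) / 2, 100 - (100 - ci) / 2], axis=1)
        out = pd.DataFrame(list(self.cells), columns=list(self.cell_cols))
        out["mean"] = avg.mean(axis=1)
        out["ci_lo"] = lo
        out["ci_hi"] = hi
        return out


def bootstrap_cells(
    trials: pd.DataFrame,
    cell_cols: tuple[str, ...],
    n_iter: int = 10_000,
    k: int = 10,
    seed: int = 0,
    observer_col: str = "observer_id",
    correct_col: str = "correct",
) -> BootstrapResult:
    """Bootstrap transformed accuracies per observer and design cell.

    For every observer and cell, each iteration draws ``k`` trial outcomes
    with replacement and records ``2*arcsin(sqrt(mean))``.  Substreams are
    derived deterministically from the master seed and the (observer, cell)
    position in canonical sorted order, so the assignment of randomness to
    cells does not depend on the row order of the trial table.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    observers = tuple(sorted(trials[observer_col].unique()))
    cells = tuple(sorted(trials.groupby(list(cell_cols)).groups.keys()))
    cells = tuple(c if isinstance(c, tuple) else (c,) for c in cells)
    draws = np.empty((len(observers), len(cells), n_iter))
    grouped = trials.groupby([observer_col, *cell_cols])
    for oi, obs in enumerate(observers):
        for ci, cell in enumerate(cells):
            key = (obs, *cell)
            try:
                idx = grouped.indices[key if len(key) > 1 else key[0]]
            except KeyError:
                raise ValueError(f"no trials for observer {obs!r}, cell {cell!r}") from None
            outcomes = trials[correct_col].to_numpy()[idx].astype(float)
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(oi, ci)))
            sample = outcomes[rng.integers(0, outcomes.size, size=(n_iter, k))]
            draws[oi, ci] = arcsine_transform(sample.mean(axis=1))
    return BootstrapResult(
        observers=observers,
        cells=cells,
        cell_cols=tuple(cell_cols),
        draws=draws,
        n_iter=n_iter,
        k=k,
        seed=seed,
    )


@dataclass(frozen=True)
class ModelFit:
    """Agreement between observed and model-predicted summaries."""

    paired: ContrastResult
    r_squared: float
    slope: float
    intercept: float
    f_statistic: float
    df_num: int
    df_den: int
    regression_p: float

    def to_dict(self) -> dict:
        return {
            "paired": self.paired.to_dict(),
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "F": self.f_statistic,
            "df": [self.df_num, self.df_den],
            "regression_p": self.regression_p,
        }


@dataclass(frozen=True)
class ModelComparisonResult:
    """Outcome of the retinotopic versus head-centric evaluation.

    ``winner`` is the model whose predictions explain more variance in the
    observed summaries; ``winner_paired_nonsignificant`` flags whether the
    winner's observed-vs-predicted paired difference is non-significant at
    the 0.05 level (the signature of a well-matching model).
    """

    models: dict[str, ModelFit]
    winner: str
    winner_paired_nonsignificant: bool
    points: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "models": {name: fit.to_dict() for name, fit in self.models.items()},
            "winner": self.winner,
            "winner_paired_nonsignificant": self.winner_paired_nonsignificant,
        }


def _regression(observed: np.ndarray, predicted: np.ndarray) -> tuple:
    n = observed.size
    res = sps.linregress(predicted, observed)
    r2 = float(res.rvalue**2)
    df_den = n - 2
    if r2 >= 1.0:
        f = math.inf
        p = 0.0
    else:
        f = r2 / (1.0 - r2) * df_den
        p = float(sps.f.sf(f, 1, df_den))
    return r2, float(res.slope), float(res.intercept), float(f), df_den, p


def compare_models(
    observed: BootstrapResult,
    maps: dict[str, pd.DataFrame],
    baseline: BootstrapResult,
) -> ModelComparisonResult:
    """Evaluate both reference-frame models against observed shift cells.

    Pairs every observer x (shift, location) observed summary with the mapped
    baseline summary; runs a two-sided paired t over all points and an OLS
    regression of observed on predicted.  The winner is the model with higher
    R^2.
    """
    if observed.observers != baseline.observers:
        raise ValueError("observed and baseline must cover the same observers")
    obs_means = observed.observer_cell_means()
    base_means = baseline.observer_cell_means()
    base_index = baseline.cell_index()
    obs_index = observed.cell_index()

    fits: dict[str, ModelFit] = {}
    point_rows = []
    for name in MODELS:
        mapping = maps[name]
        obs_vals, pred_vals = [], []
        for oi, obs_id in enumerate(observed.observers):
            for _, row in mapping.iterrows():
                ocell = (row["fixation_shift"], row["target_location"])
                bcell = (row["pred_ring_deg"], row["pred_location"])
                if ocell not in obs_index or bcell not in base_index:
                    raise ValueError(f"unmapped cell: observed {ocell}, baseline {bcell}")
                o = obs_means[oi, obs_index[ocell]]
                p = base_means[oi, base_index[bcell]]
                obs_vals.append(o)
                pred_vals.append(p)
                point_rows.append(
                    {
                        "model": name,
                        "observer_id": obs_id,
                        "fixation_shift": ocell[0],
                        "target_location": ocell[1],
                        "pred_ring_deg": bcell[0],
                        "pred_location": bcell[1],
                        "observed": o,
                        "predicted": p,
                    }
                )
        obs_arr = np.asarray(obs_vals)
        pred_arr = np.asarray(pred_vals)
        paired = paired_t(obs_arr, pred_arr)
        r2, slope, intercept, f, df_den, p = _regression(obs_arr, pred_arr)
        fits[name] = ModelFit(paired, r2, slope, intercept, f, 1, df_den, p)

    winner = max(MODELS, key=lambda m: fits[m].r_squared)
    return ModelComparisonResult(
        models=fits,
        winner=winner,
        winner_paired_nonsignificant=fits[winner].paired.p > 0.05,
        points=pd.DataFrame(point_rows),
    )
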