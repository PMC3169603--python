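"""Statistical layer for performance-field experiments.

Implements the variance-stabilizing arcsine transform of accuracies, paired
meridian contrasts evaluated in a configurable (possibly head-rolled) frame,
and the fully crossed within-subject ANOVA with factors head posture (2),
distractor orientation (2) and target location (8), each effect tested against
its own effect-by-subject interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import CANONICAL_BY_ANGLE, COMPASS_ANGLES


def arcsine_transform(prop):
    """Variance-stabilizing transform ``2*arcsin(sqrt(p))`` of a proportion.

    Maps [0, 1] onto [0, pi]; raises on out-of-range input.
    """
    p = np.asarray(prop, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = 2.0 * np.arcsin(np.sqrt(p))
    return out if out.ndim else float(out)


def inverse_arcsine_transform(t):
    """Inverse of :func:`arcsine_transform` on [0, pi]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > np.pi):
        raise ValueError("transformed values must lie in [0, pi]")
    out = np.sin(t / 2.0) ** 2
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ContrastResult:
    """Outcome of a paired comparison in transformed-accuracy units."""

    statistic: float
    df: int
    sem: float
    p: float
    mean_diff: float

    def to_dict(self) -> dict:
        return {
            "t": self.statistic,
            "df": self.df,
            "sem": self.sem,
            "p": self.p,
            "mean_diff": self.mean_diff,
        }


def paired_t(x, y) -> ContrastResult:
    """Classical paired t test, two-sided.

    Degenerate inputs are reported as limiting cases: identical pairs give
    ``t = 0, p = 1``; a constant nonzero difference gives an infinite t with
    ``p = 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValueError("missing values are not allowed")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    sem = sd / math.sqrt(n)
    df = n - 1
    if sem == 0.0:
        if mean == 0.0:
            return ContrastResult(0.0, df, 0.0, 1.0, 0.0)
        return ContrastResult(math.copysign(math.inf, mean), df, 0.0, 0.0, mean)
    t = mean / sem
    p = 2.0 * sps.t.sf(abs(t), df)
    return ContrastResult(float(t), df, sem, float(p), mean)


#: Location sets of each meridian contrast, as canonical angles in the
#: analysis frame (before any frame roll is applied).
_AXIS_SETS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "horizontal_vs_vertical": ((0.0, 180.0), (90.0, 270.0)),
    "lower_vs_upper": ((270.0,), (90.0,)),
    "intercardinal_vs_horizontal": ((45.0, 135.0, 225.0, 315.0), (0.0, 180.0)),
    "intercardinal_vs_vertical": ((45.0, 135.0, 225.0, 315.0), (90.0, 270.0)),
}


def _rolled_labels(angles: tuple[float, ...], frame_roll_deg: float) -> list[str]:
    labels = []
    for a in angles:
        rolled = (a + frame_roll_deg) % 360.0
        idx = rolled / 45.0
        if abs(idx - round(idx)) > 1e-9:
            raise ValueError("frame_roll_deg must carry canonical angles onto canonical angles")
        labels.append(CANONICAL_BY_ANGLE[int(round(idx)) % 8])
    return labels


def meridian_contrast(
    cells: pd.DataFrame,
    frame_roll_deg: float,
    axis: str,
    unit_keys: tuple[str, ...] = ("observer_id", "distractor_tilt_deg"),
    location_col: str = "target_location",
    value_col: str = "transformed",
) -> ContrastResult:
    """Paired performance-field contrast between two rolled location sets.

    Location sets are selected after rotating the canonical axes by
    ``frame_roll_deg``: with a 45-degree roll the horizontal meridian becomes
    {NE, SW}, the vertical meridian {NW, SE}, and the lower/upper vertical
    endpoints SE/NW.  Each paired unit (default: observer x distractor
    condition) contributes the mean transformed accuracy over each set, and a
    two-sided paired t test is run across units.
    """
    if axis not in _AXIS_SETS:
        raise ValueError(f"unknown axis {axis!r}; one of {sorted(_AXIS_SETS)}")
    set1, set2 = (_rolled_labels(s, frame_roll_deg) for s in _AXIS_SETS[axis])
    pivot = cells.pivot_table(
        index=list(unit_keys), columns=location_col, values=value_col, aggfunc="mean"
    )
    missing = [loc for loc in COMPASS_ANGLES if loc not in pivot.columns]
    if missing or pivot.isna().any().any():
        raise ValueError(
            "every unit must cover all 8 canonical locations; missing: "
            f"{missing or 'values within units'}"
        )
    m1 = pivot[set1].mean(axis=1).to_numpy()
    m2 = pivot[set2].mean(axis=1).to_numpy()
    return paired_t(m1, m2)


def _subset_ss(y: np.ndarray, axes: tuple[int, ...]) -> float:
    """Sum of squares of the inclusion-exclusion effect over an axis subset.

    ``y`` has the subject axis first; the effect of ``axes`` at each cell is
    the alternating sum of marginal means over all subsets of ``axes``,
    broadcast back to the full array, and the SS sums its square over every
    element (which folds in the usual replication multipliers).
    """
    k = len(axes)
    effect = np.zeros_like(y)
    for r in range(k + 1):
        for sub in combinations(axes, r):
            marg = y.mean(axis=tuple(ax for ax in range(y.ndim) if ax not in sub), keepdims=True)
            effect += (-1.0) ** (k - r) * marg
    return float((effect**2).sum())


def rm_anova_2x2x8(
    cells: pd.DataFrame,
    subject_col: str = "observer_id",
    factor_cols: tuple[str, str, str] = (
        "head_posture",
        "distractor_tilt_deg",
        "target_location",
    ),
    value_col: str = "transformed",
    degeneracy_tol: float = 1e-12,
) -> pd.DataFrame:
    """Fully crossed three-way within-subject ANOVA.

    Requires exactly one value per subject x factor cell (no imputation).
    Each effect is tested against its own effect-by-subject interaction;
    reports F, MSE, numerator/denominator df, p and partial eta squared per
    effect.  Degenerate error terms (all residuals zero) are reported as
    ``F = 0`` with the ``degenerate`` flag set.
    """
    pivot = cells.pivot_table(
        index=subject_col, columns=list(factor_cols), values=value_col, aggfunc="count"
    )
    values = cells.pivot_table(
        index=subject_col, columns=list(factor_cols), values=value_col, aggfunc="mean"
    )
    if pivot.isna().any().any() or (pivot != 1).any().any():
        raise ValueError("design must be fully crossed with one value per subject x cell")

    levels = [sorted(cells[c].unique(), key=str) for c in factor_cols]
    n_sub = values.shape[0]
    shape = (n_sub, *(len(lv) for lv in levels))
    cols = pd.MultiIndex.from_product(levels, names=list(factor_cols))
    y = values.reindex(columns=cols).to_numpy().reshape(shape)
    if np.any(np.isnan(y)):  # pragma: no cover - guarded by the count check
        raise ValueError("incomplete design")

    rows = []
    factor_axes = {name: i + 1 for i, name in enumerate(factor_cols)}
    for r in range(1, len(factor_cols) + 1):
        for combo in combinations(factor_cols, r):
            axes = tuple(factor_axes[c] for c in combo)
            ss_eff = _subset_ss(y, axes)
            ss_err = _subset_ss(y, (0, *axes))
            df_eff = int(np.prod([shape[a] - 1 for a in axes]))
            df_err = df_eff * (n_sub - 1)
            degenerate = ss_err <= degeneracy_tol
            if degenerate:
                f = 0.0 if ss_eff <= degeneracy_tol else math.inf
                p = 1.0 if f == 0.0 else 0.0
                mse = 0.0
            else:
                mse = ss_err / df_err
                f = (ss_eff / df_eff) / mse
                p = float(sps.f.sf(f, df_eff, df_err))
            eta = 0.0 if (ss_eff + ss_err) <= degeneracy_tol else ss_eff / (ss_eff + ss_err)
            rows.append(
                {
                    "effect": ":".join(combo),
                    "F": f,
                    "MSE": mse,
                    "df_num": df_eff,
                    "df_den": df_err,
                    "p": p,
                    "partial_eta_sq": eta,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows).set_index("effect")
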