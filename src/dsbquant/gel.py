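"""Densitometry: lane normalization, fold-changes, half-life fits, SSA repair kinetics.

Band intensities arrive as already-measured numbers (e.g. ImageJ output);
every quantity downstream is a ratio, so any global exposure rescaling of a
gel cancels exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecayFit",
    "FoldChange",
    "normalize_lanes",
    "fold_change",
    "fit_half_life",
    "repair_fraction",
]

LN2 = float(np.log(2.0))


@dataclass
class DecayFit:
    """First-order decay fit: level(t) = level(treat) * exp(-k (t - treat))."""

    k_per_h: float
    half_life_h: float
    r_squared: float
    n_points: int
    treat_time_h: float
    decaying: bool  # False flags a non-decreasing series (k <= 0)


@dataclass
class FoldChange:
    """Ratio of normalized levels, phrased the way gel figures report it.

    ``ratio`` = level_b / level_a; ``fold`` = 1/ratio when ratio < 1 (an
    "x-fold reduction"), else the ratio itself (an increase).
    """

    ratio: float
    fold: float
    direction: str  # "reduction" | "increase" | "unchanged"


def normalize_lanes(
    series: pd.DataFrame,
    reference: str | float = "t0",
    *,
    loading_column: str = "loading",
) -> pd.DataFrame:
    """Normalize band intensities to the loading control and a reference lane.

    level = (band / loading) / (band / loading at the reference lane), per
    condition. ``reference`` is ``"t0"`` or an explicit reference time.
    For ectopic-donor Southern blots pass ``loading_column="donor"`` (the
    donor band serves as the loading control). Returns the input with a
    ``level`` column added.
    """
    df = series.copy()
    for col in ("condition", "time_h", "band", loading_column):
        if col not in df.columns:
            raise ValueError(f"lane table missing column {col!r}")
    if (df["band"] <= 0).any() or (df[loading_column] <= 0).any():
        raise ValueError("band and loading intensities must be > 0")
    df["time_h"] = df["time_h"].astype(float)
    ref_time = 0.0 if reference == "t0" else float(reference)

    df["level"] = df["band"] / df[loading_column]
    out = []
    for cond, grp in df.groupby("condition", sort=False):
        ref_rows = grp[grp["time_h"] == ref_time]
        if ref_rows.empty:
            raise ValueError(f"condition {cond!r}: reference lane t={ref_time} missing")
        grp = grp.copy()
        grp["level"] = grp["level"] / float(ref_rows["level"].iloc[0])
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def _level_at(levels: pd.DataFrame, time_h: float) -> float:
    rows = levels[levels["time_h"].astype(float) == float(time_h)]
    if rows.empty:
        raise ValueError(f"no lane at t={time_h} h")
    return float(rows["level"].iloc[0])


def fold_change(series_a: pd.DataFrame, series_b: pd.DataFrame, time_h: float) -> FoldChange:
    """Ratio of normalized level_b to level_a at a shared timepoint."""
    a = _level_at(series_a, time_h)
    b = _level_at(series_b, time_h)
    ratio = b / a
    if ratio < 1.0:
        return FoldChange(ratio=ratio, fold=1.0 / ratio, direction="reduction")
    if ratio > 1.0:
        return FoldChange(ratio=ratio, fold=ratio, direction="increase")
    return FoldChange(ratio=1.0, fold=1.0, direction="unchanged")


def fit_half_life(levels: pd.DataFrame, treat_time_h: float) -> DecayFit:
    """Log-linear least-squares decay fit over lanes at t >= treat_time.

    Fits log(level) against (t - treat_time); returns the rate constant k,
    half-life ln2/k and r-squared. A non-decreasing series yields a warning
    and k is reported with its sign.
    """
    df = levels[levels["time_h"].astype(float) >= float(treat_time_h)]
    df = df[df["level"] > 0]
    t = df["time_h"].to_numpy(dtype=float) - float(treat_time_h)
    y = np.log(df["level"].to_numpy(dtype=float))
    if t.size < 2 or np.unique(t).size < 2:
        raise ValueError("need >=2 post-treatment timepoints with level > 0")
    fit = stats.linregress(t, y)
    k = float(-fit.slope)
    if k <= 0:
        warnings.warn("series does not decay (k <= 0); half-life reported with sign")
    half_life = LN2 / k if k != 0 else float("inf")
    return DecayFit(
        k_per_h=k,
        half_life_h=half_life,
        r_squared=float(fit.rvalue**2),
        n_points=int(t.size),
        treat_time_h=float(treat_time_h),
        decaying=k > 0,
    )


def repair_fraction(
    series: pd.DataFrame,
    *,
    reference_condition: str = "untreated",
    loading_column: str = "loading",
) -> pd.DataFrame:
    """Fraction of the repair-product band, scaled to the untreated plateau.

    For a single-strand-annealing Southern time course: product level
    (band/loading) is scaled so the reference condition's final timepoint
    equals 1. The product band may legitimately be 0 (no repair). Returns a
    DataFrame with columns ``condition, time_h, fraction``.
    """
    df = series.copy()
    for col in ("condition", "time_h", "band", loading_column):
        if col not in df.columns:
            raise ValueError(f"lane table missing column {col!r}")
    if (df["band"] < 0).any() or (df[loading_column] <= 0).any():
        raise ValueError("band must be >= 0 and loading > 0")
    df["time_h"] = df["time_h"].astype(float)
    df["level"] = df["band"] / df[loading_column]

    if reference_condition in set(df["condition"]):
        ref = df[df["condition"] == reference_condition]
    else:
        ref = df
    plateau_t = ref["time_h"].max()
    plateau = float(ref.loc[ref["time_h"] == plateau_t, "level"].iloc[0])
    if plateau == 0:
        raise ValueError("reference plateau level is 0; cannot scale")
    out = df[["condition", "time_h"]].copy()
    out["fraction"] = df["level"] / plateau
    return out.reset_index(drop=True)
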