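"""Resection-rate estimation from qPCR time courses.

The estimator proceeds in three stages, each exposed separately:

1. :func:`normalize_qpcr` — double normalization of raw quantities to the
   control (uninvolved) locus and to the pre-induction (t=0) sample,
   equivalently ``2**(-ddCq)`` for Cq-encoded input.
2. :func:`threshold_crossings` — for each timepoint's signal-vs-distance
   curve, the position where the normalized signal crosses a threshold
   (default 0.75), by linear interpolation between the nearest amplicons.
3. :func:`fit_resection_rate` — ordinary least squares of crossing distance
   on time; the slope is the population 5'->3' resection front speed in kb/h.

:func:`estimate_rate` composes the three.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AmpliconPanel

__all__ = [
    "SignalMatrix",
    "CrossingSet",
    "RateEstimate",
    "read_qpcr_table",
    "normalize_qpcr",
    "threshold_crossings",
    "fit_resection_rate",
    "estimate_rate",
]

QPCR_COLUMNS = ["condition", "replicate", "time_h", "amplicon", "value"]


@dataclass
class SignalMatrix:
    """Normalized qPCR signal s(t, d), unit by construction at t=0.

    ``mean`` is the replicate geometric mean (index: time_h, columns:
    distance_kb, ascending); ``low``/``high`` give the replicate min-max
    range; ``per_replicate`` maps replicate id to its own matrix.
    """

    mean: pd.DataFrame
    low: pd.DataFrame
    high: pd.DataFrame
    per_replicate: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return self.mean.index.to_numpy(dtype=float)

    @property
    def distances(self) -> np.ndarray:
        return self.mean.columns.to_numpy(dtype=float)


@dataclass
class CrossingSet:
    """Threshold-crossing points (time_h, distance_kb) plus a drop log."""

    points: pd.DataFrame  # columns: time_h, distance_kb
    threshold: float
    orientation: str
    dropped: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class RateEstimate:
    """Fitted resection front velocity with diagnostics.

    ``rate_kb_h`` is the OLS slope of distance on time; ``intercept_h`` the
    x-intercept (onset lag, h). ``replicate_rates`` and ``rate_range`` come
    from per-replicate fits when replicate-level matrices are available.
    """

    rate_kb_h: float
    intercept_h: float
    r_squared: float
    n_points: int
    replicate_rates: dict = field(default_factory=dict)
    rate_range: tuple | None = None

    def to_dict(self) -> dict:
        return {
            "rate_kb_h": self.rate_kb_h,
            "intercept_h": self.intercept_h,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "replicate_rates": {str(k): v for k, v in self.replicate_rates.items()},
            "range": list(self.rate_range) if self.rate_range else None,
        }


def read_qpcr_table(path, *, encoding: str | None = None) -> tuple[pd.DataFrame, str]:
    """Read a qPCR CSV, honouring an optional ``# encoding=cq|quantity`` header line.

    Returns the table and the encoding actually in effect (explicit argument
    wins over the header flag; default ``quantity``).
    """
    header_encoding = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "encoding=" in line:
                header_encoding = line.split("encoding=")[1].strip()
    df = pd.read_csv(path, comment="#")
    df = df.rename(columns={"quantity": "value", "cq": "value"})
    enc = encoding or header_encoding or "quantity"
    if enc not in ("quantity", "cq"):
        raise ValueError(f"unknown encoding {enc!r}")
    return df, enc


def normalize_qpcr(
    table: pd.DataFrame,
    panel: AmpliconPanel,
    *,
    encoding: str = "quantity",
) -> SignalMatrix:
    """Double-normalize raw qPCR quantities to the control locus and to t=0.

    Per replicate, r(t, d) = q(t, d) / q(t, control) and
    s(t, d) = r(t, d) / r(0, d); with Cq input, quantities are first
    converted as q = 2**(-Cq) (perfect doubling), which makes s equal to
    2**(-ddCq). Replicates are aggregated by geometric mean; the min-max
    range across replicates is retained.
    """
    df = table.copy()
    if "value" not in df.columns:
        for alt in ("quantity", "cq"):
            if alt in df.columns:
                df = df.rename(columns={alt: "value"})
    missing = [c for c in ("replicate", "time_h", "amplicon", "value") if c not in df.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")

    df["time_h"] = df["time_h"].astype(float)
    if encoding == "cq":
        df["value"] = 2.0 ** (-df["value"].astype(float))
    elif encoding != "quantity":
        raise ValueError(f"unknown encoding {encoding!r}")
    if (df["value"] <= 0).any():
        bad = df.loc[df["value"] <= 0].iloc[0]
        raise ValueError(
            f"non-positive quantity for amplicon {bad['amplicon']!r} at "
            f"t={bad['time_h']} (replicate {bad['replicate']})"
        )

    control_names = {a.name for a in panel.controls}
    target_dist = {a.name: a.distance_kb for a in panel.targets}
    unknown = set(df["amplicon"]) - control_names - set(target_dist)
    if unknown:
        raise ValueError(f"amplicons not in panel: {sorted(unknown)}")

    per_replicate: dict = {}
    for rep, grp in df.groupby("replicate"):
        times = np.sort(grp["time_h"].unique())
        if 0.0 not in times:
            raise ValueError(f"replicate {rep}: no t=0 block")
        ratios = {}
        for t, block in grp.groupby("time_h"):
            ctrl = block.loc[block["amplicon"].isin(control_names), "value"]
            if ctrl.empty:
                raise ValueError(f"replicate {rep}, t={t}: control amplicon missing")
            ctrl_q = float(np.exp(np.log(ctrl).mean()))  # geomean over control amplicons
            tgt = block[block["amplicon"].isin(target_dist)]
            ratios[t] = {
                target_dist[a]: v / ctrl_q for a, v in zip(tgt["amplicon"], tgt["value"])
            }
        mat = pd.DataFrame.from_dict(ratios, orient="index").sort_index()
        mat = mat[sorted(mat.columns)]
        mat = mat.div(mat.loc[0.0], axis="columns")  # t=0 self-normalization
        mat.index.name = "time_h"
        mat.columns.name = "distance_kb"
        per_replicate[rep] = mat

    stacked = np.stack([m.to_numpy() for m in per_replicate.values()])
    template = next(iter(per_replicate.values()))
    mean = pd.DataFrame(
        np.exp(np.nanmean(np.log(stacked), axis=0)),
        index=template.index,
        columns=template.columns,
    )
    low = pd.DataFrame(stacked.min(axis=0), index=template.index, columns=template.columns)
    high = pd.DataFrame(stacked.max(axis=0), index=template.index, columns=template.columns)
    return SignalMatrix(mean=mean, low=low, high=high, per_replicate=per_replicate)


def _interpolate_crossing(
    x: np.ndarray, s: np.ndarray, threshold: float
) -> tuple[float | None, str]:
    """Locate where a curve crosses the threshold, last bracketing pair.

    Works for both orientations of the curve: signal falling away from the
    break (the bracketing pair has s >= thr before s < thr) or rising away
    from it (the mirror). Returns (coordinate, reason-if-dropped).
    """
    above = s >= threshold
    if above.all():
        return None, "signal >= threshold everywhere"
    if (~above).all():
        return None, "signal < threshold everywhere"
    falling = s[0] >= s[-1]
    if falling:
        # last index with s >= thr; its successor must exist and be < thr
        i = int(np.flatnonzero(above)[-1])
    else:
        i = int(np.flatnonzero(~above)[-1])
    if i + 1 >= s.size:
        return None, "threshold not bracketed by adjacent points"
    s_lo, s_hi = s[i], s[i + 1]
    if s_hi == s_lo:
        return float(x[i]), ""
    frac = (threshold - s_lo) / (s_hi - s_lo)
    if not 0.0 <= frac <= 1.0:
        return None, "threshold not bracketed by adjacent points"
    return float(x[i] + frac * (x[i + 1] - x[i])), ""


def threshold_crossings(
    matrix: SignalMatrix | pd.DataFrame,
    threshold: float = 0.75,
    orientation: str = "distance_at_time",
) -> CrossingSet:
    """Interpolated threshold crossings of the normalized signal.

    ``distance_at_time`` (default): for each timepoint's signal-vs-distance
    curve, interpolate the distance d* where the signal crosses the
    threshold; emit (t, d*). ``time_at_distance``: per amplicon, interpolate
    the time the signal-vs-time curve crosses the threshold. Curves that
    never bracket the threshold contribute no point and are logged.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    mean = matrix.mean if isinstance(matrix, SignalMatrix) else matrix
    times = mean.index.to_numpy(dtype=float)
    dists = mean.columns.to_numpy(dtype=float)

    points: list[tuple[float, float]] = []
    dropped: list[str] = []
    if orientation == "distance_at_time":
        if dists.size < 2:
            raise ValueError("need >=2 amplicon distances for distance_at_time")
        for t in times:
            s = mean.loc[t].to_numpy(dtype=float)
            coord, reason = _interpolate_crossing(dists, s, threshold)
            if coord is None:
                dropped.append(f"t={t:g} h: {reason}")
            else:
                points.append((float(t), coord))
    elif orientation == "time_at_distance":
        if times.size < 2:
            raise ValueError("need >=2 timepoints for time_at_distance")
        for d in dists:
            s = mean[d].to_numpy(dtype=float)
            coord, reason = _interpolate_crossing(times, s, threshold)
            if coord is None:
                dropped.append(f"d={d:g} kb: {reason}")
            else:
                points.append((coord, float(d)))
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    pts = pd.DataFrame(points, columns=["time_h", "distance_kb"])
    if pts.empty:
        raise ValueError(f"no crossings: every curve was dropped ({'; '.join(dropped)})")
    return CrossingSet(points=pts, threshold=threshold, orientation=orientation, dropped=dropped)


def fit_resection_rate(
    crossings: CrossingSet | pd.DataFrame,
    replicate_crossings: dict | None = None,
) -> RateEstimate:
    """OLS of crossing distance (kb) on time (h); the slope is the rate.

    When per-replicate crossing sets are supplied, each replicate is fitted
    separately and the min-max range of the replicate slopes is reported
    (the study's error bars are ranges, not standard errors).
    """
    pts = crossings.points if isinstance(crossings, CrossingSet) else crossings
    t = pts["time_h"].to_numpy(dtype=float)
    d = pts["distance_kb"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("need >=2 crossing points to fit a rate")
    if np.unique(t).size < 2:
        raise ValueError("all crossing times identical: slope undefined")
    fit = stats.linregress(t, d)
    slope = float(fit.slope)
    x_intercept = float(-fit.intercept / slope) if slope != 0 else float("nan")
    est = RateEstimate(
        rate_kb_h=slope,
        intercept_h=x_intercept,
        r_squared=float(fit.rvalue**2),
        n_points=int(t.size),
    )
    if replicate_crossings:
        rates = {}
        for rep, cs in replicate_crossings.items():
            try:
                rates[rep] = fit_resection_rate(cs).rate_kb_h
            except ValueError:
                continue
        est.replicate_rates = rates
        if rates:
            vals = list(rates.values())
            est.rate_range = (min(vals), max(vals))
    return est


def estimate_rate(
    table: pd.DataFrame,
    panel: AmpliconPanel,
    *,
    threshold: float = 0.75,
    orientation: str = "distance_at_time",
    encoding: str = "quantity",
) -> RateEstimate:
    """End-to-end estimator: normalize -> threshold crossings -> OLS rate.

    The threshold is applied to the replicate-mean curve; per-replicate fits
    are computed alongside and reported as ``replicate_rates`` / range.
    """
    try:
        matrix = normalize_qpcr(table, panel, encoding=encoding)
    except ValueError as err:
        raise ValueError(f"normalization: {err}") from err
    try:
        crossings = threshold_crossings(matrix, threshold=threshold, orientation=orientation)
    except ValueError as err:
        raise ValueError(f"crossing detection: {err}") from err

    rep_crossings = {}
    for rep, mat in matrix.per_replicate.items():
        try:
            rep_crossings[rep] = threshold_crossings(
                mat, threshold=threshold, orientation=orientation
            )
        except ValueError:
            warnings.warn(f"replicate {rep}: no usable crossings; excluded from range")
    try:
        return fit_resection_rate(crossings, rep_crossings or None)
    except ValueError as err:
        raise ValueError(f"rate fit: {err}") from err
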