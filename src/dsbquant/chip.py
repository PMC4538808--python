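"""ChIP fold-enrichment around a DSB: normalization, spreading, persistence.

The assay is locus-directed ChIP-qPCR: IP and input quantities per position
(signed kb from the break) per timepoint. Fold-enrichment is a double ratio —
(IP/input) at the damage locus over (IP/input) at an uninvolved control
locus, further referenced to the pre-induction (t=0) sample — so plate-scale
and antibody-efficiency effects cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnrichmentMatrix",
    "chip_fold_enrichment",
    "spreading_extent",
    "persistence_ratio",
]

CHIP_COLUMNS = ["locus", "position_kb", "time_h", "replicate", "ip", "input", "is_control"]


@dataclass
class EnrichmentMatrix:
    """Fold-enrichment E(locus, position, time) relative to control and t=0.

    ``values`` is a long DataFrame with columns
    ``locus, position_kb, time_h, enrichment, low, high`` (replicate geometric
    mean and min-max range). ``per_replicate`` keeps the per-replicate values.
    """

    values: pd.DataFrame
    per_replicate: pd.DataFrame = field(default_factory=pd.DataFrame)

    def at(self, position_kb: float, time_h: float, locus: str | None = None) -> float:
        sel = self.values
        if locus is not None:
            sel = sel[sel["locus"] == locus]
        sel = sel[(sel["position_kb"] == position_kb) & (sel["time_h"] == time_h)]
        if sel.empty:
            raise KeyError(
                f"no enrichment value at position {position_kb} kb, t={time_h} h"
                + (f", locus {locus!r}" if locus else "")
            )
        return float(sel["enrichment"].iloc[0])


def chip_fold_enrichment(table: pd.DataFrame, *, percent_of_input: bool = False) -> EnrichmentMatrix:
    """Compute fold-enrichment from an IP/input ChIP table.

    E = [(IP/input)_locus,t / (IP/input)_control,t] / [same double ratio at
    t=0]; with ``percent_of_input`` the control-locus division is skipped and
    only the t=0 reference is applied. Replicates aggregated by geometric
    mean with min-max range.
    """
    df = table.copy()
    missing = [c for c in CHIP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ChIP table missing columns: {missing}")
    if (df["ip"] <= 0).any() or (df["input"] <= 0).any():
        raise ValueError("IP and input quantities must be > 0")
    df["time_h"] = df["time_h"].astype(float)
    df["ratio"] = df["ip"] / df["input"]

    per_rep_rows = []
    for rep, grp in df.groupby("replicate"):
        targets = grp[~grp["is_control"].astype(bool)]
        controls = grp[grp["is_control"].astype(bool)]
        if 0.0 not in set(grp["time_h"]):
            raise ValueError(f"replicate {rep}: no t=0 block")
        if not percent_of_input:
            if controls.empty:
                raise ValueError(f"replicate {rep}: control locus missing")
            ctrl_by_t = controls.groupby("time_h")["ratio"].apply(
                lambda v: float(np.exp(np.log(v).mean()))
            )
        for (locus, pos), series in targets.groupby(["locus", "position_kb"]):
            series = series.sort_values("time_h")
            times = series["time_h"].to_numpy()
            if 0.0 not in times:
                raise ValueError(f"replicate {rep}, locus {locus!r} pos {pos}: no t=0")
            r = series["ratio"].to_numpy(dtype=float)
            if not percent_of_input:
                missing_t = [t for t in times if t not in ctrl_by_t.index]
                if missing_t:
                    raise ValueError(
                        f"replicate {rep}: control locus missing at t={missing_t}"
                    )
                r = r / ctrl_by_t.loc[times].to_numpy(dtype=float)
            e = r / r[times == 0.0][0]
            for t, ev in zip(times, e):
                per_rep_rows.append((rep, locus, pos, t, ev))

    per_rep = pd.DataFrame(
        per_rep_rows, columns=["replicate", "locus", "position_kb", "time_h", "enrichment"]
    )
    agg = (
        per_rep.groupby(["locus", "position_kb", "time_h"])["enrichment"]
        .agg(
            enrichment=lambda v: float(np.exp(np.log(v).mean())),
            low="min",
            high="max",
        )
        .reset_index()
    )
    return EnrichmentMatrix(values=agg, per_replicate=per_rep)


def spreading_extent(matrix: EnrichmentMatrix, cutoff_fold: float = 2.0) -> pd.DataFrame:
    """Per-timepoint maximal |position| with enrichment >= cutoff.

    Grid positions only (no interpolation beyond the amplicon grid); a
    timepoint with no position above the cutoff gets extent 0. Returns a
    DataFrame with columns ``locus, time_h, extent_kb``.
    """
    if cutoff_fold <= 1:
        raise ValueError("cutoff_fold must be > 1")
    df = matrix.values
    if df["position_kb"].nunique() < 2 and len(df["position_kb"]) < 2:
        raise ValueError("need >=2 positions")
    rows = []
    for (locus, t), grp in df.groupby(["locus", "time_h"]):
        hot = grp[grp["enrichment"] >= cutoff_fold]
        extent = float(hot["position_kb"].abs().max()) if not hot.empty else 0.0
        rows.append((locus, t, extent))
    return pd.DataFrame(rows, columns=["locus", "time_h", "extent_kb"])


def persistence_ratio(
    matrix: EnrichmentMatrix,
    position_kb: float,
    time_h: float,
    *,
    locus: str | None = None,
    threshold_fold: float | None = None,
):
    """Fold over t=0 at a given position and time (E is already t0-relative).

    With ``threshold_fold`` set, returns ``(value, value >= threshold_fold)``
    for pass/fail reporting; otherwise just the value.
    """
    value = matrix.at(position_kb, time_h, locus=locus)
    if threshold_fold is not None:
        return value, bool(value >= threshold_fold)
    return value
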