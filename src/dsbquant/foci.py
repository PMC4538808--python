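"""Per-nucleus focus-count statistics and the Wilcoxon rank-sum test.

The rank-sum (Mann-Whitney) test is implemented here directly: exact
two-sided p by full enumeration of rank assignments for small pooled samples,
and the tie-corrected normal approximation with continuity correction
otherwise. Midranks are assigned over the pooled sample, so ties are handled
identically in both branches.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankSumResult",
    "summarize_foci",
    "fold_decrease",
    "rank_sum_test",
]

EXACT_LIMIT = 16  # full enumeration up to C(16, 8) = 12870 configurations


@dataclass
class RankSumResult:
    """Two-sample rank-sum test result.

    ``w`` is the rank sum of the smaller sample (ties in size: the first
    sample); ``u = w - n1(n1+1)/2`` is the Mann-Whitney statistic of that
    sample, in [0, n1*n2].
    """

    w: float
    u: float
    p_value: float
    method: str  # "exact" | "normal"
    n1: int
    n2: int
    tie_corrected: bool
    degenerate: bool = False


def summarize_foci(table: pd.DataFrame, *, k: int = 5) -> pd.DataFrame:
    """Per-condition x channel summary of focus counts pooled across experiments.

    Columns: n, mean, median, frac_ge_k (fraction of nuclei with >= k foci),
    plus per-experiment means in ``experiment_means``.
    """
    df = table.copy()
    for col in ("condition", "experiment", "count", "channel"):
        if col not in df.columns:
            raise ValueError(f"foci table missing column {col!r}")
    if df.empty:
        raise ValueError("empty foci table")
    counts = df["count"].to_numpy()
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("focus counts must be non-negative integers")

    rows = []
    for (cond, channel), grp in df.groupby(["condition", "channel"]):
        c = grp["count"].to_numpy(dtype=float)
        per_exp = grp.groupby("experiment")["count"].mean()
        rows.append(
            {
                "condition": cond,
                "channel": channel,
                "n": int(c.size),
                "mean": float(c.mean()),
                "median": float(np.median(c)),
                "frac_ge_k": float((c >= k).mean()),
                "k": k,
                "experiment_means": {int(e): float(m) for e, m in per_exp.items()},
            }
        )
    return pd.DataFrame(rows)


def fold_decrease(
    table: pd.DataFrame,
    reference_condition: str,
    treated_condition: str,
    *,
    channel: str | None = None,
) -> float:
    """Fold decrease in mean focus count: mean(reference) / mean(treated)."""
    df = table
    if channel is not None:
        df = df[df["channel"] == channel]
    ref = df.loc[df["condition"] == reference_condition, "count"]
    trt = df.loc[df["condition"] == treated_condition, "count"]
    if ref.empty or trt.empty:
        missing = reference_condition if ref.empty else treated_condition
        raise ValueError(f"condition {missing!r} absent from table")
    trt_mean = float(trt.mean())
    if trt_mean == 0:
        raise ValueError("treated mean is 0: fold decrease undefined (infinite)")
    return float(ref.mean()) / trt_mean


def _exact_tails(ranks: np.ndarray, n1: int, w_obs: float) -> tuple[float, float]:
    """P(W <= w_obs) and P(W >= w_obs) over all C(N, n1) rank assignments."""
    n = ranks.size
    total = comb(n, n1)
    le = ge = 0
    # tolerance guards float midranks (.5 steps) against roundoff
    eps = 1e-9
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if w <= w_obs + eps:
            le += 1
        if w >= w_obs - eps:
            ge += 1
    return le / total, ge / total


def rank_sum_test(x, y, method: str = "auto", alternative: str = "two-sided") -> RankSumResult:
    """Wilcoxon rank-sum test on two samples of counts.

    Midranks are assigned over the pooled sample. ``method="auto"`` uses
    exact enumeration when n1 + n2 <= 16 and the normal approximation with
    continuity correction and tie-corrected variance otherwise; ``"exact"``
    and ``"normal"`` force a branch. The two-sided p (default) doubles the
    smaller tail, capped at 1; ``alternative="greater"``/``"less"`` give the
    one-sided p that x tends greater/less than y.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    # W is the rank sum of the smaller sample (first sample on ties)
    if y.size < x.size:
        a, b, a_is_x = y, x, False
    else:
        a, b, a_is_x = x, y, True
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    degenerate = tie_counts.size == 1  # every pooled value identical

    if method == "auto":
        use_exact = n <= EXACT_LIMIT
    elif method == "exact":
        if n > 24:
            raise ValueError(f"exact enumeration refused for n1+n2={n} > 24")
        use_exact = True
    elif method == "normal":
        use_exact = False
    else:
        raise ValueError(f"unknown method {method!r}")

    if degenerate:
        return RankSumResult(
            w=w, u=u, p_value=1.0,
            method="exact" if use_exact else "normal",
            n1=n1, n2=n2, tie_corrected=has_ties, degenerate=True,
        )

    if use_exact:
        p_le, p_ge = _exact_tails(ranks, n1, w)
    else:
        mu = n1 * (n + 1) / 2.0
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return RankSumResult(
                w=w, u=u, p_value=1.0, method="normal",
                n1=n1, n2=n2, tie_corrected=has_ties, degenerate=True,
            )
        sd = np.sqrt(var)
        # continuity correction: 0.5 toward the tail being measured
        p_le = float(stats.norm.cdf((w - mu + 0.5) / sd))
        p_ge = float(stats.norm.sf((w - mu - 0.5) / sd))

    # "a greater" <=> large W of the a-sample
    p_a_greater, p_a_less = p_ge, p_le
    p_x_greater = p_a_greater if a_is_x else p_a_less
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif alternative == "greater":
        p = min(1.0, p_x_greater)
    else:
        p = min(1.0, (p_a_less if a_is_x else p_a_greater))
    return RankSumResult(
        w=w, u=u, p_value=p, method="exact" if use_exact else "normal",
        n1=n1, n2=n2, tie_corrected=has_ties,
    )
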