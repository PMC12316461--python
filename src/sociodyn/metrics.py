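"""Scalar behavioral measures: dominance, sociability, condition differences.

* Relative dominance: a subject's proportion of wins across round-robin
  tube-test contests over selected testing days.
* Social:object ratio: time on the social side of the three-chamber
  arena divided by time on the object side.
* ON-OFF difference: any metric under optical stimulation minus its
  unstimulated counterpart.
* Baseline correlation matrix: pairwise Pearson correlations across
  subjects of baseline behavioral measures.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "relative_dominance",
    "social_object_ratio",
    "on_off_difference",
    "baseline_correlation_matrix",
]


def relative_dominance(
    contests: pd.DataFrame,
    days: Sequence[int] | None = None,
) -> pd.Series:
    """Per-subject win proportion across tube-test contests.

    ``contests`` has columns ``day``, ``subject_a``, ``subject_b``,
    ``winner`` (values ``"a"`` or ``"b"``).  ``days`` restricts to a
    subset of testing days (e.g. the last 3-4).  Subjects with no contest
    in the window are absent from the result.
    """
    required = {"day", "subject_a", "subject_b", "winner"}
    missing = required - set(contests.columns)
    if missing:
        raise ValueError(f"contest table missing columns: {sorted(missing)}")
    if (contests["subject_a"] == contests["subject_b"]).any():
        raise ValueError("self-contest in table")
    bad = ~contests["winner"].isin(["a", "b"])
    if bad.any():
        raise ValueError("winner column must be 'a' or 'b'")
    df = contests if days is None else contests[contests["day"].isin(list(days))]

    wins: dict[str, int] = {}
    totals: dict[str, int] = {}
    for row in df.itertuples(index=False):
        a, b = row.subject_a, row.subject_b
        totals[a] = totals.get(a, 0) + 1
        totals[b] = totals.get(b, 0) + 1
        w = a if row.winner == "a" else b
        wins[w] = wins.get(w, 0) + 1
    scores = {s: wins.get(s, 0) / n for s, n in totals.items()}
    return pd.Series(scores, name="relative_dominance").sort_index()


def social_object_ratio(social_zone_s: float, object_zone_s: float) -> float:
    """Time on the social side divided by time on the object side."""
    if social_zone_s < 0 or object_zone_s < 0:
        raise ValueError("zone times must be nonnegative")
    if object_zone_s == 0:
        raise ValueError("zero object-zone time: ratio undefined")
    return social_zone_s / object_zone_s


def on_off_difference(metric_on: float, metric_off: float) -> float:
    """Stimulation-ON minus stimulation-OFF value of a metric."""
    return metric_on - metric_off


def baseline_correlation_matrix(measures: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of baseline behavioral measures.

    One row per subject, one column per measure; pairwise-complete
    observations.  Constant columns yield NaN rows/columns (flagged via a
    warning attribute would be overkill; callers can check for NaN).
    """
    num = measures.select_dtypes("number")
    if num.shape[1] < 2:
        raise ValueError("need at least two numeric measures")
    if len(num) < 3:
        raise ValueError("need at least three subjects")
    corr = num.corr(method="pearson")
    const = num.std(ddof=0) == 0
    for col in num.columns[const]:
        corr.loc[col, :] = np.nan
        corr.loc[:, col] = np.nan
    np.fill_diagonal(corr.values, np.where(const, np.nan, 1.0))
    return corr
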