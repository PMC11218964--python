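"""Group-level aggregation and comparison of per-nucleus ratio tables.

Results are exchanged as pandas DataFrames with one row per nucleus (the CSV
written by :func:`chromring.image_io.write_results`).  ``summarize`` reports
the mean ± SD convention; ``compare_groups`` runs a two-sided Welch t-test
(default) or Mann-Whitney U per ratio and bins p-values by the conventional
significance thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import RatioTable

__all__ = [
    "RATIO_COLUMNS",
    "GroupSummary",
    "ComparisonResult",
    "summarize",
    "compare_groups",
    "significance_bin",
]

RATIO_COLUMNS = list(RatioTable.names)

_BINS = ((1e-4, "p<=0.0001"), (1e-3, "p<=0.001"), (1e-2, "p<=0.01"), (5e-2, "p<=0.05"))


def significance_bin(p: float) -> str:
    for threshold, label in _BINS:
        if p <= threshold:
            return label
    return "ns"


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: pd.Series  # per ratio
    sd: pd.Series  # sample SD (n-1 denominator)

    def formatted(self) -> pd.Series:
        return pd.Series(
            {c: f"{self.mean[c]:.2f} ± {self.sd[c]:.2f}" for c in self.mean.index}
        )


def summarize(
    tables: pd.DataFrame, group_col: str = "group", columns: list[str] | None = None
) -> dict[str, GroupSummary]:
    """Per-group n / mean / sample-SD for each ratio column."""
    columns = columns or [c for c in RATIO_COLUMNS if c in tables.columns]
    if not columns:
        raise ValueError("no ratio columns found in the table")
    out: dict[str, GroupSummary] = {}
    for group, df in tables.groupby(group_col):
        if len(df) == 0:
            raise ValueError(f"empty group {group!r}")
        sub = df[columns].astype(float)
        out[str(group)] = GroupSummary(
            group=str(group),
            n=len(sub),
            mean=sub.mean(),
            sd=sub.std(ddof=1),
        )
    return out


@dataclass(frozen=True)
class ComparisonResult:
    ratio: str
    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float
    significance: str


def compare_groups(
    tables_a: pd.DataFrame,
    tables_b: pd.DataFrame,
    labels: tuple[str, str] = ("A", "B"),
    test: str = "welch_t",
    columns: list[str] | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Two-sided per-ratio comparison between two groups of nuclei.

    ``test``: ``welch_t`` (unequal-variance t) or ``mann_whitney``.  With
    ``holm=True`` p-values are Holm-adjusted across the ratios; the default
    reports unadjusted p-values.
    """
    if test not in ("welch_t", "mann_whitney"):
        raise ValueError(f"unknown test {test!r}")
    columns = columns or [c for c in RATIO_COLUMNS if c in tables_a.columns and c in tables_b.columns]
    if not columns:
        raise ValueError("no shared ratio columns between the two tables")
    rows = []
    for col in columns:
        a = tables_a[col].astype(float).to_numpy()
        b = tables_b[col].astype(float).to_numpy()
        if len(a) < 3 or len(b) < 3:
            raise ValueError(f"need n >= 3 per group for {col!r} (got {len(a)}, {len(b)})")
        if test == "welch_t":
            res = sps.ttest_ind(a, b, equal_var=False)
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "ratio": col,
                "group_a": labels[0],
                "group_b": labels[1],
                "test": test,
                "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
    df = pd.DataFrame(rows)
    if holm:
        order = np.argsort(df["p_value"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        df["p_value"] = adj
    df["significance"] = df["p_value"].map(significance_bin)
    return df
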