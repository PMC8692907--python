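"""Group-level aggregation and two-sample comparison of vessel metrics.

The unit of analysis is either the imaged location or the mouse: at the
``per_mouse`` level each mouse contributes the median of its locations'
per-image values, which avoids pseudo-replication when several fields of
view were scanned per animal.  Groups (e.g. wild-type vs VEGF-A
transgenic) are compared with an unpaired two-tailed t-test; Student's
pooled-variance form is the default and Welch's unequal-variance form is
available behind a flag.  Significance conventions: p < 0.05
(significant) and p < 0.001 (highly significant).  No multiple-testing
correction is applied across the vessel parameters; this is a
documented limitation of the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "aggregate", "compare_groups", "METRIC_COLUMNS"]

#: metric columns recognised by aggregate()
METRIC_COLUMNS = [
    "hb_content_au_per_mm2",
    "fill_fraction_pct",
    "vessel_count",
    "median_diameter_um",
    "median_tortuosity_deg_per_um",
]


@dataclass
class GroupComparison:
    """Result of comparing one vessel parameter between two groups."""

    parameter: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    p_value: float
    fold_change: float  # mean_b / mean_a
    test: str = "student"
    level: str = "per_location"
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    @property
    def highly_significant(self) -> bool:
        return self.p_value < 0.001

    def to_row(self) -> dict:
        return {
            "parameter": self.parameter,
            "group_a": self.group_a,
            "group_b": self.group_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "mean_a": self.mean_a,
            "sd_a": self.sd_a,
            "mean_b": self.mean_b,
            "sd_b": self.sd_b,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "fold_change": self.fold_change,
            "test": self.test,
            "level": self.level,
            "significant": self.significant,
            "highly_significant": self.highly_significant,
        }


def aggregate(records: pd.DataFrame, level: str = "per_location") -> pd.DataFrame:
    """Reduce a per-image metrics table to analysis units.

    ``per_location`` returns the table unchanged (one image per
    location is the expected layout).  ``per_mouse`` takes, per mouse,
    the median across that mouse's locations for every metric column
    present; medians ignore missing values and the number of
    contributing locations is reported as ``n_locations``.

    ``records`` is a per-image metrics DataFrame or a list of
    :class:`~vasoquant.metrics.MetricsRecord`; it must carry ``group``
    and, for per-mouse aggregation, ``mouse`` labels.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.to_row() for r in records])
    if level == "per_location":
        return records.copy()
    if level != "per_mouse":
        raise ValueError(f"unknown aggregation level {level!r}")
    if "mouse" not in records.columns or records["mouse"].isna().any() or (
        records["mouse"] == ""
    ).any():
        raise ValueError("per_mouse aggregation requires a complete 'mouse' column")
    if "group" not in records.columns:
        raise ValueError("records must carry a 'group' column")

    metric_cols = [c for c in METRIC_COLUMNS if c in records.columns]
    grouped = records.groupby(["group", "mouse"], sort=True)
    out = grouped[metric_cols].median()
    out["n_locations"] = grouped.size()
    return out.reset_index()


def compare_groups(
    table_a: pd.DataFrame | np.ndarray,
    table_b: pd.DataFrame | np.ndarray,
    parameter: str | None = None,
    group_a: str = "A",
    group_b: str = "B",
    welch: bool = False,
    level: str = "per_location",
) -> GroupComparison:
    """Unpaired two-tailed t-test between two groups of unit-level values.

    Accepts either aggregated tables (with ``parameter`` naming the
    column) or plain 1D value arrays.  Student's pooled-variance test is
    the default; pass ``welch=True`` for the unequal-variance form.
    Sample SDs use the n−1 denominator.  When both groups are constant
    and identical the test statistic is 0/0; the comparison is flagged
    degenerate and p is reported as 1.
    """
    a = _values(table_a, parameter)
    b = _values(table_b, parameter)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2 for a t-test")

    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))

    degenerate = sd_a == 0 and sd_b == 0 and mean_a == mean_b
    if degenerate:
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = sps.ttest_ind(a, b, equal_var=not welch)
        t_stat, p = float(t_stat), float(p)
        if np.isnan(p):  # zero pooled variance with distinct means
            p = 0.0

    return GroupComparison(
        parameter=parameter or "value",
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=mean_a,
        mean_b=mean_b,
        sd_a=sd_a,
        sd_b=sd_b,
        t_statistic=t_stat,
        p_value=p,
        fold_change=mean_b / mean_a if mean_a != 0 else float("nan"),
        test="welch" if welch else "student",
        level=level,
        degenerate=degenerate,
    )


def _values(table, parameter: str | None) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        if parameter is None:
            raise ValueError("parameter must name a column when passing a DataFrame")
        vals = table[parameter].to_numpy(dtype=float)
    else:
        vals = np.asarray(table, dtype=float)
    return vals[~np.isnan(vals)]


def compare_all_parameters(
    records: pd.DataFrame,
    group_a: str,
    group_b: str,
    level: str = "per_location",
    welch: bool = False,
) -> list[GroupComparison]:
    """Run :func:`compare_groups` for every metric column present."""
    agg = aggregate(records, level)
    sub_a = agg[agg["group"] == group_a]
    sub_b = agg[agg["group"] == group_b]
    out = []
    for col in METRIC_COLUMNS:
        if col not in agg.columns:
            continue
        if sub_a[col].notna().sum() < 2 or sub_b[col].notna().sum() < 2:
            continue
        out.append(
            compare_groups(
                sub_a, sub_b, parameter=col,
                group_a=group_a, group_b=group_b, welch=welch, level=level,
            )
        )
    return out
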