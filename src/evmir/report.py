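"""Headline summaries over a results table in the published-table schema.

These operate on any DataFrame carrying ``logfc``, ``auc`` and
``adj_p_value`` columns — the packaged published-results fixture or a
pipeline output — and reproduce the counts a study report quotes: how many
markers moved down vs up, how many classify above an AUC cut, the
fold-change range of the top markers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "count_by_direction",
    "count_auc_above",
    "abs_logfc_range",
    "max_adj_p",
    "summarize",
]


def count_by_direction(table: pd.DataFrame, logfc_col: str = "logfc") -> tuple[int, int]:
    """(n_down, n_up) by the sign of logFC; exact zeros count as neither."""
    logfc = table[logfc_col].to_numpy(float)
    if np.any(logfc == 0):
        warnings.warn("logFC values of exactly 0 count as neither up nor down")
    return int(np.sum(logfc < 0)), int(np.sum(logfc > 0))


def count_auc_above(table: pd.DataFrame, threshold: float, auc_col: str = "auc") -> int:
    """Number of rows with AUC strictly above the threshold."""
    return int((table[auc_col].to_numpy(float) > threshold).sum())


def abs_logfc_range(
    table: pd.DataFrame, subset_rule=None, logfc_col: str = "logfc"
) -> tuple[float, float]:
    """(min, max) of |logFC| over rows passing ``subset_rule`` (a boolean
    function of the table, or None for all rows)."""
    sub = table if subset_rule is None else table[subset_rule(table)]
    if len(sub) == 0:
        raise ValueError("subset rule selected no rows")
    a = sub[logfc_col].abs().to_numpy(float)
    return float(a.min()), float(a.max())


def max_adj_p(table: pd.DataFrame, col: str = "adj_p_value") -> float:
    if len(table) == 0:
        raise ValueError("empty table has no maximum adjusted p")
    return float(table[col].to_numpy(float).max())


def summarize(
    table: pd.DataFrame,
    auc_threshold: float = 0.9,
) -> dict:
    """Key-value headline report over a results table."""
    n_down, n_up = count_by_direction(table)
    out = {
        "n_rows": int(len(table)),
        "n_down": n_down,
        "n_up": n_up,
        "max_adj_p": max_adj_p(table),
        "min_abs_logfc": float(table["logfc"].abs().min()),
        "max_abs_logfc": float(table["logfc"].abs().max()),
    }
    if "auc" in table.columns:
        n_high = count_auc_above(table, auc_threshold)
        out["n_auc_above_threshold"] = n_high
        out["max_auc"] = float(table["auc"].max())
        if n_high:
            lo, hi = abs_logfc_range(table, lambda t: t["auc"] > auc_threshold)
            out["high_auc_min_abs_logfc"] = lo
            out["high_auc_max_abs_logfc"] = hi
    return out
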