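"""Summary arithmetic and descriptive statistics for reports and figures."""

from __future__ import annotations

import numpy as np
import pandas as pd


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded to ``ndigits`` decimals (as printed in reports)."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round(100.0 * numerator / denominator, ndigits)


def per_position_rate(total: int, n_positions: int) -> float:
    """Possible substitutions per residue position (e.g. unique single-
    nucleotide missense changes over protein length)."""
    if n_positions <= 0:
        raise ValueError("n_positions must be positive")
    return total / n_positions


def database_summary(counts: dict) -> dict:
    """Headline fractions of a variant database from its category counts.

    Expects keys: total_found, with_ep, total_possible_unique, n_positions,
    ep_changed, ep_unchanged, multi_report, multi_report_conflicting.
    """
    with_ep = counts["with_ep"]
    return {
        "pct_found_of_possible": percentage(
            counts["total_found"], counts["total_possible_unique"]),
        "pct_ep_of_possible": percentage(
            with_ep, counts["total_possible_unique"]),
        "pct_changed": percentage(counts["ep_changed"], with_ep, 0),
        "pct_unchanged": percentage(counts["ep_unchanged"], with_ep, 0),
        "pct_multi_conflicting": percentage(
            counts["multi_report_conflicting"], counts["multi_report"], 0),
        "possible_per_position": per_position_rate(
            counts["total_possible_unique"], counts["n_positions"]),
    }


def group_box_stats(frame: pd.DataFrame, value_col: str,
                    group_col: str) -> pd.DataFrame:
    """Box-plot statistics per group: median, quartiles, 1.5-IQR whisker
    bounds (clipped to observed data) and the sample mean."""
    rows = []
    for group, sub in frame.groupby(group_col, sort=True):
        v = np.asarray(sub[value_col], dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo = v[v >= q1 - 1.5 * iqr].min()
        hi = v[v <= q3 + 1.5 * iqr].max()
        rows.append([group, len(v), med, q1, q3, lo, hi, v.mean()])
    return pd.DataFrame(rows, columns=[
        group_col, "n", "median", "q1", "q3",
        "whisker_lo", "whisker_hi", "mean"])
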