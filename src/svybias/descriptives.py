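"""Sample descriptives: outcome cross-tabulations and a missingness screen.

Cross-tabulations report, per covariate level, the count and column
percentage of the non-missing sample and the count and within-level
percentage of events, together with a Pearson chi-square test of
independence (no continuity correction, matching standard
large-sample survey tabulation).  Variables with at least one third
missing values are screened out before modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = ["CrossTab", "crosstab_outcome", "pearson_chi_square", "screen_missingness"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CrossTab:
    variable: str
    table: pd.DataFrame  # columns: level, n, pct, events, event_pct
    overall: dict  # n, events, event_pct
    n_missing: int
    statistic: float
    df: int
    p_value: float


def _round_half_away(x: float, digits: int) -> float:
    """Round half away from zero (the convention of printed survey tables)."""
    factor = 10.0**digits
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


def pearson_chi_square(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a counts table.

    Returns ``(statistic, df, p)``; expected counts come from the
    row/column margins, with no continuity correction.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a 2-D table with at least 2 rows and 2 columns")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    stat, p, df, _ = chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def crosstab_outcome(data: pd.DataFrame, variable: str) -> CrossTab:
    """Level-by-outcome cross-tabulation for one covariate.

    Missing covariate values are excluded with a logged count; a
    single-level variable reproduces the overall row and carries a
    degenerate test (statistic 0, p 1).
    """
    if variable not in data.columns:
        raise ValueError(f"unknown variable {variable!r}")
    y = data["y"].to_numpy()
    if not np.isin(y[~pd.isna(y)], (0, 1)).all():
        raise ValueError("outcome must be binary 0/1")
    values = data[variable]
    missing = int(values.isna().sum())
    if missing:
        logger.info("crosstab %s: excluded %d missing values", variable, missing)
    sub = data.loc[~values.isna(), [variable, "y"]]
    total = len(sub)
    grouped = sub.groupby(variable, sort=False, observed=True)["y"].agg(["size", "sum"])
    table = pd.DataFrame(
        {
            "level": grouped.index.astype(str),
            "n": grouped["size"].to_numpy(int),
            "events": grouped["sum"].to_numpy(int),
        }
    )
    table["pct"] = [_round_half_away(100.0 * n / total, 1) for n in table["n"]]
    table["event_pct"] = [
        _round_half_away(100.0 * e / n, 1) for e, n in zip(table["events"], table["n"])
    ]
    table = table[["level", "n", "pct", "events", "event_pct"]]
    overall = {
        "n": int(total),
        "events": int(table["events"].sum()),
        "event_pct": _round_half_away(100.0 * table["events"].sum() / total, 1),
    }
    if len(table) < 2:
        stat, df, p = 0.0, 0, 1.0
    else:
        counts = np.column_stack(
            [table["events"], table["n"] - table["events"]]
        )
        stat, df, p = pearson_chi_square(counts)
    return CrossTab(
        variable=variable,
        table=table,
        overall=overall,
        n_missing=missing,
        statistic=stat,
        df=df,
        p_value=p,
    )


def screen_missingness(
    data: pd.DataFrame, variables: list[str], threshold: float = 1.0 / 3.0
) -> tuple[list[str], pd.DataFrame]:
    """Drop variables whose missing fraction reaches the threshold.

    "At least one third missing" is inclusive at the boundary: a
    variable with exactly ``threshold`` missing is dropped.  Returns
    the kept variable names and a report of all rates (3 dp).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    rows = []
    kept = []
    for name in variables:
        if name not in data.columns:
            raise ValueError(f"unknown variable {name!r}")
        rate = float(data[name].isna().mean())
        dropped = rate >= threshold
        rows.append(
            {"variable": name, "missing_rate": round(rate, 3), "dropped": dropped}
        )
        if not dropped:
            kept.append(name)
    return kept, pd.DataFrame(rows)
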