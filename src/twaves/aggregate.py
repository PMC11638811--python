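"""Collapse per-window wave power to the units of statistical analysis.

The chain is: per-trial window series -> retention-interval average per
trial -> mean (or median) across trials per participant x condition x
axis-role x direction x band cell -> optional pooling of subexperiments.
Window membership in an interval is decided by the window *center* lying in
the closed interval.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RETENTION_WINDOWS",
    "average_retention",
    "aggregate_trials",
    "pool_conditions",
]

#: Retention-period analysis intervals (s) for the two study layouts.
RETENTION_WINDOWS: dict[str, tuple[float, float]] = {
    "DS1": (0.200, 1.200),
    "DS2": (0.250, 1.550),
}

#: The grouping key of a condition cell (whatever subset is present is used).
CELL_KEYS = ["participant", "experiment", "arrangement", "load", "set_size",
             "side", "axis", "axis_role", "band", "direction"]


def _present_keys(df: pd.DataFrame, extra_exclude: Sequence[str] = ()) -> list[str]:
    return [k for k in CELL_KEYS if k in df.columns and k not in extra_exclude]


def average_retention(series: pd.DataFrame, window: tuple[float, float]) -> pd.DataFrame:
    """Average window values whose center lies in the closed interval.

    ``series`` is a long table with a ``window_time`` column and a ``db``
    value column; the mean is taken per trial (and any other key columns
    present).  An interval containing no window center is rejected.
    """
    t0, t1 = window
    mask = (series["window_time"] >= t0) & (series["window_time"] <= t1)
    if not mask.any():
        raise ValueError(f"no window centers inside [{t0}, {t1}] s")
    sub = series.loc[mask]
    keys = ["trial"] + _present_keys(sub)
    out = sub.groupby(keys, sort=False, observed=True, dropna=False)["db"] \
        .mean().reset_index()
    return out


def aggregate_trials(cells: pd.DataFrame, statistic: str = "mean") -> pd.DataFrame:
    """Collapse trials to one value per condition cell.

    ``statistic`` is "mean" or "median" (the latter is the robustness
    variant).  Cells with no trials are not silently dropped: if the input
    carries a categorical condition structure, missing combinations remain
    absent from the output and downstream layout validation flags them.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    if cells.empty:
        raise ValueError("no trials to aggregate")
    keys = _present_keys(cells)
    if not keys:
        raise ValueError("no grouping columns found")
    grouped = cells.groupby(keys, sort=False, observed=True, dropna=False)["db"]
    out = (grouped.mean() if statistic == "mean" else grouped.median()).reset_index()
    out["statistic"] = statistic
    out = out.rename(columns={"db": "value"})
    return out


def pool_conditions(
    tables: Mapping[str, pd.DataFrame] | Iterable[tuple[str, pd.DataFrame]],
    scheme: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame | dict[str, pd.DataFrame]:
    """Pool subexperiment tables by shared condition vocabulary.

    ``tables`` maps experiment tag -> cell table; participants are tagged by
    their source experiment.  With ``scheme = None`` the pooled table is
    returned.  Otherwise ``scheme`` maps analysis name -> list of experiment
    tags to retain for it (a full-factorial analysis only includes the
    experiments that ran all factor levels) and a dict of filtered tables is
    returned.  Conflicting condition vocabularies are rejected.
    """
    items = list(tables.items()) if isinstance(tables, Mapping) else list(tables)
    tagged = []
    vocab: dict[str, set] = {}
    for tag, df in items:
        df = df.copy()
        df["experiment"] = tag
        for col in ("arrangement", "band", "direction", "axis_role"):
            if col in df.columns:
                vals = set(df[col].dropna().unique())
                prev = vocab.setdefault(col, vals)
                if not (vals <= prev or prev <= vals):
                    raise ValueError(
                        f"conflicting {col!r} labels across experiments: "
                        f"{sorted(prev)} vs {sorted(vals)}"
                    )
                vocab[col] = prev | vals
        tagged.append(df)
    pooled = pd.concat(tagged, ignore_index=True) if tagged else pd.DataFrame()
    if scheme is None:
        return pooled
    out = {}
    for analysis, tags in scheme.items():
        out[analysis] = pooled[pooled["experiment"].isin(list(tags))].reset_index(drop=True)
    return out


def validate_factorial(cells: pd.DataFrame, factors: Sequence[str],
                       value_col: str = "value") -> pd.DataFrame:
    """Check a complete within-participant factorial layout.

    Returns the table sorted by participant and factors; raises with the
    missing cells named if the layout is incomplete (missing cells are
    explicit, never imputed).
    """
    idx_cols = ["participant", *factors]
    counts = cells.groupby(idx_cols, observed=True).size()
    participants = cells["participant"].unique()
    level_sets = [cells[f].unique() for f in factors]
    full = pd.MultiIndex.from_product([participants, *level_sets], names=idx_cols)
    missing = full.difference(counts.index)
    if len(missing):
        raise ValueError(f"incomplete factorial layout; missing cells: "
                         f"{list(missing[:5])}{'...' if len(missing) > 5 else ''}")
    if (counts > 1).any():
        raise ValueError("duplicate condition cells; aggregate trials first")
    return cells.sort_values(idx_cols).reset_index(drop=True)
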