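"""Sampling-effort experiment: plot-subset enumeration and turnover recomputation.

Sampling effort is varied by recomputing the weekly turnover series on
every non-empty subset of survey plots (for six plots, all 63 subsets,
covering subset sizes one through six).  Because the minimum-richness
filter is applied per subset, smaller subsets may retain fewer survey
rounds than larger ones.  Results are aggregated as arithmetic means of
the three dissimilarity components within (subset size, year, week pair,
method) groups — the observations used by the effort regressions.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .records import InteractionRecord, filter_min_richness, pool_networks
from .turnover import METHODS, Method, series_to_frame, turnover_series

#: Guard against accidental 2^n blow-ups on user data.
MAX_PLOTS_DEFAULT = 12

EFFORT_ROW_COLUMNS = [
    "n_plots",
    "subset_id",
    "year",
    "week_pair",
    "day_mid",
    "gap_days",
    "method",
    "beta_wn",
    "beta_os",
    "beta_st",
    "degenerate_os",
]


def subset_id(plots: Iterable[str]) -> str:
    """Canonical identifier of a plot subset: sorted labels joined with '+'."""
    return "+".join(sorted(str(p) for p in plots))


def enumerate_subsets(
    plots: Iterable[str],
    max_plots: int = MAX_PLOTS_DEFAULT,
) -> list[frozenset[str]]:
    """All non-empty subsets of the plot set, ordered by size then lexicographically."""
    unique = sorted(set(str(p) for p in plots))
    if not unique:
        raise ValueError("plot set must be non-empty")
    if len(unique) > max_plots:
        raise ValueError(
            f"{len(unique)} plots would give {2 ** len(unique) - 1} subsets; "
            f"raise max_plots (currently {max_plots}) to proceed"
        )
    out: list[frozenset[str]] = []
    for k in range(1, len(unique) + 1):
        for combo in combinations(unique, k):
            out.append(frozenset(combo))
    return out


def effort_analysis(
    records: Sequence[InteractionRecord],
    plots: Iterable[str] | None = None,
    min_plants: int = 3,
    min_pollinators: int = 3,
    methods: Iterable[Method] = METHODS,
    max_plots: int = MAX_PLOTS_DEFAULT,
) -> pd.DataFrame:
    """Recompute the turnover series on every plot subset.

    Returns a tidy table with one row per (subset, year, week pair,
    method).  Subsets that retain fewer than two networks in a year
    contribute no rows for that year.  ``plots`` defaults to every plot
    appearing in the records.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if plots is None:
        plots = {r.plot for r in records}
    methods = tuple(methods)

    frames = []
    for subset in enumerate_subsets(plots, max_plots=max_plots):
        networks = pool_networks(records, subset)
        series_by_year = filter_min_richness(networks, min_plants, min_pollinators)
        for year in sorted(series_by_year):
            series = series_by_year[year]
            if len(series) < 2:
                continue
            frame = series_to_frame(turnover_series(series, methods))
            if frame.empty:
                continue
            frame.insert(0, "n_plots", len(subset))
            frame.insert(1, "subset_id", subset_id(subset))
            frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=EFFORT_ROW_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out[EFFORT_ROW_COLUMNS + [c for c in out.columns if c not in EFFORT_ROW_COLUMNS]]


def aggregate_effort(rows: pd.DataFrame, drop_degenerate: bool = False) -> pd.DataFrame:
    """Mean dissimilarities over subsets within (n_plots, year, week_pair, method).

    ``day_mid`` is averaged over the contributing subsets (their pooled
    networks can carry representative days one apart when a plot was
    surveyed a day late).  With ``drop_degenerate`` the rows whose
    rewiring component was undefined (no shared-species links; recorded
    as 0) are excluded from the beta_os and beta_st means, never from
    beta_wn.
    """
    if rows.empty:
        raise ValueError("no effort rows to aggregate")
    keys = ["n_plots", "year", "week_pair", "method"]
    grouped = rows.groupby(keys, sort=True)
    agg = grouped.agg(
        day_mid=("day_mid", "mean"),
        beta_wn=("beta_wn", "mean"),
        n_subsets=("subset_id", "nunique"),
        n_degenerate=("degenerate_os", "sum"),
    ).reset_index()
    if drop_degenerate:
        ok = rows[~rows["degenerate_os"].astype(bool)]
        comp = ok.groupby(keys)[["beta_os", "beta_st"]].mean().reset_index()
        agg = agg.merge(comp, on=keys, how="left")
    else:
        comp = grouped[["beta_os", "beta_st"]].mean().reset_index()
        agg = agg.merge(comp, on=keys, how="left")
    cols = keys + ["day_mid", "beta_wn", "beta_os", "beta_st", "n_subsets", "n_degenerate"]
    return agg[cols].sort_values(keys, kind="mergesort").reset_index(drop=True)


def grand_means_by_effort(agg: pd.DataFrame) -> pd.DataFrame:
    """Grand mean of each component per (n_plots, method), across years and weeks."""
    return (
        agg.groupby(["method", "n_plots"], sort=True)[["beta_wn", "beta_os", "beta_st"]]
        .mean()
        .reset_index()
    )
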