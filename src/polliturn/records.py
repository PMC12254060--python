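"""Interaction records and weekly bipartite network assembly.

The raw unit of observation is one plant-pollinator visit event recorded
during a timed plot survey.  Records are pooled into one bipartite network
per survey round (year, week), optionally restricted to a subset of plots,
and a minimum-richness filter keeps only networks with enough plant and
pollinator species to make pairwise dissimilarity meaningful.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

RECORD_COLUMNS = ("year", "ordinal_day", "week_index", "plot", "plant", "pollinator", "count")

#: Default mapping from record fields to input-file column names.
DEFAULT_COLUMN_MAP = {
    "year": "year",
    "ordinal_day": "ordinal_day",
    "week_index": "week",
    "plot": "plot",
    "plant": "plant",
    "pollinator": "pollinator",
    "count": "count",
}


@dataclass(frozen=True)
class InteractionRecord:
    """One observed visit: a pollinator on a plant, in a plot, on a day.

    ``week_index`` is the survey round within the year and is authoritative
    for grouping; a round may span adjacent calendar days across plots.
    Taxon labels are opaque strings (genus-level identifications are
    treated as species-level units).
    """

    year: int
    ordinal_day: int
    week_index: int
    plot: str
    plant: str
    pollinator: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if not 1 <= self.ordinal_day <= 366:
            raise ValueError(f"ordinal_day out of calendar range: {self.ordinal_day}")


@dataclass(frozen=True)
class InteractionNetwork:
    """A pooled bipartite network for one survey round.

    ``links`` maps (plant, pollinator) to the summed visit count over the
    contributing records.  Species sets are derived from the links, so no
    unlinked species can appear.  ``ordinal_day`` is the representative day
    of the round: the minimum day among contributing records.
    """

    year: int
    week_index: int
    ordinal_day: int
    plots_included: frozenset[str]
    links: Mapping[tuple[str, str], int]

    @property
    def plants(self) -> frozenset[str]:
        return frozenset(p for p, _ in self.links)

    @property
    def pollinators(self) -> frozenset[str]:
        return frozenset(i for _, i in self.links)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.links.values()):
            raise ValueError("all link counts must be >= 1")


@dataclass
class NetworkSeries:
    """Retained weekly networks of one year, ascending by week, plus the exclusion log."""

    year: int
    networks: list[InteractionNetwork]
    excluded: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        weeks = [n.week_index for n in self.networks]
        if weeks != sorted(set(weeks)):
            raise ValueError("networks must have strictly increasing week_index")

    def __len__(self) -> int:
        return len(self.networks)


@dataclass
class IngestReport:
    """Bookkeeping from :func:`read_records`."""

    n_rows: int
    n_kept: int
    n_dropped_missing_taxon: int


def read_records(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> tuple[list[InteractionRecord], IngestReport]:
    """Read a delimited long-format record table.

    The file must be UTF-8 text with a header row; comma or tab delimiters
    are auto-detected unless ``delimiter`` is given.  Rows with a missing
    plant or pollinator label are dropped and counted in the report.  A
    missing mapped column or a non-numeric count is a hard error naming
    the offending column or row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    if delimiter is None:
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
        delimiter = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","

    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False, encoding="utf-8")
    missing_cols = [col for col in cmap.values() if col not in df.columns]
    if missing_cols:
        raise ValueError(f"mapped column(s) not found in {path.name}: {missing_cols}")

    records: list[InteractionRecord] = []
    n_dropped = 0
    for idx, row in enumerate(df.to_dict("records"), start=2):  # header is line 1
        raw = {f: row[cmap[f]] for f in RECORD_COLUMNS}
        if str(raw["plant"]).strip() == "" or str(raw["pollinator"]).strip() == "":
            n_dropped += 1
            continue
        try:
            count = int(raw["count"])
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric count {raw['count']!r} at line {idx} of {path.name}"
            ) from None
        records.append(
            InteractionRecord(
                year=int(raw["year"]),
                ordinal_day=int(raw["ordinal_day"]),
                week_index=int(raw["week_index"]),
                plot=str(raw["plot"]),
                plant=str(raw["plant"]),
                pollinator=str(raw["pollinator"]),
                count=count,
            )
        )
    report = IngestReport(n_rows=len(df), n_kept=len(records), n_dropped_missing_taxon=n_dropped)
    return records, report


def write_records(records: Iterable[InteractionRecord], path: str | Path, delimiter: str = ",") -> None:
    """Write records as a delimited table with the default column names."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(DEFAULT_COLUMN_MAP[f] for f in RECORD_COLUMNS)
        for r in records:
            writer.writerow(
                [r.year, r.ordinal_day, r.week_index, r.plot, r.plant, r.pollinator, r.count]
            )


def records_to_frame(records: Iterable[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=list(RECORD_COLUMNS))


def pool_networks(
    records: Sequence[InteractionRecord],
    plot_subset: Iterable[str],
) -> dict[tuple[int, int], InteractionNetwork]:
    """Pool records over a plot subset into one network per (year, week).

    Link counts are summed over all records matching the round and subset;
    rounds with no matching records produce no network.
    """
    subset = frozenset(plot_subset)
    if not subset:
        raise ValueError("plot_subset must be non-empty")

    links: dict[tuple[int, int], dict[tuple[str, str], int]] = {}
    days: dict[tuple[int, int], int] = {}
    plots_seen: dict[tuple[int, int], set[str]] = {}
    for r in records:
        if r.plot not in subset:
            continue
        key = (r.year, r.week_index)
        bucket = links.setdefault(key, {})
        bucket[(r.plant, r.pollinator)] = bucket.get((r.plant, r.pollinator), 0) + r.count
        days[key] = min(days.get(key, r.ordinal_day), r.ordinal_day)
        plots_seen.setdefault(key, set()).add(r.plot)

    return {
        key: InteractionNetwork(
            year=key[0],
            week_index=key[1],
            ordinal_day=days[key],
            plots_included=frozenset(plots_seen[key]),
            links=bucket,
        )
        for key, bucket in sorted(links.items())
    }


def filter_min_richness(
    networks: Mapping[tuple[int, int], InteractionNetwork],
    min_plants: int = 3,
    min_pollinators: int = 3,
) -> dict[int, NetworkSeries]:
    """Keep networks with at least ``min_plants`` plant and ``min_pollinators``
    pollinator species; return per-year ordered series with an exclusion log."""
    if min_plants < 1 or min_pollinators < 1:
        raise ValueError("richness thresholds must be >= 1")
    by_year: dict[int, NetworkSeries] = {}
    for (year, week), net in sorted(networks.items()):
        series = by_year.setdefault(year, NetworkSeries(year=year, networks=[]))
        n_pl, n_po = len(net.plants), len(net.pollinators)
        if n_pl >= min_plants and n_po >= min_pollinators:
            series.networks.append(net)
        else:
            series.excluded.append(
                (week, f"{n_pl} plants, {n_po} pollinators (need >= {min_plants}x{min_pollinators})")
            )
    return by_year


def networks_to_edgelist(
    networks: Mapping[tuple[int, int], InteractionNetwork]
) -> pd.DataFrame:
    """Tidy edge-list export: one row per (year, week, plant, pollinator, count)."""
    rows = []
    for (year, week), net in sorted(networks.items()):
        for (plant, poll), count in sorted(net.links.items()):
            rows.append(
                {
                    "year": year,
                    "week": week,
                    "ordinal_day": net.ordinal_day,
                    "plant": plant,
                    "pollinator": poll,
                    "count": count,
                }
            )
    return pd.DataFrame(
        rows, columns=["year", "week", "ordinal_day", "plant", "pollinator", "count"]
    )
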