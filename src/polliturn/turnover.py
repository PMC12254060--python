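"""Pairwise network dissimilarity and its rewiring / species-turnover partition.

Interaction turnover between two bipartite networks is measured with
Whittaker's pairwise dissimilarity (equivalently the Sørensen dissimilarity)
on binary link sets,

    beta_WN = (b + c) / (2a + b + c),

where ``a`` is the number of links shared by both networks and ``b``, ``c``
are the numbers of links unique to the first and second network.  beta_WN is
split additively into a rewiring component ``beta_OS`` (dissimilarity of
interactions among species present in both networks) and a species-turnover
component ``beta_ST`` (links involving species gained or lost), under two
schemes in common use:

``poisot``
    beta_OS is the Whittaker dissimilarity of the shared-species
    subnetworks, computed with its own denominator
    ``(b_os + c_os) / (2a + b_os + c_os)``; beta_ST is obtained by
    subtraction, ``beta_WN - beta_OS``.

``commondenom``
    both components keep the denominator of beta_WN and only the numerator
    is split: ``beta_OS = (b_os + c_os) / (2a + b + c)`` and
    ``beta_ST = (b_st + c_st) / (2a + b + c)``.  Because the numerators are
    equal but the denominator is never smaller, commondenom rewiring is
    always less than or equal to poisot rewiring.

A link counts toward the rewiring (OS) side only when both its plant and
its pollinator occur, with at least one link, in both networks; shared
status is evaluated per guild.  All dissimilarities are computed on link
presence/absence; counts in the data model are ignored here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import pandas as pd

from .records import InteractionNetwork, NetworkSeries

Method = Literal["poisot", "commondenom"]
METHODS: tuple[Method, ...] = ("poisot", "commondenom")

#: Additivity of the partition (beta_os + beta_st == beta_wn) is enforced
#: to this absolute tolerance.
ADDITIVITY_TOL = 1e-12


@dataclass(frozen=True)
class LinkClassification:
    """Counts of union links classified by sharing and species overlap.

    ``a`` links present in both networks; ``b_*`` unique to network 1,
    ``c_*`` unique to network 2, with the ``_os`` part having both
    endpoints shared between the networks and ``_st`` the remainder.
    """

    a: int
    b_os: int
    b_st: int
    c_os: int
    c_st: int

    @property
    def b(self) -> int:
        return self.b_os + self.b_st

    @property
    def c(self) -> int:
        return self.c_os + self.c_st

    def __post_init__(self) -> None:
        if min(self.a, self.b_os, self.b_st, self.c_os, self.c_st) < 0:
            raise ValueError("link-classification counts must be non-negative")


@dataclass(frozen=True)
class TurnoverResult:
    """One pairwise partition: beta_WN = beta_ST + beta_OS."""

    beta_wn: float
    beta_os: float
    beta_st: float
    method: Method
    classification: LinkClassification
    shared_plants: int
    shared_pollinators: int
    degenerate_os: bool = False


@dataclass(frozen=True)
class TurnoverSeriesRow:
    """Turnover of one consecutive week pair, all methods attached."""

    year: int
    week_pair: tuple[int, int]
    day_mid: float
    gap_days: int
    results: dict[Method, TurnoverResult] = field(hash=False)


def classify_links(net1: InteractionNetwork, net2: InteractionNetwork) -> LinkClassification:
    """Classify every link of the union of two binarized link sets.

    Raises ``ValueError`` on an empty network: with no links there is no
    species set and the partition is undefined.
    """
    links1, links2 = set(net1.links), set(net2.links)
    if not links1 or not links2:
        raise ValueError("cannot classify links of an empty network")
    shared_plants = net1.plants & net2.plants
    shared_polls = net1.pollinators & net2.pollinators

    def both_shared(link: tuple[str, str]) -> bool:
        return link[0] in shared_plants and link[1] in shared_polls

    a = len(links1 & links2)
    b_only = links1 - links2
    c_only = links2 - links1
    b_os = sum(1 for lk in b_only if both_shared(lk))
    c_os = sum(1 for lk in c_only if both_shared(lk))
    return LinkClassification(
        a=a,
        b_os=b_os,
        b_st=len(b_only) - b_os,
        c_os=c_os,
        c_st=len(c_only) - c_os,
    )


def whittaker(a: int, b: int, c: int) -> float:
    """Pairwise Whittaker (Sørensen) dissimilarity (b + c) / (2a + b + c)."""
    if a < 0 or b < 0 or c < 0:
        raise ValueError("set counts must be non-negative")
    denom = 2 * a + b + c
    if denom == 0:
        raise ValueError("whittaker dissimilarity undefined for a = b = c = 0")
    return (b + c) / denom


def partition(
    net1: InteractionNetwork,
    net2: InteractionNetwork,
    method: Method,
) -> TurnoverResult:
    """Partition the pairwise dissimilarity of two networks.

    When the pair shares no possible link among shared species
    (``a = b_os = c_os = 0``) the rewiring component has an empty or
    undefined denominator under either scheme; it is defined as 0 and the
    result is flagged ``degenerate_os`` so downstream aggregation can
    exclude such pairs if desired.  This keeps additivity:
    beta_ST then equals beta_WN.
    """
    if method not in METHODS:
        raise ValueError(f"unknown partition method: {method!r}")
    cls = classify_links(net1, net2)
    beta_wn = whittaker(cls.a, cls.b, cls.c)

    degenerate = cls.a == 0 and cls.b_os == 0 and cls.c_os == 0
    if degenerate:
        beta_os = 0.0
    elif method == "poisot":
        beta_os = (cls.b_os + cls.c_os) / (2 * cls.a + cls.b_os + cls.c_os)
    else:  # commondenom
        beta_os = (cls.b_os + cls.c_os) / (2 * cls.a + cls.b + cls.c)

    if method == "poisot":
        beta_st = beta_wn - beta_os
    else:
        beta_st = (cls.b_st + cls.c_st) / (2 * cls.a + cls.b + cls.c)

    assert abs((beta_st + beta_os) - beta_wn) <= ADDITIVITY_TOL
    return TurnoverResult(
        beta_wn=beta_wn,
        beta_os=beta_os,
        beta_st=beta_st,
        method=method,
        classification=cls,
        shared_plants=len(net1.plants & net2.plants),
        shared_pollinators=len(net1.pollinators & net2.pollinators),
        degenerate_os=degenerate,
    )


def turnover_series(
    series: NetworkSeries,
    methods: Iterable[Method] = METHODS,
) -> list[TurnoverSeriesRow]:
    """Partition every consecutive pair of a within-year network series.

    Consecutive retained networks are paired even when an intervening
    survey round was excluded by the richness filter; the day gap of each
    pair is recorded so callers can drop long-gap pairs.  The ordinal day
    attached to a pair is the midpoint of the two networks' representative
    days.
    """
    methods = tuple(methods)
    if len(series.networks) < 2:
        warnings.warn(
            f"network series for year {series.year} has fewer than 2 networks; "
            "no turnover can be computed",
            stacklevel=2,
        )
        return []
    rows = []
    for n1, n2 in zip(series.networks, series.networks[1:]):
        rows.append(
            TurnoverSeriesRow(
                year=series.year,
                week_pair=(n1.week_index, n2.week_index),
                day_mid=(n1.ordinal_day + n2.ordinal_day) / 2.0,
                gap_days=n2.ordinal_day - n1.ordinal_day,
                results={m: partition(n1, n2, m) for m in methods},
            )
        )
    return rows


def series_to_frame(rows: Iterable[TurnoverSeriesRow]) -> pd.DataFrame:
    """Tidy long-format table of a turnover series, one row per (pair, method)."""
    out = []
    for row in rows:
        for method, res in row.results.items():
            cls = res.classification
            out.append(
                {
                    "year": row.year,
                    "week_pair": f"{row.week_pair[0]}-{row.week_pair[1]}",
                    "day_mid": row.day_mid,
                    "gap_days": row.gap_days,
                    "method": method,
                    "beta_wn": res.beta_wn,
                    "beta_os": res.beta_os,
                    "beta_st": res.beta_st,
                    "a": cls.a,
                    "b_os": cls.b_os,
                    "b_st": cls.b_st,
                    "c_os": cls.c_os,
                    "c_st": cls.c_st,
                    "degenerate_os": res.degenerate_os,
                }
            )
    return pd.DataFrame(out)
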