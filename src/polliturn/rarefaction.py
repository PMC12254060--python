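"""Sample-based (incidence) richness accumulation and Chao2 extrapolation.

Richness of plants, pollinators and unique links is interpolated over the
number of pooled sampling units (plots by default) with the standard
incidence-based rarefaction formula

    S(t) = S_obs - sum_i C(T - Y_i, t) / C(T, t),

where Y_i is the number of units in which entity i occurs, and
extrapolated beyond the observed T units toward the Chao2 asymptote

    S_hat = S_obs + ((T - 1) / T) * Q1^2 / (2 * Q2),

(Q1, Q2 = entities found in exactly one / two units; the bias-corrected
form Q1 (Q1 - 1) / (2 (Q2 + 1)) is used when Q2 = 0) with the standard
exponential approach from S_obs toward S_hat.  Binomial coefficients are
evaluated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .records import InteractionRecord

Unit = Literal["plot", "survey"]
ENTITY_CLASSES = ("plants", "pollinators", "links")


@dataclass(frozen=True)
class IncidenceData:
    """Incidence frequencies for one entity class over T sampling units."""

    T: int
    incidence: tuple[int, ...]  # Y_i per entity, 1 <= Y_i <= T

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("need at least one sampling unit")
        if any(not 1 <= y <= self.T for y in self.incidence):
            raise ValueError("incidence counts must satisfy 1 <= Y_i <= T")

    @property
    def s_obs(self) -> int:
        return len(self.incidence)

    @property
    def q1(self) -> int:
        return sum(1 for y in self.incidence if y == 1)

    @property
    def q2(self) -> int:
        return sum(1 for y in self.incidence if y == 2)


def build_incidence(
    records: Sequence[InteractionRecord],
    unit: Unit = "plot",
) -> dict[str, IncidenceData]:
    """Incidence vectors for plants, pollinators and links.

    A sampling unit is either a plot (pooled over all surveys; the effort
    axis of the plot-subsampling experiment) or a single (year, week, plot)
    survey.
    """
    if not records:
        raise ValueError("records must be non-empty")

    def unit_key(r: InteractionRecord):
        return r.plot if unit == "plot" else (r.year, r.week_index, r.plot)

    units = sorted({unit_key(r) for r in records}, key=str)
    T = len(units)
    membership: dict[str, dict[object, set]] = {c: {} for c in ENTITY_CLASSES}
    for r in records:
        u = unit_key(r)
        membership["plants"].setdefault(r.plant, set()).add(u)
        membership["pollinators"].setdefault(r.pollinator, set()).add(u)
        membership["links"].setdefault((r.plant, r.pollinator), set()).add(u)
    return {
        cls: IncidenceData(
            T=T, incidence=tuple(sorted(len(us) for us in members.values()))
        )
        for cls, members in membership.items()
    }


def _log_choose(n: np.ndarray | int, k: int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    return gammaln(n + 1) - gammaln(np.maximum(n - k, 0) + 1) - gammaln(k + 1)


def rarefy_incidence(data: IncidenceData, t: int) -> float:
    """Expected richness when t of the T units are pooled (1 <= t <= T)."""
    if t < 1:
        raise ValueError("t must be >= 1")
    if t > data.T:
        raise ValueError("t exceeds the number of observed units; use chao2_extrapolate")
    if t == data.T:
        return float(data.s_obs)
    y = np.asarray(data.incidence)
    # P(entity i absent from all t chosen units) = C(T - Y_i, t) / C(T, t)
    feasible = (data.T - y) >= t
    log_p_absent = _log_choose(data.T - y[feasible], t) - _log_choose(data.T, t)
    return float(data.s_obs - np.exp(log_p_absent).sum())


def chao2(data: IncidenceData) -> float:
    """Chao2 asymptotic richness estimate from singletons and doubletons."""
    T, q1, q2 = data.T, data.q1, data.q2
    if q2 > 0:
        q0 = (T - 1) / T * q1 * q1 / (2 * q2)
    else:
        q0 = (T - 1) / T * q1 * (q1 - 1) / 2.0
    return data.s_obs + q0


def chao2_extrapolate(data: IncidenceData, t: int) -> float:
    """Expected richness at t > T pooled units.

    Rises exponentially from S_obs toward the Chao2 asymptote:
    S(T + t*) = S_obs + Q0_hat * (1 - (1 - Q1 / (Q1 + T * Q0_hat))^t*).
    """
    if t <= data.T:
        raise ValueError("extrapolation requires t > T; use rarefy_incidence")
    q0_hat = chao2(data) - data.s_obs
    if q0_hat <= 0 or data.q1 == 0:
        return float(data.s_obs)
    t_star = t - data.T
    rate = data.q1 / (data.q1 + data.T * q0_hat)
    return float(data.s_obs + q0_hat * (1.0 - (1.0 - rate) ** t_star))


def accumulation_curve(
    data: IncidenceData,
    t_max: int | None = None,
) -> pd.DataFrame:
    """Interpolated and extrapolated richness for t = 1 .. t_max (default 2T)."""
    t_max = 2 * data.T if t_max is None else t_max
    rows = []
    for t in range(1, t_max + 1):
        if t <= data.T:
            rows.append({"t": t, "kind": "interpolated", "richness": rarefy_incidence(data, t)})
        else:
            rows.append({"t": t, "kind": "extrapolated", "richness": chao2_extrapolate(data, t)})
    return pd.DataFrame(rows)


def accumulation_curves(
    incidence: dict[str, IncidenceData],
    t_max: int | None = None,
) -> pd.DataFrame:
    """Curves for every entity class in one tidy table."""
    frames = []
    for cls, data in incidence.items():
        frame = accumulation_curve(data, t_max)
        frame.insert(0, "entity_class", cls)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
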