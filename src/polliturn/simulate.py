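"""Synthetic seasonal plant-pollinator survey generator.

Emulates a multi-year weekly survey of a temperate meadow: six fixed plots
(five full-size and one smaller, at two-thirds effort) visited once per
survey round, 13-17 rounds per year roughly 7 days apart across a
late-May-to-September flowering season (days 150-260).  Species activity
is phenology-driven: each plant and pollinator has a seasonal peak day
(jittered per year) and a Gaussian activity window, with a slower decay
after the peak than before it, so communities assemble quickly early in
the season and disperse gradually late — making week-to-week dissimilarity
highest at the start of the season.

Counts arise from a Poisson observation process: each co-active
(plant, pollinator) pair in each plot-visit draws a count with mean

    base_rate x plant_activity x pollinator_activity x preference
              x plot_effort x year_factor,

and zero counts emit no record.  Pollinator preferences per plant follow a
Dirichlet distribution (small concentration = a few dominant visitors per
plant); a rewiring knob redraws a fraction of the plant preference rows
each week, creating link turnover among co-active species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .records import InteractionRecord

#: Seed of the canonical simulated dataset used throughout the documentation
#: and the qualitative test properties.
REFERENCE_SEED = 42

#: Species activity is truncated to zero beyond this many (one-sided) SDs
#: from the seasonal peak, so no record can involve a species outside its
#: activity window.
ACTIVITY_TRUNCATION_SD = 4.0


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic community and survey process.

    Defaults mirror the survey design being emulated: 8 years, 6 plots
    (one at reduced effort), weekly rounds 7 days apart, 13-17 rounds per
    year over a season spanning days 150-260.
    """

    n_years: int = 8
    start_year: int = 2015
    weeks_per_year: tuple[int, int] = (13, 17)  # inclusive range, drawn per year
    survey_interval_days: int = 7
    season_start_day: int = 150
    season_length_days: int = 110
    n_plots: int = 6
    plot_effort_multipliers: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 2.0 / 3.0)
    n_plants: int = 25
    n_pollinators: int = 60
    phenology_breadth_sd: float = 4.0  # days; entry-side SD of the activity window
    phenology_exit_slowdown: float = 8.0  # exit-side SD multiplier (> 1: slow decay)
    peak_jitter_sd: float = 5.0  # per-year shift of each species' peak day
    peak_clustering: float = 1.8  # Beta(a, a) shape of peak days over the season; 1 = uniform
    plant_abundance_sigma: float = 1.4  # lognormal sigma of per-plant abundance
    pollinator_abundance_sigma: float = 1.4  # lognormal sigma of per-pollinator abundance
    preference_concentration: float = 0.12  # Dirichlet concentration per plant row
    preference_min_share: float = 0.05  # affinities below this share are forbidden links
    base_visit_rate: float = 30.0  # expected visits per 15-min survey at full activity
    year_effect_sd: float = 0.3  # lognormal sigma of the yearly activity factor
    rewiring_rate: float = 0.35  # weekly max probability of redrawing a plant's preferences
    seed: int = REFERENCE_SEED

    def __post_init__(self) -> None:
        if self.base_visit_rate < 0:
            raise ValueError("base_visit_rate must be >= 0")
        if len(self.plot_effort_multipliers) != self.n_plots:
            raise ValueError("need one effort multiplier per plot")
        if any(not 0 < m <= 1 for m in self.plot_effort_multipliers):
            raise ValueError("effort multipliers must lie in (0, 1]")
        if not 0 <= self.rewiring_rate <= 1:
            raise ValueError("rewiring_rate must lie in [0, 1]")
        lo, hi = self.weeks_per_year
        if not 1 <= lo <= hi:
            raise ValueError("weeks_per_year must be an increasing positive range")


@dataclass
class GroundTruth:
    """Latent state behind the generated records, keyed by (year, week)."""

    plant_peaks: Mapping[int, np.ndarray]  # year -> per-plant peak day
    pollinator_peaks: Mapping[int, np.ndarray]
    active_plants: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    active_pollinators: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    rate_matrices: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)


def _activity(day: float, peaks: np.ndarray, breadth: float, exit_slowdown: float) -> np.ndarray:
    """Asymmetric-Gaussian activity in [0, 1], truncated beyond 4 SD."""
    delta = day - peaks
    sd = np.where(delta <= 0, breadth, breadth * exit_slowdown)
    z = delta / sd
    act = np.exp(-0.5 * z * z)
    act[np.abs(z) > ACTIVITY_TRUNCATION_SD] = 0.0
    return act


def simulate_surveys(config: SimulationConfig) -> tuple[list[InteractionRecord], GroundTruth]:
    """Generate one multi-year survey record table plus its latent ground truth.

    Deterministic given ``config.seed``.  Survey rounds may span two
    adjacent calendar days (one plot is occasionally visited a day late),
    as happens in the field.
    """
    rng = np.random.default_rng(config.seed)
    n_pl, n_po = config.n_plants, config.n_pollinators
    season_end = config.season_start_day + config.season_length_days

    # peak days cluster toward mid-season (richness highest in mid-summer)
    a = config.peak_clustering
    plant_base_peaks = config.season_start_day + config.season_length_days * rng.beta(a, a, size=n_pl)
    poll_base_peaks = config.season_start_day + config.season_length_days * rng.beta(a, a, size=n_po)
    # species abundance heterogeneity: lognormal, unit mean
    s_pl, s_po = config.plant_abundance_sigma, config.pollinator_abundance_sigma
    plant_abund = rng.lognormal(-0.5 * s_pl**2, s_pl, size=n_pl)
    poll_abund = rng.lognormal(-0.5 * s_po**2, s_po, size=n_po)

    def draw_pref_row(r: np.random.Generator) -> np.ndarray:
        """Plant preference row: Dirichlet affinity weighted toward abundant
        pollinators, with sub-threshold affinities zeroed (forbidden links)."""
        row = r.dirichlet(np.full(n_po, config.preference_concentration)) * poll_abund
        row /= row.sum()
        row[row < config.preference_min_share] = 0.0
        if row.sum() == 0:  # pathological draw: keep the single best partner
            row[int(np.argmax(poll_abund))] = 1.0
        return row / row.sum()

    base_pref = np.stack([draw_pref_row(rng) for _ in range(n_pl)])

    plot_names = [f"P{k + 1}" for k in range(config.n_plots)]
    truth = GroundTruth(plant_peaks={}, pollinator_peaks={})
    records: list[InteractionRecord] = []

    for y_idx in range(config.n_years):
        year = config.start_year + y_idx
        plant_peaks = plant_base_peaks + rng.normal(0.0, config.peak_jitter_sd, size=n_pl)
        poll_peaks = poll_base_peaks + rng.normal(0.0, config.peak_jitter_sd, size=n_po)
        truth.plant_peaks[year] = plant_peaks
        truth.pollinator_peaks[year] = poll_peaks
        year_factor = float(rng.lognormal(0.0, config.year_effect_sd))
        n_weeks = int(rng.integers(config.weeks_per_year[0], config.weeks_per_year[1] + 1))
        pref = base_pref.copy()

        for week in range(1, n_weeks + 1):
            round_day = config.season_start_day + (week - 1) * config.survey_interval_days
            # weekly rewiring: some plants' realized preferences are redrawn
            act_pl = _activity(
                round_day, plant_peaks, config.phenology_breadth_sd, config.phenology_exit_slowdown
            )
            act_po = _activity(
                round_day, poll_peaks, config.phenology_breadth_sd, config.phenology_exit_slowdown
            )
            # a plant re-sorts its visitor spectrum mostly while in full bloom,
            # so realized rewiring peaks in mid-season when activity is highest;
            # abundant generalists keep a stable core of links while rare
            # plants' realized partners are more stochastic week to week
            lability = act_pl * np.minimum(1.0, 1.0 / plant_abund)
            redraw = rng.random(n_pl) < config.rewiring_rate * lability
            for i in np.flatnonzero(redraw):
                pref[i] = draw_pref_row(rng)
            rate = (
                config.base_visit_rate
                * year_factor
                * np.outer(plant_abund * act_pl, act_po)
                * pref
            )
            truth.active_plants[(year, week)] = np.flatnonzero(act_pl > 0)
            truth.active_pollinators[(year, week)] = np.flatnonzero(act_po > 0)
            truth.rate_matrices[(year, week)] = rate

            # one plot per round is occasionally surveyed a day late
            late_plot = int(rng.integers(0, config.n_plots)) if rng.random() < 0.3 else -1
            for p_idx, plot in enumerate(plot_names):
                day = min(round_day + (1 if p_idx == late_plot else 0), 366)
                counts = rng.poisson(rate * config.plot_effort_multipliers[p_idx])
                for i, j in zip(*np.nonzero(counts)):
                    records.append(
                        InteractionRecord(
                            year=year,
                            ordinal_day=day,
                            week_index=week,
                            plot=plot,
                            plant=f"plant_{i + 1:03d}",
                            pollinator=f"poll_{j + 1:03d}",
                            count=int(counts[i, j]),
                        )
                    )
    return records, truth


def reference_dataset() -> list[InteractionRecord]:
    """The canonical simulated dataset: default configuration, documented seed."""
    records, _ = simulate_surveys(SimulationConfig(seed=REFERENCE_SEED))
    return records


def config_with_seed(seed: int, **overrides) -> SimulationConfig:
    """Convenience: default config with a different seed (and any overrides)."""
    return replace(SimulationConfig(), seed=seed, **overrides)
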