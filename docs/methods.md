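# Methods

## Data model and network assembly

The unit of observation is one recorded visit: (year, ordinal day, survey
week, plot, plant, pollinator, count). The survey week index is
authoritative for grouping; a survey round may span two adjacent calendar
days (plots are occasionally visited a day late), and the representative
day of a pooled network is the minimum contributing day — a deterministic,
order-independent convention. Taxon labels are opaque strings; genus-level
identifications are treated as species-level units.

Pooling a plot subset sums counts per (plant, pollinator) link within each
(year, week); species sets are derived from the links, so a network can
never contain an unlinked species. The inclusion filter keeps networks
with ≥ 3 plant and ≥ 3 pollinator species (both thresholds configurable).
Consecutive *retained* networks within a year are paired even when an
intervening week was excluded; each pair carries its day gap so users can
drop long-gap pairs. The ordinal day attached to a pair is the midpoint of
the two representative days.

## The partition

All dissimilarities are computed on link presence/absence (counts are kept
in the data model but never weighted — the Whittaker/Sørensen statistic is
binary). A species is "shared" if it has at least one link in both
networks, evaluated per guild; a unique link counts toward rewiring only
if both endpoints are shared. The poisot ßST is always obtained by
subtraction (ßWN − ßOS), never directly, and additivity is asserted to
1e-12 inside `partition` itself.

When a pair has no shared-species links at all (a = b_os = c_os = 0) the
rewiring component has an empty denominator under either scheme; it is
defined as 0 and the result is flagged `degenerate_os`. This preserves
additivity (ßST = ßWN) while keeping such pairs auditable. Degenerate
pairs are included in component means by default; `drop_degenerate`
excludes them from the ßOS/ßST means (never from ßWN) to show sensitivity.

## The effort experiment

All 2^n − 1 non-empty plot subsets are enumerated (deterministically, by
size then lexicographically; a guard refuses more than 12 plots). The
richness filter is applied per subset, so smaller subsets may retain fewer
weeks. Aggregation takes the arithmetic mean of each component over
subsets within (subset size, year, week pair, method); these means are the
observations for the effort regressions, which collapses subset
pseudo-replication while keeping the year-season structure visible. The
per-group mean day is carried along as a value (subsets can differ by one
day when a plot was surveyed late).

## Regression layer

* **Effort regressions.** OLS of a mean component on ordinal day and plot
  count, each as linear + quadratic terms. Quadratics use orthogonalized
  (centered, QR-based) polynomial coding — fitted values and AIC are
  unchanged, but the artificial degree-1/degree-2 collinearity of raw
  polynomials is removed. The initial model may include the day × plots
  interaction on raw scales; the collinearity screen computes the
  generalized variance inflation factor per term via determinant ratios of
  the predictor correlation matrix and reports gVIF^(1/(2·Df)). Any value
  above 5 triggers removal of the interaction and a refit, after which the
  table is reported again. Linear-only and quadratic candidates are
  compared by AIC (only fits of identical observations are comparable).
* **Plot-count contrasts.** The selected model is refit with plot count as
  a categorical factor (day terms retained); estimated marginal means are
  evaluated at the mean ordinal day, so level differences reduce to
  factor-coefficient differences. All pairwise differences are tested with
  studentized-range (Tukey) adjusted p-values; with two levels this
  reduces exactly to the unadjusted t-test. α = 0.05 throughout.
* **Seasonal mixed models.** For the full-effort weekly series:
  response ~ centered day + day² (fixed) + (1 | year), REML. REML is
  appropriate because no AIC comparison across different fixed-effect
  structures is performed on the LMMs. When the between-year variance
  estimate lands on the zero boundary the model degenerates to OLS and the
  OLS fit is reported (the profiled mixed-model intercept is numerically
  meaningless there); this also makes the zero-variance LMM reproduce OLS
  estimates exactly, as it should.

## Rarefaction

Incidence-based interpolation S(t) = S_obs − Σ C(T−Y_i, t)/C(T, t), with
binomial coefficients in log space; S(T) = S_obs exactly, and the curve
equals the exhaustive average over all C(T, t) unit subsets. Extrapolation
beyond T rises exponentially from S_obs toward the Chao2 asymptote
S_obs + ((T−1)/T)·Q1²/(2·Q2) (bias-corrected Q1(Q1−1)/(2(Q2+1)) when
Q2 = 0). The default sampling unit is the plot — the same axis the effort
experiment varies; survey-level units are available. Diversity order is
q = 0 (richness); coverage standardization and interval estimates are out
of scope (bootstrap hooks only).

## Synthetic surveys

The generator emulates a subalpine-meadow survey: 8 years, 6 plots (five
at full effort, one at 2/3 — a shorter plot), 13–17 weekly rounds per year
7 days apart across a season spanning days 150–260, 25 plant and 60
pollinator species, 15-minute-survey count data. Counts are Poisson with
mean = base rate × plant activity × pollinator activity × preference ×
plot effort × year factor; zero counts emit no record.

Parameter choices that matter, with rationale:

* **Phenology.** Peak days cluster toward mid-season (Beta(1.8, 1.8) over
  the season — mid-summer richness peak) with per-year jitter SD 5 days.
  Activity is an asymmetric Gaussian: entry-side SD 4 days, exit-side SD
  32 days (8× slower), truncated at 4 SD. Sharp entry and slow exit make
  communities assemble quickly and disperse gradually, so week-to-week
  dissimilarity is highest early in the season and declines — the seasonal
  signature the analysis is designed to detect. The two one-sided SDs
  average ≈ 18 days, a realistic total activity window.
* **Abundance and preferences.** Species abundances are lognormal
  (σ = 1.4, unit mean) in both guilds; each plant's visitor affinities are
  Dirichlet(0.12) weighted by pollinator abundance, with shares below 0.05
  zeroed (forbidden links — limited partner sets are a well-documented
  property of mutualistic networks). This makes link rates bimodal: core
  links are detected reliably even by one plot, peripheral species flicker
  in and out with effort. That bimodality is what lets sampling effort
  reclassify turnover: at low effort, rare species are simply absent and
  their dynamics register as species turnover; at high effort they are
  shared between weeks and the same dynamics register as rewiring.
* **Rewiring.** Each week a plant's preference row is redrawn with
  probability 0.35 × activity × min(1, 1/abundance): plants re-sort their
  visitor spectrum mostly in full bloom (so realized rewiring peaks
  mid-season, when partner options are richest), and abundant generalists
  keep a stable core while rare plants' realized partners are stochastic.
* **Observation.** Base rate 30 visits per 15-minute survey for a
  fully-active, unit-abundance plant; the realized average is ≈ 18 visits
  per plot-survey (~12,800 records over 8 years). Yearly activity factors
  are lognormal (σ = 0.3).

The canonical dataset (`reference_dataset()`, seed 42) retains ~89% of
weekly networks under the 3×3 filter, with median full-effort networks of
16 plants × 21 pollinators × 42 links.

What the generator does **not** emulate: negative-binomial overdispersion,
observer or weather effects, within-day ordering, plot spatial structure,
climate covariates, and taxonomic ambiguity. Passing tests on it therefore
demonstrate that the pipeline's *mechanics* recover known structure from a
phenology-driven Poisson world, not that field data will show the same
effect sizes.

## Numerical conventions

Partition additivity tolerance 1e-12 (asserted internally). Binomial
coefficients via log-gamma. Subset enumeration and all groupby
aggregations use stable deterministic orderings, so identical inputs give
byte-identical tables. All simulator randomness flows from a single
`numpy` Generator seeded by `SimulationConfig.seed`.

## Known limitations

* Poisot-scheme rewiring is nearly flat in effort on the canonical
  dataset (its ratio estimator on small shared subnetworks is biased
  upward at low effort, offsetting the reclassification gain); the
  commondenom scheme shows the clean monotone increase. The effort trends
  for ßWN and ßST are strong under both schemes.
* The generator's species turnover declines over the season along with
  overall turnover; a late-season ßST uptick (a second wave of phenology
  change) is not built in.
* The effort regressions inherit the non-independence of overlapping plot
  subsets; as in the analyses they mirror, they describe trends rather
  than support strict inference.
* Chao2 extrapolation is a point estimate; no variance or coverage
  machinery is provided.
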