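# polliturn

Week-to-week turnover of plant–pollinator interactions, its partition into
**rewiring** and **species turnover**, and the sensitivity of all three to
**sampling effort**.

Temperate plant–pollinator networks reassemble continuously: species enter
and leave with their phenologies, and the species that stay switch
partners. Both processes show up as dissimilarity between the networks
observed in consecutive weekly surveys, and both are entangled with how
hard you sample — a sparsely sampled network looks more variable than it
is. `polliturn` is a pipeline for quantifying this on long-format visit
records (year, survey week, plot, plant, pollinator, count): it builds
weekly bipartite networks, measures their pairwise dissimilarity,
partitions it, repeats the whole calculation on every subset of survey
plots to expose the effort dependence, and fits the regression and
mixed-model layer used to summarize the trends. A seeded generator of
synthetic seasonal surveys makes every stage testable end to end.

## The statistic

For two binary link sets with `a` shared links and `b`, `c` unique links,
interaction turnover is Whittaker's pairwise dissimilarity
(= Sørensen dissimilarity):

```
ßWN = (b + c) / (2a + b + c)
```

Unique links are split by whether both endpoint species occur in both
networks (`b_os`, `c_os`) or not (`b_st`, `c_st`), and ßWN is partitioned
additively, `ßWN = ßOS + ßST`, under two schemes:

* **poisot** — ßOS is the Whittaker dissimilarity of the shared-species
  subnetworks, `(b_os + c_os) / (2a + b_os + c_os)`; ßST is obtained by
  subtraction.
* **commondenom** — only the numerator is split over the common
  denominator: `ßOS = (b_os + c_os) / (2a + b + c)`,
  `ßST = (b_st + c_st) / (2a + b + c)`. Same numerators over a larger
  denominator, so commondenom rewiring is always ≤ poisot rewiring.

Weekly networks are retained only if they contain at least three plant and
three pollinator species. Sampling effort is varied by recomputing the
turnover series on all `2^n − 1` non-empty subsets of the n survey plots
(63 subsets for six plots) and averaging within subset size. Species and
link richness versus pooled sampling units are summarized with
incidence-based rarefaction and Chao2 extrapolation.

## Worked example

```python
from polliturn import (reference_dataset, pool_networks,
                       filter_min_richness, turnover_series)
from polliturn.effort import (effort_analysis, aggregate_effort,
                              grand_means_by_effort)

records = reference_dataset()          # canonical simulated survey, 12837 visits
rows = effort_analysis(records)        # all 63 plot subsets, both partitions
gm = grand_means_by_effort(aggregate_effort(rows))
print(gm.round(3).to_string(index=False))
```

```
     method  n_plots  beta_wn  beta_os  beta_st
commondenom        1    0.511    0.158    0.352
commondenom        2    0.451    0.169    0.283
commondenom        3    0.426    0.172    0.253
commondenom        4    0.401    0.176    0.225
commondenom        5    0.391    0.176    0.215
commondenom        6    0.384    0.176    0.208
     poisot        1    0.511    0.245    0.266
     poisot        2    0.451    0.237    0.215
     poisot        3    0.426    0.232    0.194
     poisot        4    0.401    0.224    0.177
     poisot        5    0.391    0.222    0.169
     poisot        6    0.384    0.220    0.165
```

Reading the table: pooling more plots lowers apparent interaction turnover
(ßWN drops from 0.51 at one plot to 0.38 at six) and apparent species
turnover, while the rewiring share rises (commondenom) or holds steady
(poisot) — under-sampling masquerades as species turnover. The step from
five to six plots changes ßWN far less than the step from one to two:
estimates saturate as the community becomes well sampled. ßWN is identical
across methods by construction; the methods differ in how much of it they
call rewiring.

## Command line

```
polliturn simulate --seed 42 --out records.csv
polliturn all --input records.csv --outdir out/      # or: polliturn all --seed 42
polliturn effort --seed 42 --outdir out/ --methods commondenom
```

Stages (`turnover`, `effort`, `models`, `curves`, `all`) write tidy CSV
tables plus a JSON manifest with row counts and checksums; a fixed seed
reproduces every byte.

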