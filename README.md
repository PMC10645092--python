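# traitcooc

Do species traits predict which species co-occur? `traitcooc` is a
Python library for linking pairwise species co-occurrence in
presence/absence survey data to per-trait dissimilarities, built around
the workflow used for lake-fish metacommunities: lakes are grouped into
watersheds, each watershed is a binary species × lakes incidence
matrix, and the question is whether segregated or aggregated species
pairs are the ones that differ in body size, temperature preference or
trophic level.

## The statistic

For a species pair with occupancies $r_a$, $r_b$ and $s$ shared lakes,
the **C-score** is the number of checkerboard units

$$C_{ab} = (r_a - s)(r_b - s),$$

which is 0 when one range nests inside the other and maximal when the
two species never share a lake. Each observed C-score is standardized
against a **fixed–fixed null model** — matrices with exactly the
observed row totals (species occupancies) and column totals (lake
richnesses), sampled uniformly with the **curveball algorithm** (a
Markov chain that trades lakes between two species' exclusive sets):

$$\mathrm{SES}_{ab} = \frac{C_{obs} - C_{exp}}{SD_{exp}},$$

with $C_{exp}$ and $SD_{exp}$ the mean and standard deviation of the
null C-scores (999 samples by default). Positive SES = segregation,
negative = aggregation. Pair SES values are averaged across the
watersheds where both species occur, then regressed on per-trait
Euclidean distances between z-scored traits (plus quadratic terms for
body size and trophic level) in four hypothesis models:

| model | predictors | question |
|---|---|---|
| H1_full | all five terms | do the traits jointly structure co-occurrence? |
| H2_body | $d_{body}, d_{body}^2$ | competition vs predation by size |
| H3_temp | $d_{temp}$ | environmental (thermal) filtering |
| H4_trophic | $d_{troph}, d_{troph}^2$ | competition vs predation by diet |

Because pairwise distances are not independent observations, each slope
is judged by a Mantel-style **randomization test**: the SES response is
shuffled over pairs (9999 times by default) while the trait-distance
design stays fixed; the two-sided permutation p-value is the headline
inference, with parametric OLS p-values reported alongside.

A synthetic metacommunity generator with tunable environmental
filtering, predation and competition effects makes the whole pipeline
testable end to end without access to survey data.

## Worked example

`examples/02_pair_ses.py` builds a hand-made 4-species × 8-lake
watershed in which "pike" never shares a lake with "dace":

```
observed C-score pike vs dace: 16
 dace - pike  C_obs 16 null  5.80 +/- 3.38  SES +3.02
 bass - pike  C_obs  6 null  4.83 +/- 3.06  SES +0.38
 dace - perch C_obs  6 null  5.00 +/- 3.16  SES +0.32
perch - pike  C_obs  2 null  4.80 +/- 3.10  SES -0.90
 bass - dace  C_obs  2 null  5.11 +/- 3.20  SES -0.97
 bass - perch C_obs  1 null  4.64 +/- 2.74  SES -1.33
```

pike–dace show 16 observed checkerboard units against a null
expectation of 5.8 ± 3.4: an SES of +3.0, strong segregation. The
bass–perch pair shares more lakes than the null expects (SES −1.3,
aggregation).

`examples/03_trait_distance_regression.py` simulates 8 watersheds with
strong thermal filtering and predation planted, then runs the full
pipeline. The H3 temperature slope comes out positive and significant
(0.38, permutation p = 0.001) and the H4 trophic quadratic term as well
(0.125, p = 0.031), while both body-size terms stay non-significant —
exactly the planted effect structure.

A thin CLI wraps the same stages:

```bash
traitcooc simulate --config sim.yaml --out data/
traitcooc run --manifest data/incidence/manifest.csv \
              --traits data/traits.csv --out results/ --seed 1
traitcooc regress --design results/design_table.csv --out rerun/
```

Every stage writes a CSV checkpoint (per-watershed SES, pooled pairs,
design table, regression reports); re-running a downstream stage from a
checkpoint reproduces its outputs byte-for-byte.

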