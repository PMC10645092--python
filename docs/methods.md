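# Methods

## Scope and data model

The unit of observation is a *watershed*: one binary species × lakes
incidence matrix. Watersheds with fewer than 20 lakes or fewer than 20
occurring species are removed before analysis (inclusive thresholds: a
20 × 20 matrix is retained), so that every randomized matrix has a
minimum size of 20 × 20. Species present in a watershed's file but
occurring in zero lakes are dropped at read time, *before* the species
count is taken — the filter counts species that actually occur.

Traits are read per species: body size (total length, cm, > 0),
temperature preference (°C) and trophic level (dimensionless, ≥ 1).
Missing temperature preferences are imputed as the unweighted mean over
congeners (species sharing the `genus` column) with known values; a
missing species without an informative congener is a hard error, and
body size and trophic level must be complete from the start. Imputation
never alters observed values.

## Null model

The pair C-score is `(r_a − s)(r_b − s)` checkerboard units. The null
ensemble fixes both row totals (species occupancy) and column totals
(lake richness) and is sampled with the curveball algorithm: a trade
picks two distinct species rows uniformly at random, pools the lakes
exclusive to either, and re-partitions that pool uniformly while
preserving each row's number of exclusive lakes. Trades where either
row has no exclusive lake are no-ops; keeping them in the chain is what
makes the stationary distribution uniform over the fixed-marginal set.
Uniformity is verified in the test suite against exhaustive enumeration
of small matrices (chi-square at α = 0.01).

Chain protocol: 1000 burn-in trades, then one sample every 100 trades
(both configurable). These defaults are deliberately conservative for
20 × 20-and-larger matrices and are validated empirically by the
uniformity tests; for tiny test matrices a thinning of 20 is already
statistically indistinguishable from independent sampling, while 5 is
not (chain autocorrelation visibly overdisperses the chi-square
statistic).

Per watershed, every unordered pair gets `SES = (C_obs − C_exp)/SD_exp`
from `n_null = 999` null samples; `SD_exp` is the sample standard
deviation (n − 1). The observed matrix is *not* included among the null
samples. Pairs whose null C-score distribution has zero spread are
flagged degenerate rather than assigned SES 0 — an uninformative null
cannot certify "random" co-occurrence — and are excluded from pooling.
Pooled mean SES is the arithmetic mean of defined SES values across the
watersheds where the pair occurs. Pairs are stored in lexicographic
order so pooling keys are stable.

Each watershed runs an independent chain seeded from the master seed
plus a CRC-32 hash of the watershed id, so any watershed can be re-run
in isolation (or in parallel) with identical results.

## Distances and design table

Traits are z-scored (sample SD, n − 1) over exactly the species that
enter the pooled pair table (switchable to the full trait CSV). The
per-trait Euclidean distance between two species is then `|z_a − z_b|`.
Quadratic terms are squares of these distances, not re-centered or
re-standardized; the resulting collinearity between d and d² is
accepted as part of the model definition. The design table carries one
row per pooled pair: `mean_ses` and the five predictors `d_body,
d_body_sq, d_temp, d_trophic, d_trophic_sq`.

## Regression and permutation inference

Each hypothesis model is an OLS fit with intercept (the intercept is
always estimated, never reported as a hypothesis term). Significance is
assessed by randomizing the response vector while holding the
trait-distance design fixed, refitting, and comparing absolute slopes:

    p = (1 + #{|b*| ≥ |b_obs|}) / (n_perm + 1)

two-sided, with the add-one correction so p is never 0 and lies on the
grid [1/(n_perm+1), 1]. Ties are counted as exceedances, with a 1e-9
relative tolerance absorbing floating-point rounding (exact-tie
permutations otherwise fall on the wrong side of the comparison by one
ulp, a bias visible against an exhaustive-enumeration oracle even at
n = 4).

Two shuffle modes are provided because the procedure can be read two
ways and they are *not* equivalent:

* `pair_shuffle` (default): the mean-SES vector is permuted freely over
  pairs — the literal "randomize the co-occurrence values of the
  species pairs".
* `species_identity`: species labels are permuted and each pair reads
  its response from the relabelled pair, preserving the dependence
  between pairs that share a species — the Mantel-test analogue. This
  mode requires a complete pair table over the species set.

Observed estimates are identical in both modes; only p-values differ.
Parametric t-test p-values are reported for completeness, but the
permutation p is the appropriate assessor given that pairwise distances
are mutually dependent.

## Synthetic metacommunity generator

The generator emulates the hypothesized assembly mechanisms, not any
specific survey. Per watershed, each lake draws a temperature from
Normal(`temp_mean` = 18 °C, `temp_sd` = 4 °C) and each species occupies
each lake independently with probability

    logit p = logit(base_occupancy) − beta_env · ((T_sp − T_lake)/temp_scale)²

(`base_occupancy` = 0.3, `temp_scale` = 4 °C). Two cull passes follow,
applied once in the order environment → predation → competition (no
iteration to equilibrium, which keeps planted effect directions
analyzable):

* **predation**: a species whose trophic level sits more than
  `pred_gap` = 1.5 below the highest co-occurring trophic level is
  culled with probability `1 − exp(−beta_pred · excess)`, where
  `excess` is the overshoot beyond the gap. The hazard *grows* with
  trophic separation. A constant-probability cull (hazard independent
  of the overshoot) was evaluated and rejected: it saturates, producing
  a concave SES–distance relationship whose quadratic term is
  *negative*, i.e. it cannot generate the accelerating-segregation
  signature the predation hypothesis describes.
* **competition**: in pairs closer than `comp_width` = 0.5 body-size
  z-units, a random member is culled with probability
  `1 − exp(−beta_comp)` per shared lake.

Traits: body size is log-normal (median 30 cm, log-SD 0.7); temperature
preference is Normal(18, 4) °C; trophic level is stratified-uniform on
[2, 4.5] — one draw per equal-width bin, shuffled — so the marginal
distribution is uniform but every simulated pool spans herbivores
through top predators. The stratification is a realism choice (a lake
fish community without piscivores is not a plausible species pool) with
a statistical consequence: it removes between-replicate variance in the
number of predator–prey pairs, which under i.i.d. draws makes the
planted predation effect size itself strongly random. Genus labels come
in blocks of 3 so congeneric imputation is always exercisable, and an
optional fraction of species (never a whole genus) loses its
temperature value.

Watersheds whose draw leaves fewer than 20 occurring species are
redrawn (up to 50 times), so generator output always passes the
watershed filter. The generator never calls the pipeline's own
statistics, so parameter-recovery tests are not circular.

With all strengths zero the generator is exactly neutral: occupancy is
i.i.d. Bernoulli, and the permutation p-values of every regression term
are uniform — the test suite verifies calibration (per-term rejection
rates and KS uniformity over 200 neutral replicates).

## Problem sizes used in validation

Statistical tests run at deliberately scaled-down sizes chosen so each
check retains power while the whole suite stays fast: calibration uses
25 species × 3 watersheds × 30 lakes with 199 null samples and 499
permutations over 200 replicates; parameter recovery uses 25 species ×
12 watersheds × 60 lakes (10 replicates per scenario), with planted
strengths `beta_env` = 4 and `beta_pred` = 6 selected by a pilot power
analysis so the planted signal dominates process noise at that scale.
Oracle comparisons (exhaustive enumeration of fixed-marginal matrix
sets, exhaustive permutations) are only feasible on tiny inputs
(≤ 4 × 5 matrices, 4-row designs) and are exact there.

## What passing tests do and do not show

The generator produces independent Bernoulli occupancy modified by
three stylized mechanisms. Real survey data differ in ways the
simulation does not emulate: spatial autocorrelation among lakes,
dispersal limitation and post-glacial colonization history, correlated
traits (body size and trophic level co-vary in real fish), detection
error, and richness gradients across watersheds. Passing recovery tests
therefore shows the pipeline correctly measures what the null model and
regression define — not that those definitions capture every process
structuring real communities. In particular, the fixed–fixed null
conditions on observed marginals, so any mechanism that expresses
itself purely through occupancy totals is invisible by construction.

## Numerical and degenerate-input choices

* Null SD ≤ 1e-12 is treated as exactly zero (degenerate pair).
* Zero-variance trait columns are a hard error in z-scoring.
* Rank-deficient regression designs are rejected, naming the most
  collinear term pair.
* The design-table CSV is a bit-exact checkpoint: the pipeline
  regresses on the serialized table (pandas round-trip float parsing),
  so re-running the regression stage from the file reproduces the
  pipeline's reports exactly.
* All randomness flows from one master seed through named streams
  (CRC-32-tagged `SeedSequence`), so results are independent of
  execution order and worker count.
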