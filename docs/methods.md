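# Methods

## Model

The package treats reproductive isolation between two taxa as a set of named
barriers, each reducing gene flow by a per-stage strength, combined by a
sequential cascade. Two families of raw input feed the barrier strengths:

* **Mating outcomes** `(H, C)`: heterospecific and conspecific cross
  success, here fruit set (fruits over flowers) from reciprocal hand
  pollinations. Three metrics are defined on them:
  symmetric `1 − 2H/(H+C)` (a deviation-from-random-mating index in
  [−1, 1]), and proportional `1 − H/C` (the fraction of conspecific-level
  gene flow the barrier removes, unbounded below).
* **Sharing summaries** `(S, U)`: the shared and unshared extent of an
  ecological resource between the two populations, with co-occurrence RI
  `1 − S/(S+U)`. For species assemblages, `S` is the count-based Jaccard
  fraction `|A ∩ B| / |A ∪ B|` and `U = 1 − S`; an abundance-weighted
  alternative uses the fraction of pooled visits made by shared species.
  A `direct` method carries externally supplied `(S, U)` pairs, needed when
  a published table prints sharing fractions whose species lists are not
  reproduced in full.

The cascade multiplies passages: with strengths `s_1 … s_k` in life-cycle
order, barrier `n` removes `AC_n = s_n · Π_{i<n}(1 − s_i)` of total gene
flow, the total is `T = 1 − Π(1 − s_i)`, and relative contributions are
`RC_n = AC_n / T`. `T` is order-invariant; the `AC_n` are not, so the
default order for the packaged example is the study's: host trees → seed
dispersers → pollinators → the two post-pollination cross directions.

### Why two post-pollination metrics

Published barrier tables print the symmetric metric as the "RI value" of
post-pollination barriers but are numerically consistent only if the
cascade consumed the proportional metric: for the packaged example,
`(1 − 0.185/0.814) · 0.064 = 0.049` reproduces the printed contribution,
while the symmetric value would give 0.040. `BarrierEstimate` therefore
carries both; reports display the symmetric value and the cascade uses the
proportional one by default, switchable via
`--post-strength-formula symmetric`.

### Treating the two cross directions as two cascade stages

The packaged example follows the source analysis in running one five-stage
cascade in which the two reciprocal cross directions are consecutive
barriers. A direction-specific analysis (two four-barrier cascades) may be
more standard; it is available by passing the appropriate `--order` /
barrier subsets, but is not the default because the default must reproduce
the published table.

## Display conventions

Internal values are never rounded between stages. For display, cumulative
columns and raw values use round-half-even at the report precision
(default 3). Two quirks of the published table are reproduced deliberately:

* the **relative** column shows the *rounded* absolute contribution divided
  by the unrounded total (0.0494545 → 0.049; 0.049/0.99030 → 0.049, where
  the unrounded ratio 0.04994 would display as 0.050);
* the **RI value** column is truncated toward zero rather than rounded
  (0.62963 prints as 0.629). A guard rounding at `precision + 6` decimals
  absorbs binary representation noise first, so 0.19999999999999996 still
  prints as 0.200.

Negative strengths (heterospecific advantage) are never clipped: they
propagate through the cascade (contributions may be negative, the total may
decrease) and the report flags the affected rows.

## Estimation and inference

* **Fruit set** is the pooled ratio of sums, Σfruits/Σflowers, per group —
  not the mean of per-plant proportions — matching the definition of
  reproductive success as fruits produced over flowers pollinated.
* **Uncertainty** comes from a percentile bootstrap (default 2,000
  resamples) that resamples *plants* with replacement, because flowers are
  nested within plants and flower-level resampling would understate
  variance. Percentile rather than BCa intervals keep the procedure simple
  and exactly reproducible under a seed. Single-plant groups return a
  degenerate interval and are flagged rather than rejected.
* **The treatment permutation test** uses the range (max − min) of pooled
  per-level fruit-set proportions as its statistic and permutes labels over
  whole plant-by-level record groups. p-values use the add-one estimator
  `(1 + #{permuted ≥ observed}) / (1 + n_perm)`, with a 1e−12 tolerance in
  the ≥ comparison to make tie handling deterministic. Exchangeability of
  clusters under the null makes the test exactly valid (never
  anticonservative) at any design size; with very small designs the range
  statistic is heavily tied and the test becomes conservative. The
  calibration suite therefore uses 15 plants × 6 flowers per treatment,
  a size at which the permutation distribution resolves α = 0.05 nearly
  nominally while running in seconds.
* **Reciprocal-cross asymmetry** is reported as max/min with the direction
  of the larger value; a zero denominator yields an undefined-flagged
  result, not an exception, because a zero fruit-set arm is a legitimate
  observation.

## Synthetic data

The generators emulate the structure of the study design, not any
particular dataset:

* **Crossing experiments**: per population and treatment, each of
  `n_plants` plants receives `flowers_per_plant` flowers; a per-plant
  normal effect on the logit scale (sd `plant_sd`) shifts all of that
  plant's treatment probabilities, then each flower is an independent
  Bernoulli trial. `plant_sd = 0` recovers iid flowers exactly, and
  probabilities of exactly 0 or 1 are left untouched by the plant effect.
  The logit-normal (rather than beta-binomial) parameterisation makes
  `plant_sd` directly interpretable as a log-odds spread.
* **Assemblages**: two species sets of configured sizes whose Jaccard
  sharing equals the nearest *feasible* value to the requested overlap
  (shared counts are integers, so only `k/(n_a + n_b − k)` is achievable);
  infeasible targets trigger a warning and the nearest value. Realized
  sharing is exact by construction. Species names are zero-padded synthetic
  labels; real species names appear only in the packaged fixture.
* **Visitation**: one multinomial draw of the configured total across the
  population's species proportions.

Randomness: one global integer seed; each generator derives a 31-bit child
seed by SHA-256 hashing of `"{seed}:{label}"`, so adding a generator never
perturbs the draws of existing ones.

### Default study configuration

`default_study_config()` mirrors the printed design: 10 plants × 3 flowers
per treatment per population (30 flowers per treatment), interspecific
success 0.20 for pollen moving into the AO population and 0.05 into CO (the
two printed reciprocal-cross fruit sets), pollinator assemblages of 4 and 5
species with Jaccard 0.8, disperser and host overlaps 0.4 and 0.2, and
visitation totals/shares from the observed hummingbird counts (55 and 59
visits). Per-flower probabilities for the intraspecific treatments are not
printed anywhere, so the defaults (autogamy 0.15, geitonogamy 0.25–0.35,
xenogamy 0.40–0.45, open 0.65) encode only the reported qualitative
ordering (open > outcross > self); synthetic runs reproduce that ordering,
not any particular bar heights. `plant_sd` defaults to 0.5, a moderate
between-plant spread (odds ratio ≈ 1.6 for a 1-sd plant).

What passing tests on synthetic data do **not** show: real crossing data
have unbalanced cluster sizes, treatment-by-plant interactions, and
non-logit-normal heterogeneity; real assemblages are open-ended samples,
not fixed-size sets. The generators validate the machinery, not the
field protocol.

## Numerical choices

* Totals are accumulated with `math.fsum`; the cascade's product identity
  `|ΣAC − (1 − Π(1 − s))| ≤ 1e−12` is asserted in `total_isolation` (at
  1e−9 against corruption) and property-tested at 1e−12.
* Proportions are decimals in [0, 1] everywhere internally; percentage
  inputs must be divided by 100 by the caller. The observed visit
  percentages (summing to 99.9) are renormalised to exactly 1 in the
  default configuration.
* The `direct` sharing method tolerates `S + U ≠ 1` (published raw pairs
  are sometimes rounded); computed methods enforce complementarity to
  1e−9.
* CSV readers reject unknown as well as missing columns, and close the
  treatment vocabulary, to fail loudly on schema drift; assemblage rows
  that normalize to the same species are merged with counts summed, but
  byte-identical duplicate rows are rejected as double entry.

## Problem sizes used in the validation suite

The stochastic suites use 200 replicates of 10,000 flowers per arm for
symmetric-RI parameter recovery (tolerance ±0.03, ≥95% coverage) and 1,000
simulated null datasets × 199 permutations for test calibration (rejection
rate 0.05 ± 0.02 at α = 0.05); both complete in well under a minute on one
core.

## Known limitations

* The cascade assumes barriers act independently given order; correlated
  barriers (e.g. host choice constraining disperser exposure) are not
  modelled — their joint effect is whatever the raw values already absorb.
* Unmeasured barriers (phenology, F1 viability, hybrid breakdown) are out
  of scope; a reported total is a lower bound on isolation only under the
  usual assumption that omitted barriers are non-negative.
* The host and disperser sharing fractions in the packaged fixture are
  carried as `direct` values because the underlying species lists are not
  fully enumerable from the published material; only the pollinator value
  is recomputed from raw lists.
* `abundance_weighted` sharing pools visits across both populations, which
  weights the better-sampled population more; with equal sampling effort
  this is the natural estimator, with unequal effort consider rarefying
  first.
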