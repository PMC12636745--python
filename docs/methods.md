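# Methods

This note records the modeling choices behind `cogload`: what each stage
assumes, which parameters matter, what the synthetic generator does and does
not emulate, and where the design was genuinely open.

## Encounter assembly

An encounter is defined by its id, never by elapsed time: a chart review in
the afternoon and documentation the next morning belong to the same
encounter if they share the id. Within an encounter, events are stably
sorted by timestamp (ties keep file order, since audit logs have
second-level resolution) and partitioned into segments wherever the gap to
the previous event exceeds `gap_minutes`.

**`gap_minutes` (default 30).** Audit-log conventions do not fix what bounds
an "active" segment, so the threshold is our construct and configurable. 30
minutes is a conventional sessionization cutoff; it keeps 1–2-minute pauses
inside a segment while splitting the canonical pattern of a 3-minute chart
review followed 37 minutes later by a face-to-face visit. Only segment
boundaries depend on it — trace membership never does. Segment counts are
monotone non-increasing in the threshold (property-tested).

## Cognitive-load metrics

* **Loops** — every non-first occurrence of an event type counts one loop,
  so loops = total − distinct (A,B,C,A,B,D → 2). An alternative that ignores
  immediate repeats is exposed (`immediate_only=True`, default off); both
  reproduce the worked example.
* **Distinct events** — set cardinality of event types.
* **Duration** — sum of segment spans (minutes). A single-event trace has
  duration 0.
* **Average time per event** — mean of within-segment inter-event gaps
  (seconds); the dwell of event *i* is the gap to event *i+1* inside the
  same segment, so segment-final events carry no dwell. Single-event traces
  return 0 by definition. A naive duration÷events reading is *not* used:
  with it, the metric would be redundant given duration and event count
  in a way that is inconsistent with observed cohort summaries, whereas the
  dwell-based construction is the defensible per-event reading. Both the
  dwell rule and the degenerate-value conventions are frozen here because
  they silently change downstream regression inputs.

**Row unit.** The modeling table carries one row per (encounter, provider)
pair. By default each row repeats the *combined* encounter trace's metrics —
the encounter's total effort — so multi-provider encounters contribute
duplicated metric rows distinguished only by the provider fixed effect;
this is precisely what encounter-clustered standard errors absorb, and it
matches cohorts where the observation count exceeds the encounter count.
A per-provider-stream variant (`per_provider_streams=True`) computes each
row from that provider's own events instead.

**Outliers.** Tukey fences Q1 − 1.5·IQR, Q3 + 1.5·IQR per metric, quartiles
by linear interpolation (numpy's default; the rule is recorded so fences are
reproducible). A record is an outlier if any metric breaches its fence.
The outlier-vs-initiation association uses a Pearson chi-square without
continuity correction, a risk ratio, and a Woolf log-OR 95% CI with the
Haldane–Anscombe 0.5 correction when a cell is empty.

## Synthetic cohort generator

The generator is the package's stand-in for protected audit-log data; its
defaults are the study conditions every calibrated test runs under.

What it emulates (per-encounter, defaults in parentheses):

* distinct event types ~ rounded normal (mean 33.7, sd 6.5, clipped [5, 80]);
* loops ~ negative binomial (mean 73.2, sd 36.8, cap 500); total events =
  distinct + loops, and the event sequence contains each chosen type at
  least once with the remainder multinomial — so realized loops/distinct
  match the draw exactly;
* 1–3 segments (probabilities 0.45/0.40/0.15) separated by 35–480-minute
  gaps; per-event dwells are log-normal (log-sd 1.0) with the per-encounter
  mean set so active duration hits a log-normal target (mean 38.3 min, sd
  21); dwells are clipped below the gap threshold so the planted segment
  structure is exactly recoverable;
* 1–3 providers (0.735/0.235/0.03) from a pool of 50 with roles
  physician/NP/PA (0.824/0.117/0.059) and zero-mean normal fixed effects
  (sd 0.3);
* patient covariates: truncated-normal age (58.8 ± 10.8 on [20, 75]),
  sex, five race/ethnicity levels, insurance class, ≥1 active diagnoses,
  integer comorbidity index — all matching the emulated cohort's margins;
* outcome: encounter-level Bernoulli from the quadratic logit applied to
  the realized (post-rounding) metrics, the covariates, and the primary
  provider's effect, with the six cognitive-load coefficients defaulting to
  the published estimates (loop vertex 93.9, distinct vertex 17.9). No
  intercept is published, so it is solved by Brent root-finding to a target
  prevalence (45.5%).

What it does not emulate: the real event-type vocabulary (types are opaque
codes), any joint dependence between metrics beyond what the construction
induces (only marginals are published; in particular the per-event dwell
mean is *determined* by duration and event count, realizing ≈24 s — between
the emulated cohort's median ≈22 s and its heavy-tailed mean ≈42 s), event
grammar or ordering semantics, eligibility (all patients are assumed
statin-eligible), and event-level outcome signal. That last point matters
for interpretation: passing tests demonstrate that the pipeline recovers
*aggregate-metric* effects it was told to plant; they cannot certify
event-level AUROC or attribution rankings on real data, where the signal
lives in specific event types.

## Association model

Estimation is iteratively reweighted least squares (Newton scoring with
step-halving), converging when the maximum score component falls below 1e-8
or the relative log-likelihood change below 1e-10. The implementation is
validated against an independent GLM fit in the test suite (coefficients to
1e-8, clustered SEs to 1e-8 relative).

* **Design.** Intercept; loops and distinct events with squared terms;
  duration and average time linear; dummy-coded covariates against fixed
  reference levels (White, Male, commercial); dense provider dummies
  against the most frequent provider. Providers with fewer than 2 rows are
  pooled into a single "rare" dummy; provider dummies whose rows have a
  constant outcome (perfect separation) are merged into the reference with
  a warning (configurable to error). All-constant columns are dropped with
  a warning. Dense dummies are fine at realistic provider counts (~50);
  absorption/demeaning is out of scope.
* **Clustered covariance.** CR1 sandwich: bread = inverse observed
  information, meat = outer products of within-cluster score sums,
  small-sample factor G/(G−1)·(n−1)/(n−k). With singleton clusters this
  reduces to HC0 up to the factor; duplicating every row within its cluster
  leaves clustered SEs essentially unchanged (both verified).
* **Fit statistics.** McFadden pseudo-R² and its adjusted form (explicitly
  labeled as such — "adjusted R²" has no canonical logit definition), plus
  the RMSE of predicted probability against the 0/1 outcome.
* **Curvature testing.** Joint Wald test of the squared terms under the
  clustered covariance, plus the adjusted-pseudo-R² difference against a
  refitted all-linear model. Simulation checks of test size and power run
  at 100 replicates of n = 2,000 — sizes chosen as this package's standard
  small-simulation design.
* **Vertex and AME.** Vertex = −β_lin/(2β_quad) in raw metric units,
  undefined (error) at β_quad = 0; no CI is attached by default. AME =
  mean[(β_lin + 2β_quad xᵢ) pᵢ(1−pᵢ)] over all rows or the subsets
  below/above the vertex, verified against central finite differences to
  1e-6. Predicted-probability curves hold other continuous terms at sample
  means, categoricals at reference, and the provider effect at its sample
  mean.

## Event-level model and attribution

Features are (event type × kind) with kind ∈ {avg dwell, loops-to-event,
presence}; unvisited events are zero everywhere, and all-zero columns are
dropped with a warning. Rows are encounters (the outcome is
encounter-level). The classifier is LightGBM with learning rate 0.1, depth
6, up to 500 rounds, early stopping on validation log-loss with patience
20, `deterministic=True` and a single thread so a seed fully reproduces the
run; none of the tree controls beyond the learning rate and split come from
the emulated study, so they are recorded here as configuration. Each of
`n_repeats` repetitions draws a fresh stratified 70/15/15 split and scores
AUROC on its test fold; the 95% CI is percentile-based across repeats (the
CI construction was an open choice).

**Attribution.** Signed and absolute attributions are exact Shapley values
of the margin difference f(x) − f(z) against a fixed reference row z (all
zeros: the provider who engaged with nothing), computed in closed form from
the dumped tree structures and validated against brute-force subset
enumeration. The reference-based game is what makes the *direction* column
well-defined: the self-centered (path-dependent) decomposition has
per-feature dataset means of exactly zero for additive effects, so the sign
of such a mean is sampling noise; against a fixed baseline, a
monotone-increasing dependence yields a stably positive mean. Local
accuracy (row sums reproduce the margin) holds to machine precision.
LightGBM's native path-dependent `pred_contrib` remains available through
the booster and is cross-checked against its own enumeration oracle in the
tests. Relative contribution = mean |SHAP| normalized across features;
per-category aggregation sums it within metric kinds.

## Numerical and degenerate-input conventions

* Timestamps are second-resolution; ties preserve input order everywhere.
* Empty traces are rejected by metric operations; empty event sets yield
  empty trace lists (not errors) from assembly.
* An all-constant outcome raises (no MLE); non-convergence warns and flags
  rather than failing silently.
* Quartiles need ≥4 records; a zero 2×2 cell triggers the 0.5 correction
  with a warning.
* All randomness flows from numpy `default_rng` seeds; equal seeds give
  byte-identical cohorts and reports.

## Problem sizes used by the checks

Calibration and recovery checks simulate 15,450 encounters (≈20,000
provider×encounter rows); interval-coverage checks run 500 replicates of
200 clusters × 10 rows; SHAP-stage checks run 20 split repetitions over
~1,500 rows; unit-level simulations use 1,000–4,000 rows. These sizes are
the package's standard test design, balancing statistical resolution
against a fast default suite.

## Known limitations

* The generator's joint metric structure is a construction; conclusions
  about real audit logs require real extracts through the same interfaces.
* Fixed effects use dense dummies; thousands of providers would need an
  absorption path.
* The event-feature matrix is dense; very large event vocabularies would
  warrant a sparse representation.
* Direction/CI columns for features with near-zero attribution remain
  noisy even against a fixed reference; the CI columns are the guard.
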