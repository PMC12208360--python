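# Methods

## The estimand and its scale

A worker's physical behaviour during work hours is the three-part
composition (SB, LPA, MVPA) of work time. Compositions carry only relative
information, so all modelling happens in isometric log-ratio (ilr)
coordinates under the fixed sequential binary partition SB | {LPA, MVPA},
then LPA | MVPA:

    ilr1 = sqrt(2/3) * ln( SB / sqrt(LPA * MVPA) ),
    ilr2 = sqrt(1/2) * ln( LPA / MVPA ).

The part order (SB, LPA, MVPA) is fixed package-wide; alternative contrasts
are expressed as pivot rotations (each behaviour moved into first position),
never by re-declaring the basis. The rotation is an isometry, so the squared
norm of the coordinate pair is pivot-invariant — a property the test suite
checks numerically. A slope β on a first pivot coordinate per unit of a
determinant translates to a percentage change of the pivot behaviour
relative to the geometric mean of the other two:

    %Δ = 100 * (exp(β * sqrt(D/(D−1))) − 1),  D = 3.

This translation is validated in the tests against four worked magnitudes
(β = 0.03 → +3.7%, −0.03 → −3.6%, 0.01 → +1.2%, −0.05 → −5.9%).

## Day-level processing

* **Validity rule** — a measured workday counts if it has at least 4 h of
  work-time measurement; the bound is closed (exactly 4.0 h is valid).
  Workers left with zero valid days are flagged excluded, never silently
  dropped by a join.
* **Zero replacement** — a day with exactly zero time in a part (possible in
  real accelerometer data, not produced by the generator) is repaired
  multiplicatively: the zero becomes δ_j = half the smallest nonzero
  fraction observed for that part across the dataset, and the day's nonzero
  parts are shrunk proportionally so the day still sums to its work
  duration. If a part is zero on every day there is nothing to impute from
  and the pipeline stops with an error.
* **Aggregation** — a worker's analysis composition is the compositional
  centre (part-wise geometric mean, re-closed) of their valid daily
  compositions. An arithmetic-mean alternative is available as a
  sensitivity switch (`--aggregation arithmetic`). Days enter only through
  this aggregate; the mixed models are three-level (institution, team,
  worker), not four-level.
* **Complete-case** — association models require all 15 determinants;
  missing rows are dropped with per-determinant counts logged. No
  imputation.

## Mixed models

All estimation uses one in-house REML engine for Gaussian random-intercept
models (`codawork.reml`). The variance structure is
V = σ²_e I + Σ_j σ²_j Z_j Z_j' with indicator matrices for institutions and
(globally uniquely labelled) teams. The restricted likelihood is profiled
over the residual variance and the fixed effects, leaving a criterion over
the non-negative variance ratios; it is minimised by L-BFGS-B from a
deterministic expected-mean-squares start and polished by Nelder-Mead
(criterion tolerance ~1e-10). Negative components are excluded by the
constraint, i.e. truncated at zero. All linear algebra runs through the
Woodbury identity on precomputed cross-products, so cost scales with the
number of groups. The engine was written in-house because the
variance-components analysis needs a structure none of the usual formula
interfaces expresses directly (below); statsmodels' MixedLM serves as an
independent cross-check in the test suite, and on balanced designs the
engine must agree with closed-form ANOVA estimators to 1e-6 (tested).

* **Variance-components analysis.** The two ilr coordinates are stacked as
  two datasets sharing one variance parameter per level (institution, team;
  worker = residual) but with separate means and independent random-effect
  realisations per coordinate — matching how the generator draws them. This
  yields a single estimate per organisational level, reported with its %
  contribution. A per-coordinate decomposition is attached as a diagnostic.
  Designs where every team has one worker confound team/institution
  variance with worker variance and are refused, as are single-institution
  designs.
* **Model 1.** Each coordinate is regressed on all 15 determinants (raw
  scales, no standardisation; treatment contrasts with reference male /
  pedagogue / private) with the nested random intercepts. The single
  reported p per determinant is a 2-df Wald test combining the two
  coordinate-wise z statistics, which assumes cross-coordinate
  independence; per-coordinate estimates, Wald 95% CIs and p-values are
  always reported alongside. Inference is large-sample Wald z — no
  Satterthwaite/Kenward-Roger correction and no multiplicity adjustment —
  a documented limitation; the type-I simulation shows the joint test is
  close to nominal for worker-level determinants at the study size.
* **Pivot models.** Three more fits with the same structure, one per
  behaviour's first pivot coordinate; the SB-pivot model is algebraically
  identical to Model 1's ilr1 equation (asserted to 1e-8 in tests). Slopes
  carry the %-change translation.
* **Prediction curves.** For a chosen continuous determinant, fitted
  (ilr1, ilr2) are evaluated along a grid (default: the observed range)
  with all other covariates at sample means/modes and random effects at
  zero, then mapped back through the inverse ilr transform. Grids outside
  the observed range warn rather than fail.

## The synthetic generator

The generator reproduces the *design* of the motivating study, not any
worker's data. Defaults: 16 institutions; teams per institution uniform on
{4, 5} (~72 teams); workers per team 2/3/4 with probabilities
0.60/0.35/0.05 (~176 workers); 1–5 measured days per worker with mean 3.3;
daily work hours lognormal around a geometric mean of 6.61 h with log-SD
0.25 (chosen so a small share of days falls under the 4-h validity bound
and the filter has work to do).

Outcomes are generated on the ilr scale per coordinate as grand mean +
Σ β_d (x_d − centre_d) + institution + team + worker effects, all Gaussian,
with default variances 0.079 (worker), 0.0017 (team), 0.0021 (institution)
per coordinate and default effects β = −0.03 (physical exertion) and +0.03
(max pain intensity) on ilr1 only; no effects are placed on ilr2 because no
coordinate-resolved magnitudes are available for it. Covariates are centred
at their configured population means so the grand-mean composition
(0.4767, 0.4000, 0.1233) is the composition of an average worker. Day-level
measurements add mean-zero Gaussian noise (SD 0.1 per coordinate, a
placeholder — between-day within-worker variability is not an estimated
quantity) around the worker value.

Determinants are drawn independently (published information is marginal
only; no copula). Continuous determinants use truncated normals inside
their instrument ranges, with underlying parameters moment-matched so the
*truncated* mean equals the published mean exactly — naive truncation would
shift, e.g., mean age by more than a year. The SD is matched as closely as
the family allows; for pain interference (mean 3.5, SD 6.6 on 0–28 days) no
truncated normal attains that overdispersion (the achievable SD is ≈3.5),
which the mean-based convergence tests tolerate and real zero-inflated pain
data would not share. Binary determinants are Bernoulli at the published
proportions (female 84.3%, pedagogue 56.7%, public institution 62.5%).
Missingness is masked after outcome generation (hence MCAR and
non-informative) at a per-cell rate of 0.0125 on the 11 worker-level
determinants, reproducing in expectation the observed complete-case
attrition from ~178 to ~155 workers.

What passing tests therefore show: the pipeline recovers the parameters of
a correctly specified hierarchical Gaussian ilr model at the study's size
and noise levels. What they cannot show: robustness to the features the
generator omits — correlated determinants, informative missingness,
zero-inflated pain scores, day-of-week structure, or non-Gaussian
behaviour compositions.

## Replicated validation studies

`codawork.montecarlo` (used by tests and `scripts/acceptance.py`):

* **Variance recovery** — 50 study-sized replicates; the mean worker-level
  contribution lands in the low-to-mid 90s (%), consistent with the
  dominant worker-level share the design generates. Team/institution
  estimates at near-zero truth are boundary-truncated, so their replicate
  means sit slightly above truth — inherent to non-negative REML.
* **Effect recovery** — 50 replicates at 50×5×4 = 1000 workers without
  missingness; the mean exertion coefficient on ilr1 is unbiased to within
  Monte-Carlo error.
* **Type-I error** — 500 study-sized null replicates (all β = 0, default
  missingness, complete-case applied); rejection rate of the joint test for
  a worker-level determinant is close to the nominal 5%. Replicates whose
  random draw makes a determinant constant (e.g. all 16 institutions the
  same type, probability ≈0.1% per replicate) cannot identify every effect;
  they are excluded from the denominator and counted.

Replicate counts balance Monte-Carlo error against runtime on a single CPU;
replicate seeds are spawned from one base seed, so every study is exactly
reproducible.

## Numerical choices and degenerate inputs

* Closure tolerance 1e-12; ilr round-trip verified to 1e-10 on random
  compositions.
* All-zero duration vectors, negative durations, non-positive parts and
  non-finite coordinates raise typed errors; zeros must be replaced before
  transforming.
* REML convergence: criterion tolerance ~1e-10, deterministic ANOVA-type
  initialisation; non-convergence raises an error carrying the evaluation
  trace.
* Rank-deficient fixed designs are refused with the collinear columns
  named; constant determinants are the typical cause.
* Dataset CSVs are validated on read: duplicated worker ids, unknown day
  workers and non-numeric cells in numeric columns raise errors naming the
  offending row/column; missing cells stay missing.
* Reports avoid timestamps, so a config + seed reproduces a byte-identical
  bundle (asserted in tests).
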