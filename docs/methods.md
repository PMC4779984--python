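# Methods

## The model and its assumptions

`cqplan` treats a quantification cycle as the sum of a stratum mean and
independent Gaussian stage effects,

    Cq_ijk = μ + a_i + b_j(i) + c_k(ij),

where the indices run over RNA extractions (i), RT reactions within an
extraction (j) and qPCR wells within an RT (k). The model is defined
*within* a single treatment group — one subject, tissue and gene — so
strata are always estimated separately; pooling subjects into one
stratum is deliberately not offered, since subjects would add a fourth
nesting level the model does not have. Averaging the per-subject SD
estimates across subjects (`NestedCqResults.mean_over_subjects`) is the
supported way to combine replicate subjects.

Assumptions worth stating: effects are Gaussian on the Cq scale (Cq is
already a log-scale quantity, which makes this reasonable for
well-behaved assays), homoscedastic within a stratum, and independent
across levels. Missingness is ignorable (complete-case analysis); no
imputation is attempted.

## Estimation

Estimation is method-of-moments nested ANOVA for the unbalanced
fully-nested random model — the computation performed by classical
nested variance-component routines (e.g. SAS's PROC NESTED), not REML.
Type-I nested sums of squares are formed from group means; expected
mean squares use coefficients computed from the realized group sizes
(`n_ij` wells in RT j of extraction i):

    E[MS_qpcr]     = σ_k²
    E[MS_rt]       = σ_k² + c1 σ_j²
    E[MS_sampling] = σ_k² + c2 σ_j² + c3 σ_i²

with `c1 = (N − Σ_i(Σ_j n_ij²)/n_i·)/(Σ_i b_i − a)`,
`c2 = (Σ_i(Σ_j n_ij²)/n_i· − Σ n_ij²/N)/(a − 1)`,
`c3 = (N − Σ n_i·²/N)/(a − 1)`. For a balanced a×b×n design these
reduce to (n, n, bn) — (3, 3, 12) for the bundled pilot's 4×4×3
layout. The triangular system is solved bottom-up using the *raw*
(possibly negative) moment solutions; negative final estimates are then
truncated to zero and recorded per level in `truncated`.
`truncate=False` preserves raw values — the right mode for bias
diagnostics, since the raw variance estimator is unbiased and
truncation trades a boundary artifact for upward bias.

Numerical conventions: sums of squares below 1e-12 cycles² are treated
as exactly zero (guards against floating-point cancellation on
constant data); a level with zero degrees of freedom is flagged
non-estimable and reported as NaN rather than guessed; replicate
indices are nominal, and all estimates are invariant to renumbering
(property-tested).

Two totals are reported side by side and labeled: the quadrature
combination of the three step SDs (the model-based total noise of one
reading) and the empirical pooled SD of all readings in the stratum.
They agree only to the extent the model fits; published pilot tables
can additionally fold between-subject spread into their observed
totals, which is why the bundled preset carries the observed totals as
a separate field rather than deriving them.

## Planning calculus and the optimizer

The expected variance of a group-mean Cq under a balanced plan divides
each step's variance by the number of independent realizations of that
step and the whole technical term by the subject count; an optional
between-subject variance component (default 0) joins the subject-level
division. Step-noise inputs must declare their scale (`sd` inputs are
squared on ingest; `variance` inputs pass through) and the declaration
is echoed in every report — reproducing widely circulated planning
tables requires feeding the tabulated step values in as
variance-scale, and the explicit declaration keeps that choice honest.

`optimize_plan` enumerates every balanced integer plan whose total cost
fits the budget (upper bounds per level derived from the budget and
unit costs, or given explicitly; a level with zero marginal cost
requires an explicit cap). `min_subjects` defaults to 3: fewer than
three biological replicates per condition is below accepted practice,
and without the floor the optimizer will happily spend the budget on
two heavily-replicated subjects. The default is overridable and echoed
in reports.

Plans whose predicted variances differ by less than `variance_tol`
(default 0.005 cycles², i.e. half a unit in the second decimal place)
are treated as tied, and ties resolve to the cheaper plan, then the one
with fewer qPCR reactions per condition, then lexicographically. The
rationale: pilot variance components carry far more than 1% relative
uncertainty, so a predicted-variance edge in the third decimal place
should never buy more lab work. With the default tolerance the
optimizer prefers, among near-equal plans, the one a practitioner
would actually run; `variance_tol=0` gives the strict mathematical
minimizer. (In the README's budget example the strict minimizer is
3×3×2×2 at 0.0722 while the tolerance rule selects 3×4×1×2 at 0.0733 —
equal cost, 12 fewer reactions per condition, indistinguishable
precision.)

## The simulator

`simulate_stratum` / `simulate_study` draw the model exactly: Gaussian
effects per level, summed, with optional MCAR drop-out (each record
independently missing with probability `missing_rate`, kept as an
explicitly missing row). One `numpy.random.default_rng` seed drives an
entire study, so equal seed means byte-identical output. The bundled
`pilot_study_specs()` preset emulates a real blueberry pilot: nine
(tissue, gene) strata with published mean Cq and step SDs, two
subjects, 4 extractions × 4 RTs × 3 wells each (864 reactions total).

What the simulator does *not* emulate: amplification-efficiency
differences between assays, inhibitor effects, heteroscedasticity
(noise growing near the detection limit), non-Gaussian tails, or
informative missingness (failed wells are in reality more likely at
high Cq). Passing parameter-recovery tests on simulated data therefore
shows the estimator is correct *under the model*, not that real pilot
data satisfy the model.

## Monte-Carlo recovery, and how it is aggregated

Recovery tests simulate many 4×4×3 strata at fixed step SDs and
re-estimate. Because the top level has only 3 degrees of freedom, the
per-replicate *SD* estimate is strongly Jensen-biased (the mean of
√v̂ sits ~20% below the true SD at these settings even though v̂ is
unbiased). Recovery is therefore judged on the variance scale: the
recovered SD is defined as the square root of the mean estimated
variance across replicates, which is the statistically correct way to
pool variance-component estimates. At 500 replicates this recovers
step SDs of (0.45, 0.73, 0.32) within a few percent.

## Problem sizes used in checks

The test suite and acceptance script run at desk scale: single strata
of 48 records, full simulated studies of 864 records, Monte-Carlo
loops of 40–500 strata, one large calibration stratum of 400 000
records, and exhaustive plan enumerations of at most a few thousand
candidate plans. The whole suite completes in well under a minute.

## Known limitations

- No confidence intervals on variance components, and no REML or
  Bayesian alternatives: the estimator is deliberately the classical
  moment method.
- Only balanced plans are enumerated; unbalanced allocations (e.g.
  extra wells for one extraction) are out of scope.
- The 3′:5′ integrity ratio helper implements the comparative-Cq
  computation only; efficiency-corrected variants exist but are not
  bundled.
- Costs are linear in counts; volume discounts or per-plate step costs
  must be approximated by the per-unit model.
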