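# Methods notes

## Model and assumptions

The 2-HT eyewitness identification model is a binary-tree MPT over the six
outcome categories of a lineup task (suspect ID / filler ID / rejection ×
culprit-present / culprit-absent). Detection is discrete ("high threshold"):
with probability *dP* the witness detects the culprit's presence and always
identifies him; with probability *dA* the witness detects the culprit's
absence and always rejects the lineup. When neither detection state is
reached, selection is driven by lineup unfairness (*b*) or guessing (*g*),
and a guessing-based selection hits the suspect with the known sampling
probability *c* = 1 / lineup size. All four parameters are probabilities in
the closed interval [0, 1]; boundary values are legal (fair lineups really
do produce *b* = 0).

Assumptions the analysis inherits:

- **Independence of decisions.** The likelihood is product-multinomial over
  conditions × lineup types. When participants contribute several
  decisions (the replication contributes four per person) these are treated
  as independent; within-participant dependence is not modelled.
- **Known constant *c*.** The guessing split is fixed by the lineup size,
  not estimated. A proper position randomization is assumed, which also
  makes *c* independent of the instruction manipulation.
- **Aggregation.** Counts are aggregated over suspect positions and
  participants; no hierarchical (participant-level) extension is provided.

## Suspect constant convention

`LineupDesign(mode="paper")` (the default) rounds 1/lineup size to five
decimals — 0.16667 for six-person lineups — matching the convention of the
multiTree analyses the fixtures were originally analyzed with, so fitted
statistics are comparable digit for digit. `mode="exact"` uses 1/6. The
difference propagates into category probabilities with a multiplier ≤ 1,
i.e. at most 4 × 10⁻⁵, and never changes any reported statistic at two
decimals (the `replicate --mode exact` report confirms this at run time).

## Estimation

- **Primary optimizer: EM.** The E-step distributes each observed category
  count over the latent branches ending in that category; the M-step
  re-estimates each free parameter as expected successes over expected
  traversals, pooling across the conditions an equality constraint joins.
  Box constraints hold by construction and boundary solutions are reached
  smoothly.
- **Restarts.** One central start (all parameters 0.5) plus `n_restarts`
  (default 10) seeded uniform draws on (0.02, 0.98); best log-likelihood
  wins, ties to the lowest restart index. The likelihood surface of this
  small model is well behaved — restarts are cheap insurance against
  boundary-induced local optima, and simulation experiments default to the
  single central start for speed.
- **Convergence.** Absolute log-likelihood change < 1e-10 (default) or
  10,000 iterations; non-convergence is reported in the result object, not
  raised.
- **Cross-check.** `method="lbfgs"` maximizes the same likelihood with
  box-constrained L-BFGS-B; the suite verifies agreement within 1e-6 in
  log-likelihood on 100 simulated datasets.
- **Goodness of fit.** G² = 2 Σ obs·ln(obs/expected) with 0·ln(0/e) := 0,
  df = 4·(#conditions) − (#free parameters), p from the central χ² upper
  tail. Identical (within 1e-8) to 2·(logL_saturated − logL_model).
  Note the *unrestricted* 2-HT model (df = 0) is saturated only where an
  interior solution exists; real tables can push *b* to the boundary and
  leave df = 0 with G² > 0.
- **Standard errors.** Square roots of the diagonal of the inverse expected
  Fisher information at the MLE (category-probability Jacobian by central
  differences, step 1e-6, one-sided at the boundary). Parameters estimated
  on the boundary are flagged: their SEs come from the unconstrained
  information matrix and standard asymptotics are distorted there. Singular
  information falls back to a pseudo-inverse with a flag. Published SEs for
  the fixtures are treated as soft references since the original tool's SE
  convention at the boundary is not documented.
- **Nested tests.** ΔG² = G²(restricted) − G²(base) with Δdf the number of
  free parameters removed; p from central χ²(Δdf). Tiny negative ΔG² (<
  1e-6 in magnitude) from finite stopping rules is clamped to zero and
  marked; anything more negative raises, since it means the base fit was
  not at the global optimum. No multiplicity correction is applied across
  the dP and g tests; both run at α = 0.05.

## Sensitivity and power

`sensitivity_w(alpha, power, n, df)` solves
`P(χ²(df, λ) > χ²₁₋α(df)) = power` for the noncentrality λ* (Brent's method
on the noncentral-χ² tail) and returns w = √(λ*/n); `power_of_test` is its
inverse. n counts identification decisions (participants × lineups). The
default df is 1, the single-parameter restriction actually tested; at the
replication's inputs (α = β = 0.05, n = 1420) both df = 1 and df = 2 round
to w = 0.10, so the choice is not result-critical.

## Synthetic data

`GeneratingScenario` + `simulate` draw one multinomial per condition and
lineup type from the model's category probabilities — exactly the sampling
scheme the likelihood assumes. The default scenario mirrors the replication
design: two conditions, six-person lineups, 366/366 and 344/344 CP/CA
decisions. Its generating parameters are the full-precision MLEs of the
base-model-plus-equal-dP fit to the packaged replication table, computed on
first use: that keeps dP, b and dA shared across conditions with only
guessing g differing — the structure the replication design implies under
the no-detection-effect hypothesis — and avoids hard-coded guesses for
parameters whose point values were published only graphically.

What the generator deliberately does *not* emulate: participant-level
dependence between a person's four decisions, the sequential photo-by-photo
decision process, instruction lockout mechanics, and confidence ratings.
Passing recovery and calibration tests therefore validate the estimator
under the model's own assumptions; they cannot detect violations of the
independence assumption in real data.

`recovery_experiment` aggregates simulate→fit replicates into per-parameter
bias, RMSE, boundary-fit fraction and ΔG²-test rejection rates, excluding
(and counting) unconverged replicates; summaries from fewer than 30
replicates carry a low-precision flag.

## Problem sizes used in the checks

The statistical guarantees are exercised at sizes chosen to make Monte-Carlo
error small relative to the tolerance being checked: type-I calibration of
the ΔG² test uses 2,000 replication-scale datasets (binomial SE ≈ 0.005
around 0.05); large-sample recovery bias uses 40 replicates at 10⁵
decisions per tree; the √n RMSE-decay check uses 30 replicates at each of
n = 10³, 10⁴, 10⁵; optimizer cross-checks use 100 simulated datasets; the
normalization property uses 10⁶ random parameter draws.

## Known limitations

- Only the 2-HT lineup tree topology is implemented; arbitrary MPT
  structures are out of scope. Unfair-lineup designs with condition-specific
  *b* are expressible through the restriction system, but no dedicated
  inference about lineup fairness is provided.
- SEs at boundary estimates are reported with a caveat flag rather than via
  a boundary-corrected (mixture) null; p-values likewise use the central χ²,
  matching standard MPT practice.
- No Bayesian/hierarchical estimation, no confidence-rating or ROC
  analyses, and no information-criterion model selection.
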