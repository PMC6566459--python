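# Methods

## Setting and model

A two-arm randomized trial (treatment `U=1`, control `U=0`, `n` subjects per
arm) measures a continuous baseline biomarker `X` and a normal outcome `Y`.
The generating model is

    Y = β0 + β1·U + β2·f(X) + β3·U·f(X) + ε,      ε ~ N(0, σ²),

with `f` a shared prognostic/predictive shape: a step indicator `1{X ≤ γ}`
(decreasing), its complement (increasing), linear trends `1−X` / `X`, or an
indicator of the central band `(0.5−γ/2, 0.5+γ/2]` for the
"intermediate-peak" misspecification scenario.  The band variant is our
interpretation of "largest effects at intermediate biomarker values"; it is
centred so that its prevalence remains `γ`, keeping the scenarios
comparable across shapes.  `β2` moves the outcome in both arms (prognostic
effect), `β3` modifies the treatment effect (predictive effect).

Simulated trials allocate exactly `n` subjects per arm; the biomarker is
i.i.d. uniform on `[0, 1]` and independent of arm.  Subgroup sample sizes
are therefore random, which is essential: the realized per-arm counts (and,
under a prognostic effect, the subgroup variances) drive the correlation
structure of the tests.

## Hypotheses and statistics

For pre-specified increasing thresholds `q1 < … < qK`, the nested
biomarker-positive subpopulations are `S+(qk) = {i : xi ≤ qk}` (membership
inclusive at the threshold; with `qK` equal to the biomarker maximum the
last test is the full-population test).  Each `H0k: δ(qk) ≤ 0` with
`δ(qk) = μt(qk) − μc(qk)` is tested one-sided against `δ(qk) > 0` using:

- pooled-variance two-sample t statistics (df `nt+nc−2`); Welch statistics
  are deliberately not offered because the boundary theory assumes a common
  within-subgroup variance across arms,
- known-variance z statistics (validation oracle),
- biomarker-adjusted regression statistics from the within-subgroup fit
  `Y = b0 + b1·U + b2·X + ε` (df `nt+nc−3`, observed information
  `1/Var(b̂1)`), or
- weighted inverse-normal combination statistics over the disjoint slices
  `S+(q_{k−1}, q_k]`:
  `C(qk) = Σ_{m≤k} √wm Φ⁻¹(1−pm) / √(Σ_{m≤k} wm)` with slice weights
  `wm = (1/nt + 1/nc)⁻¹` and one-sided slice t-test p-values `pm`.  The
  typeset source of this statistic is ambiguous; we use the canonical
  standardized form, whose unit-variance and `√(Ij/Ik)` correlation
  contracts are verified by simulation tests.  The first slice's lower edge
  is `−∞`, so the construction works on any biomarker scale.

## Critical boundaries

Under the global null the statistics are (asymptotically) multivariate
normal; boundaries `cα(qk)` must satisfy
`1 − Φ_{0,Σ}(cα(q1), …, cα(qK)) ≤ α`.  Σ is built four ways:

- **equal-variance**: entry `√[(1/nt(qk)+1/nc(qk)) / (1/nt(qj)+1/nc(qj))]`
  for `j<k` — the classical group-sequential information ratio, valid when
  the outcome variance is constant across subpopulations;
- **variance-adjusted plug-in** (default for the adjusted t-test): the
  equal-variance entry times the pooled-SD ratio `σ̂(qj)/σ̂(qk)`
  (simplified form, assuming equal variances across arms within a
  subgroup), or the general per-arm-variance form; sample variances are
  plugged in per dataset;
- **information-based**: `√(Ij/Ik)` from observed information (regression,
  inverse-normal cumulative weights);
- **general-subgroup**: for arbitrary interval-union subgroups `Bk`, the
  entry uses the pairwise-intersection counts and variances; disjoint sets
  get correlation 0.  On nested sets this reduces exactly to the per-arm
  nested form (tested algebraically).

**Families.**  Pocock-type boundaries use a single common `c` (the default,
matching the simulation study); O'Brien-Fleming-type boundaries use
`ck = C/√(Ik/IK)`.  In both cases the level equation is solved to 1e-8 on
`c`, bracketed by the unadjusted and Bonferroni quantiles.  For t-based
procedures the normal-scale boundary is mapped to the t scale by quantile
substitution `Ψ_df⁻¹(Φ(c))` with df equal to the subgroup's own degrees of
freedom (`nt+nc−2`, or `nt+nc−3` for the regression procedure) — this is
what lets subgroups of very different sizes carry different df.

**Numerics.**  Nested designs produce product-form ("Markov") correlation
matrices `Σjk = uj/uk`; for these the joint lower orthant probability is
computed by the classical group-sequential recursion, integrating each
stage by Gauss–Legendre quadrature on `[−7.5, ck]` (64 nodes by default,
raised adaptively to ≥18/s when the narrowest conditional kernel
`s = √(1−r²)` between adjacent stages gets small, capped at 1025; stages
with `r ≈ 1` are merged exactly).  Absolute error is below 1e-9 across a
random battery of profiles, at ~0.1 ms per evaluation.  General matrices
fall back to scipy's
Genz-type randomized-QMC integrator with a fixed internal seed, so every
boundary is reproducible.  The two routes are cross-checked against each
other in the test suite.  Plug-in covariance matrices that come out
slightly non-PSD are repaired by eigenvalue clipping and re-standardization
(with a warning); monotone product-form matrices are PSD by construction
and skip the check.  A non-monotone plug-in SD profile (possible in small
samples) would produce correlations above 1; entries are then clipped and
repaired and the fast path is not used.

## Procedures

`sidak` (per-test level `1−(1−α)^{1/K}` on t quantiles), `z_gs` (t
statistics against the normal-scale equal-variance boundary — the liberal
"z-test"), `t_gs` (same boundary after quantile substitution), `adjusted_t`
(variance-adjusted covariance + substitution), `regression`,
`inverse_normal`, and the `full_population` single t-test comparator.  All
are single-step; strong FWER control of the level-controlling procedures
follows from the closed testing principle (restricting to any hypothesis
subset only enlarges the remaining rejection regions — property-tested).
Sequentially rejective improvements are out of scope.

Adjusted p-values are the smallest `α` at which a hypothesis is rejected,
found by bisection on `α` (tolerance 1e-6) and floored at 1e-5: below that
the level equation would require tail probabilities beyond the integration
accuracy, and a smaller reported value would be spurious precision.

**Degenerate subgroups** (an arm with fewer than 2 members, or zero pooled
variance): in analysis mode an error instructs the user to merge
thresholds; in simulation mode the affected hypotheses are treated as not
rejected and the events are counted and reported.  This is conservative
and keeps the estimated FWER valid.  For the inverse-normal procedure a
degenerate slice poisons every union containing it (those hypotheses are
not rejected and counted); remaining computable hypotheses are tested
jointly at the full level, which again cannot inflate the FWER.

## Monte-Carlo engine

Replicate `r` of a run with root seed `s` uses `default_rng([s, r])`: each
replicate is reproducible in isolation and results are invariant to
execution order and parallelism.  Boundary root-solves are memoized across
replicates, keyed by the realized subgroup counts (plus pooled-SD ratios
rounded to 0.01 for the adjusted t-test, or information fractions rounded
to 0.002 for the regression/inverse-normal procedures — the boundary error
induced by the rounding is O(1e-3) on `c`, invisible at simulation
precision), and warm-started from the previous solve.

Default replicate count is 10^4 (the original study used 5·10^5); at 10^4
the Monte-Carlo standard error of a rate near 0.025 is ~0.0016 and near 0.9
is ~0.003, so every comparison in the tests is stated as a multiple of the
reported MC SE, never as an absolute reproduction of smooth published
curves.

`sample_size_search` brackets the target on integer `n`, proposing
candidates by probit-scale false position with midpoint safeguards and
evaluating each candidate's disjunctive power with common random numbers
(the same replicate seeds for every `n`), which keeps the empirical power
curve essentially monotone; it reports the power estimates straddling the
target and errors out if the bracket does not straddle it.  Because the
Monte-Carlo noise of the located edge is roughly one subject per
(power-SE / power-slope), an optional refinement stage re-estimates the
sizes adjacent to the edge at a higher replicate count — replicates are
index-seeded, so refinement simulates only the additional indices and
pools them with the first-stage estimates.  The simulation-based
sample sizes for the adjusted t-test (K=4, step model, 1-SD subgroup
effect, power 0.9) land at 54 per group for γ=0.5 and 180 for γ=0.2, with
an expected ±1–2 subject wobble from MC noise at the search edge.  The
analytic `analytic_two_sample_n` uses the exact noncentral-t power
(df `2n−2`, noncentrality `d√(n/2)`), giving 86 (effect 0.5) and 527
(effect 0.2) per group.

## What the generator does and does not emulate

The synthetic generator reproduces the simulation study's conditions:
equal arms, uniform biomarker, normal errors, unit σ, step/linear/peak
effect shapes, thresholds at quantiles `k/K`.  It does not emulate
non-uniform biomarker distributions, non-normal or heteroscedastic errors
beyond the subgroup-mixture mechanism, unequal randomization, dropout, or
measurement error in the biomarker.  Passing tests therefore demonstrate
correctness of the procedures under the stated model, not robustness of
real-data conclusions; the analysis-mode CLI accepts any user CSV but the
operating characteristics quoted here apply to the simulated conditions.

## Design choices taken where the design was open

- Arm allocation fixed (not Bernoulli): subgroup imbalance comes from the
  biomarker alone.
- Threshold membership inclusive (`x ≤ q`); slice intervals half-open
  `(q_{k−1}, q_k]`.
- One-sided α = 0.025 throughout; Pocock-type equal critical values as the
  default family.
- The `z_gs` procedure follows the simulation operationalization: t
  statistics compared with normal-scale boundaries (no variance is truly
  known in practice); true z statistics with known variances are available
  separately as the `z_known` validation oracle.
- Fixture datasets are generated, not stored; the degenerate fixture's
  manifest records a data-derived threshold that isolates a single subject
  so the documented handling triggers by construction.

## Known limitations

- Normal outcomes only; no survival/binary endpoints.
- Single-step decisions plus adjusted p-values; no step-down shortcuts.
- The regression procedure's boundary assumes a common residual variance
  across subpopulations and is anti-conservative under step-type
  misspecification (visible in the FWER grids) — this is a property of the
  method, not a defect of the implementation.
- Boundary families beyond Pocock/O'Brien-Fleming (alpha-spending,
  futility) are not implemented.
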