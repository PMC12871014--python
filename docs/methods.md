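# Methods

This note records the statistical model, the numerical conventions, and the
design choices behind the package, at the level of detail a maintainer or a
reviewer of a trial analysis plan would need.

## Trial model and notation

A two-stage adaptive seamless design with G treatment arms (g = 1..G) and a
shared control (g = 0).  Stage 1 randomizes N_{g,1} subjects per group; at
the interim analysis a pre-specified rule selects the arm(s) carried into
Stage 2, which randomizes N_{g,2} subjects per remaining group.  The
short-term endpoint is a binary response observed a fixed landmark time
(default 0.5 years) after entry; the confirmatory endpoint is overall
survival, compared by the unstratified log-rank test in score form: u is the
observed-minus-expected control-arm death count under the hypergeometric
null, V the hypergeometric variance sum (with the standard multiple-death
tie correction), Z = u/√V, p = 1 − Φ(Z).

Sign convention: u counts control-arm excess deaths, so treatment
superiority gives Z > 0 and a small one-sided p.  This makes the rejection
region "small p" coherent throughout; swapping arm labels negates u and Z
exactly.  Ties between a death and a censoring at the same time are resolved
deaths-first (the conventional risk-set rule; required for agreement with
standard log-rank implementations, which the test suite verifies against
lifelines to 1e-8 on the chi-square scale).  A comparison with zero events
returns u = 0, V = 0, Z = 0, p = 0.5 with a warning — an uninformative
comparison, not an error.  The score-scale effect estimate u/V is exposed on
the result object for completeness but feeds no decision.

## The conventional (combination-test) analysis

Stagewise one-sided p-values are combined with the weighted inverse-normal
rule C(p1, p2) = 1 − Φ(w1 Φ⁻¹(1−p1) + w2 Φ⁻¹(1−p2)), w1² + w2² = 1, and the
selected arm's hypothesis is rejected only if every intersection hypothesis
containing it is rejected at level α (closed testing).  Choices made where
the convention leaves latitude:

* **Stage-1 intersection p-values.**  "Dunnett" uses the exact
  equicoordinate probability of |I| equicorrelated standard normals at the
  observed max Z; "Holm" uses the closed-testing shortcut factor |I|;
  "Bonferroni" uses the single-step factor G for every intersection.  These
  operationalizations give the classical per-dataset rejection ordering
  Dunnett ⊇ Holm ⊇ Bonferroni, which the tests assert.
* **Dunnett correlation.**  With equal allocation, score statistics sharing
  the control arm have pairwise correlation ≈ 0.5; rho defaults to 0.5 and
  is configurable.  The equicoordinate probability is computed by
  deterministic adaptive quadrature over the shared latent factor
  (∫ φ(x) Φ((c − √ρ x)/√(1−ρ))^k dx), validated against Monte-Carlo in the
  tests; no randomized MVN CDF is involved.
* **Stage 2.**  The Stage-2 p-value of every intersection is the selected
  arm's Stage-2 p-value (Stage-2 statistics use Stage-2 subjects only).
  When more than one arm is selected, the package extends the comparator by
  applying the same adjustment family to the Stage-2 statistics of the
  selected arms inside the intersection (factor |I ∩ l| for
  Bonferroni/Holm, equicoordinate MVN for Dunnett); this multi-arm Stage-2
  rule is the package's own reading, isolated in one function.
* **Numerical clamping.**  Φ⁻¹ arguments are clamped to
  [1e-12, 1 − 1e-12]; the clamp is invisible at any practical α and is
  flagged with a dedicated warning class (a Bonferroni p capped at 1.0
  clamps routinely and is silenced inside batch runs).

## The conditional randomization test

Stage-1 evidence enters as p_{k|Q}: the probability, over uniform
reallocations of the Stage-1 subjects to the fixed group sizes with all
outcomes held fixed, that the Stage-1 log-rank statistic of arm k is at
least the observed value, *given* that the re-applied selection rule
reproduces the observed selection event.  Conventions:

* The comparison Z⁽ⁱ⁾ ≥ z* is inclusive, with the observed statistic
  recomputed through the identical vectorized code path so float ties
  resolve consistently (a 1e-12 slack guards rounding).
* The observed allocation is **not** force-included in the Monte-Carlo sums;
  a zero numerator therefore yields p = 0 with a warning suggesting a larger
  M*.  No add-one smoothing is applied by default.
* Under the multi-arm rule the conditioning event is exact equality of the
  selected *set* (not membership of the target arm), which is strictly the
  event observed.
* The selection tie-break is re-drawn per rerandomization from the supplied
  generator, in exact mode too: the exhaustive pass enumerates every
  allocation once but realizes one tie-break per pattern.  Exhaustive
  enumeration is guarded at 10⁶ patterns; the count is the multinomial
  coefficient N₁!/∏ N_{g,1}!.
* Fewer than 50 event-matching rerandomizations triggers a coarseness
  warning; zero matches is an error carrying diagnostics.

The final test rejects H_k iff C(p_{k|Q}, p_{k,2}) ≤ α; with several
selected arms the combined p-values are tested with Bonferroni, step-down
Holm, or single-step Dunnett across the selected set.

The rerandomization loop is the hot path: assignments are generated in
batches, selection is applied vectorized, and the log-rank score is
evaluated for all batch rows simultaneously on a pre-sorted event table
(with a no-ties fast path, since continuous simulated times are almost
surely distinct).  One conditional p-value at N₁ = 150 and M* = 500 costs a
few milliseconds.

## Synthetic-data generator

Each subject carries a latent response time R and survival time D with
exponential marginals coupled by a Clayton copula,
S(t_R, t_D) = (S_R^{−θ} + S_D^{−θ} − 1)^{−1/θ}, Kendall's τ = θ/(θ+2).
Sampling uses the gamma-frailty construction (a shared Gamma(1/θ) frailty
mixing two unit exponentials); an independent conditional-inversion sampler
exists solely as a cross-check in the tests.  Hazards are parameterized from
design quantities: λ_D = −ln S_D(3)/3 from the 3-year survivor probability,
λ_R = −ln S_R(0.5)/0.5 from the response rate, so the landmark indicator
R > 0.5 has mean S_R(0.5) exactly.  The landmark tie R = 0.5 counts as
non-response (measure-zero; fixed for determinism).

Calendar geometry (defaults): Stage-1 entries uniform on [0, 1.7] years;
interim at 2.2 (every Stage-1 response observed); Stage-2 entries uniform on
(1.7, 5.0]; final analysis at 8.0 with administrative censoring — the unique
reading that gives the last Stage-1 entrant ≥ 6.3 years of follow-up and the
last Stage-2 entrant 3.0.  Accrual is uniform (a modelling choice; no
accrual distribution is implied by the design figures).  Stage-2 subjects
are generated after the selection and only for control plus the selected
arm(s); their response is recorded as missing because no analysis consumes
it.  The generator omits dropout, non-exponential hazards, other copula
families and covariate effects, so passing simulations demonstrate
operating characteristics under proportional-hazards exponential data with
Clayton dependence — not robustness to real-world departures from them.

Combination weights default to the fixed design pair (0.543, 0.839),
renormalized internally to satisfy w1² + w2² = 1 exactly; in the four-arm
configuration the weights are recomputed per trial from the expected event
counts implied by the calendar model and the realized number of selected
arms, using the control (null) hazard as the design-stage hazard.  The
closed-form expected-event count under uniform accrual and administrative
censoring is n(1 − (e^{−λt₀} − e^{−λt₁})/(λa)) with t₀/t₁ the
shortest/longest follow-up and a the accrual length.

## Experiment harness

Scenario grids are run with every method applied to identical datasets
within a cell (paired comparison), replicates seeded by
(master seed, experiment, cell, replicate) so results are order-invariant
and byte-reproducible.  The reported family-wise error under a global null
is P(reject any arm); per-arm and either-of-arms rates are tabulated
alongside with Clopper-Pearson 95% intervals.  The fixed-design comparator
enrols 100 subjects per arm uniformly over the full 5-year accrual window,
analyses at year 8, and adjusts its two pairwise comparisons with the
configured method (Dunnett by default).

Default problem sizes are a scaled-down profile — 1000 replicates and
M* = 500 (analysis-style conditional p-values use M* = 5000 by default) —
chosen so a full type-I-error or power cell completes in seconds while
keeping the binomial Monte-Carlo error around half a percentage point;
larger profiles are plain parameter changes.

## Known limitations

* Group-sequential early stopping and sample-size re-estimation are out of
  scope; the interim performs selection only.
* The multi-arm Stage-2 intersection rule in the comparator is a documented
  extension, not a published convention.
* Exact-mode conditional p-values are exhaustive over allocations but not
  over selection tie-breaks; with heavily tied response rates the exact
  value retains a small tie-break Monte-Carlo component.
* The conditional p-value's null uniformity is asymptotic in the Stage-1
  size; the suite checks it empirically at N₁ = 150.
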