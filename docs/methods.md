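# Methods

## The problem and the modelling frame

The package asks how two personality traits — extraversion (E) and
neuroticism (N) — jointly relate to loneliness (L) in adolescent cohorts, and
whether that relation is merely additive-linear or carries monotone
non-linearities (saturating or exponential trait effects) or genuine
interaction structure.  Rather than testing one model against a null, the
analysis poses a *complete candidate set* of hypotheses and lets an
information-theoretic comparison allocate relative evidence among them.

The global model is the full second-order polynomial in the centered traits,

    L_i = b0 + b1 E_i + b2 N_i + b3 E_i^2 + b4 E_i N_i + b5 N_i^2 + e_i,
    e_i ~ N(0, sigma^2),

and every hypothesis is a constraint system on (b0..b5): fixed zeros, linear
equalities and linear inequalities.  The catalogue contains 19 models: the
intercept-only null; three effect shapes (linear, saturating, exponential) for
each trait alone; the full 3×3 grid of two-trait shape combinations; two
one-parameter composite interaction surfaces (mutual compensation
`b0 + c (E − e_hi)(N − n_lo)`, c ≤ 0, and optimal constellation
`b0 + c (E − e_lo)(N − n_hi)`, c ≥ 0); and the unconstrained full model, in
which everything else nests.

Shape constraints are anchored at the *observed* extremes of the centered
traits (the "range box"), so a claimed monotone direction is guaranteed over
the whole region where data exist, not merely at the mean.  A saturating
extraversion effect, for instance, is `b3 ≥ 0` together with
`b1 + 2 b3 e_hi ≤ 0`: decreasing everywhere in the box, flattest at high E.
Directional (sign) inequality constraints leave their parameter free, so K —
the count used by the information criterion — is the number of free
coefficients plus the residual variance (plus the baseline-outcome slope in
the longitudinal analysis).  These counts reproduce every published K for
this catalogue (null 2; single-trait 3–4; two-trait 4–6; composites 3; full 7
cross-sectionally, 8 longitudinally).

## Preprocessing

All variables are mapped onto a common 1–7 metric by proportion-of-maximum
scaling (POMS), a linear map from the instrument's *theoretical* bounds —
theoretical rather than observed, because only theoretical bounds make the
transformed range exactly 1–7 regardless of sample.  Traits are then
mean-centered; outcomes are rescaled but never centered.  Both operations are
affine, so fit quality (R², likelihood ratios) is invariant to them — a
property the tests verify.

Influence screening fits the full polynomial by OLS on complete cases and
computes DFFITS, Cook's D and hat values (via statsmodels).  A row is an
influential case when its leverage exceeds 2p/n *and* at least one of
|DFFITS| > 2√(p/n) or D > 4/n fires (p = 6 design columns with intercept).
The joint rule reflects that influence = leverage × discrepancy; flagged rows
are reported, never silently removed.  The exact published screening rule for
this design is not available in text form, so this three-indicator joint rule
is the package's documented convention.

## Estimation

Each candidate is estimated by Gaussian maximum likelihood conditional on the
design.  Profiling out sigma^2 reduces the problem to least squares under the
spec's linear constraints.  The equality constraints (including fixed zeros)
are eliminated by a null-space reparameterization; the remaining
inequality-constrained convex QP is solved *exactly* by enumerating candidate
active sets and solving each KKT system directly, accepting the primal-feasible
point with nonnegative multipliers.  With at most four inequalities per model
the enumeration is at most 16 linear solves — deterministic, free of step-size
or convergence tolerances, and immune to the boundary stalls that
line-search methods exhibit on these problems (which is why an iterative
optimizer was not used).  When the unconstrained optimum is already feasible
it is returned as-is, so unconstrained fits equal the OLS solution to
numerical precision.  Active inequalities are reported; K is *not* reduced at
boundary solutions, matching the published K accounting.

Missing data: predictors and the baseline outcome are complete by
construction (rows violating that are dropped and counted at ingest).  Only
the follow-up outcome may be missing; such persons contribute no
conditional-likelihood term but remain in `n_obs`, the sample size used in
the AICc correction.  This matches the published AICc arithmetic, which
back-solves to the full baseline sample sizes (346 / 237), not the
complete-case counts.  With zero missingness the fit is exactly complete-case
OLS.

The nesting relation among the 19 feasible sets is decided by linear
programming: A nests in B iff every restriction of B is implied over A's
feasible set (each equality pinned, each inequality's maximum bounded).  A
syntactic zero-set rule would miss, e.g., that the null model nests in the
composite interaction surfaces.  The relation is invariant to the numeric
range-box anchors (tested on two distinct boxes), so it is computed once per
analysis mode and cached.

## Comparison

Models are ranked by AICc = −2LL + 2K + 2K(K+1)/(n−K−1).  Before weights are
computed, *redundant* models are pruned: processing candidates by increasing
K, a model is excluded when its log-likelihood gain over any retained model
nested in it is below 1.0 — extra parameters that buy almost no likelihood
only dilute the weights.  Akaike weights are computed over the retained set;
the 95% confidence set is the shortest AICc-ordered prefix with cumulative
weight above 0.95; evidence ratios are weight quotients.  Weights are
reported over the full retained set by default, with an optional column
renormalized within the confidence set (published tables exist in both
conventions).

A chi-square likelihood-ratio gate precedes all of this: the catalogue is
compared only when the full model beats the null at alpha = 0.05.  A failed
gate ends the analysis as a recorded decision — the behaviour a
high-stability, high-attrition longitudinal cohort actually produces.

## Response surfaces

When the full model earns a place in the confidence set it is interpreted via
response-surface methodology: a1 = b1 + b2 and a2 = b3 + b4 + b5 (slope and
curvature along E = N), a3 = b1 − b2 and a4 = b3 − b4 + b5 (along E = −N).
Grid predictions are masked to the convex hull of the observed (E, N) pairs —
the hull reproducibly captures the "interpret only where data live" purpose
that bag-and-fence plots serve graphically, without the depth-median
machinery.  Shape classification evaluates the partial slopes at the box
corners (they are linear in (e, n), so corners decide the box): one sign
everywhere gives a monotone label, with curvature opposing the slope
magnitude labelled saturating and reinforcing it exponential; a sign reversal
yields "non-monotone" plus the fraction of observed *persons* on each side of
the reversal (per-person rather than per-grid-area, since the substantive
claim is about people).  Stationary points are reported only when the
curvature determinant clears 1e-8.

## Power

A-priori power for the 5-df omnibus full-vs-null test is simulated: traits
bivariate standard normal with correlation r, outcome from a coefficient
pattern scaled so the population R² hits its target exactly — the scaling
uses the closed-form covariance of (E, N, E², EN, N²) under bivariate
normality (linear and quadratic blocks uncorrelated; quadratic block by
Isserlis' theorem).  Defaults: main-effects pattern b1:b2 = −1:1, 10,000
replicates, chi-square LR statistic (the pipeline's own gate), F available.
Because both statistics are monotone in the residual-sum-of-squares ratio,
the noncentral-F distribution with noncentrality nR²/(1−R²) gives the *exact*
analytic power for either via the mapping LR = n log(1 + df1 F / df2); the
simulation is checked against that oracle, not against an approximation.
Power is insensitive to how the pattern distributes R² across terms (tested),
which is what licenses reproducing published power claims without knowing the
original pattern.  One caveat on the oracle comparison: the oracle fixes the
noncentrality at its expectation, while the simulation redraws the design
each replicate; power is concave in the noncentrality at these levels, so the
Monte-Carlo estimate sits a couple of tenths of a percentage point below the
fixed-λ value (well within the 4-SE band the tests allow).

## Synthetic cohorts

The generator emulates the cohorts this analysis is designed for: traits
bivariate normal with default moments E 4.69/0.95, N 3.87/1.07, r = −0.31 on
a 1–7 scale; baseline outcome from any catalogue model on the centered traits
plus Gaussian noise (default residual SD 0.8, intercept 2.2); follow-up
outcome sharing the generating surface with an autoregressive residual
(default stability 0.5, putting marginal retest correlations in the published
0.47–0.71 band); follow-up dropout missing-completely-at-random at 18.21% or
45.57% (the two study attrition rates), with an optional
extraversion-dependent dropout for robustness experiments.  Defaults were
fixed from the published descriptives before any recovery experiment ran.

Two deliberate conventions: range-dependent composite surfaces are anchored
at the *realized* sample's centered extremes, and traits are centered at
sample means, so generating coefficients live on exactly the scale the
fitting stage estimates — otherwise extreme-order-statistic noise in the
anchors would contaminate parameter-recovery assessments.  Outcomes are
clipped to the 1–7 bounds by default (with the clipped fraction logged)
because real instruments are bounded; recovery experiments switch clipping
off, because truncation biases coefficient recovery and those experiments
validate the estimator under its own assumptions.  What the generator does
*not* emulate: item-level measurement error, floor effects in skewed
loneliness distributions, non-normal trait marginals, and informative
(outcome-dependent) dropout.  Green recovery tests therefore certify the
machinery, not the robustness of the substantive conclusions to those
features.

## Problem sizes used in the shipped experiments

Parameter recovery runs all 19 generators at n = 2000 with 200 replicates
(median absolute coefficient error < 0.05 everywhere; the worst case is the
intercept of the doubly-exponential shape model at ≈ 0.04).  Model recovery
for linear main effects runs n = 1000, 200 replicates.  The
recovery-improves-with-n property is checked on two representative generators
at n ∈ {200, 1000, 5000} with 12 replicates each, as fractions that may not
degrade beyond Monte-Carlo slack.  Type-I calibration of the LR gate uses
n = 500 with 5,000 replicates against the exact small-sample level.  The
shipped analysis drivers use 40 replicates per generator.  These sizes are
the package's choices for routine runs; all are parameters.

## Known limitations

* The likelihood is conditional on the design terms; a joint-normal FIML over
  all observed variables (as structural-equation software implements) could
  shift LL differences when follow-up missingness correlates with traits.
  Under the MCAR/complete-predictor contract here the two coincide.
* Robust (sandwich) standard errors are not implemented; they would not enter
  LL, AICc or weights, which is all the comparison consumes.
* The redundancy-pruning order (K-ascending, alphabetical within ties) is a
  determinism convention; other orders can retain a different near-redundant
  model when chains overlap.
* Shape labels at constraint boundaries (e.g. a curvature estimated exactly
  at zero) degenerate to "linear" by design; the active-constraint report on
  the fit is the authoritative record that a bound was hit.
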