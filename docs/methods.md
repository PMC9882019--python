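# Methods

## Model manifolds and evidence

A candidate explanation for a trial's point cloud is a family of isotropic
2D Gaussians (known σ) whose center μ(s) lives on a point, a straight
segment, or a circular arc. All one-dimensional manifolds are arc-length
parameterized, so |dμ/ds| = 1 everywhere. Consequences used throughout:

* the expected per-datum Fisher information is g = 1/σ², independent of
  position and curvature;
* the Jeffreys prior ∝ √g is uniform, w(s) = 1/Λ on [0, Λ];
* the observed per-datum information is
  h(s) = (1/σ²)(1 + (μ(s) − x̄)·μ''(s)), a data-dependent noisy version of g
  that deviates from it only through curvature (μ'' is the curvature
  vector; h ≡ g for segments).

Because the Gaussian family is a location family, all evidence quantities
depend on the data only through the centroid x̄ (plus an additive constant
carrying the scatter), which is what makes the batched implementations
cheap: a trial costs one projection and, for arcs, one quadrature.

The exact log marginal is computed in closed form for points and segments
(the likelihood is exactly Gaussian in s on a line, leaving a Φ-difference
for the domain truncation) and by adaptive Gauss–Legendre quadrature for
arcs (node doubling from 64 until successive estimates agree to 1e-8, in
log-space with max-subtraction; non-convergence at 4096 nodes raises with
diagnostics). The quadrature path also exists for segments and is used in
tests as the independent cross-check of the closed form.

## The evidence expansion

The log evidence is expanded around the (possibly clamped) maximum-likelihood
arc-length ŝ as maximum log likelihood plus four penalty terms:
dimensionality −(d/2)log(N/2π); volume −log∫√g ds; robustness
−½ log(h(ŝ)/g(ŝ)); and a boundary term
(N/2)‖l̂‖²_{h⁻¹} + log[Φ(z_hi) − Φ(z_lo)], where l̂ is the per-datum
likelihood gradient at ŝ, ‖l̂‖²_{h⁻¹} = l̂ᵀh⁻¹l̂, and
z = √(Nh)·(domain bound − s*) with s* = ŝ + h⁻¹l̂ the unconstrained
quadratic optimum. The boundary factor is the probability mass the Laplace
Gaussian leaves inside the parameter domain, so it is defined at every ŝ:
exponentially near zero deep in the interior, exactly −log 2 when the
optimum sits on an endpoint, and increasingly punitive as the data pull the
optimum outside. Writing it uniformly keeps the approximation continuous
through the interior/boundary crossing; a variant that applies the term
only at clamped optima would jump by log 2 there. A side effect worth
knowing: for small N the interior truncation mass is not negligible (that
is precisely why the expansion is *exact*, not asymptotic, for straight
segments), so "the boundary term vanishes at interior optima" holds only at
the exponential rate set by √(Nh)·distance-to-endpoint.

Degenerate trials — h ≤ 0 at ŝ, which happens when the centroid reaches an
arc's center of curvature — are flagged; the breakdown reports a non-finite
robustness term, regression designs drop such rows with a logged count, and
simulated FIA observers fall back to the maximum-likelihood score on those
trials so a choice is always produced. With the shipped geometry the
degenerate rate is ~0 (for a circle, h ∝ |x̄ − C|, which vanishes only at
the exact center).

All quantities are in nats; g and h are per-datum, with N appearing
explicitly in the terms.

## Task variants and calibration

The four shipped variants isolate one term each: point vs segment
(dimensionality), congruent segments offset horizontally so that almost
every centroid projects onto an endpoint of exactly one model (boundary),
short vs long segments (volume, length ratio 1:12 so the log-volume
difference is large enough to matter), and a straight segment vs a
three-quarter circular arc of equal length opening toward it (robustness).
Shapes sit symmetrically about the x-axis; per trial a fair coin decides
which shape is on top ("mirror randomization") and an independent fair coin
picks the generating shape; the latent center is drawn uniformly in arc
length (the Jeffreys prior) and N = 10 points are drawn around it.

The study-level design property is the *difficulty*, not the coordinates:
the observation noise σ of each variant is tuned by `calibrate_difficulty`
until ideal-Bayes observers beat maximum-likelihood observers by 1
percentage point of generative accuracy. The gap is non-monotone in σ
(zero for trivially easy and impossibly hard stimuli), so the calibration
scans a log-spaced grid, brackets the first upward crossing of the target,
and bisects; the Monte-Carlo evaluations use paired trials (both observer
strategies decide the same stimuli), which shrinks the gap's standard error
to the disagreement rate, about 0.1 pp at the default 60k-trial budget.
Geometries were chosen so the maximum achievable gap clears the 1 pp target
with headroom; for equal-length straight-vs-curved pairs this requires
substantial curvature (the arc's marginal must differ measurably from the
segment's where the posterior is uncertain), which is why the robustness
arc is a 270° "C" facing the segment. Its center of curvature lies on the
opposing model's side, the positive sign of the package's curvature
convention, and data falling between the shapes see h > 0 everywhere.

One regime note: the sign of the net complexity preference depends on σ
relative to the manifold lengths. The volume term −log(Λ/σ) is a *bonus*
when Λ < σ (a short segment then contains fewer than one distinguishable
distribution), so at the calibrated noise of the dimensionality variant the
exact-Bayes observer actually chooses the segment slightly more often than
the distance rule does. The classic picture — integration shifts choices
toward the simpler model — holds in the σ < Λ regime, which is where the
boundary-map analyses and the worked single-datum example live.

## Observers

The Noise-Integration-Noise observer processes each trial in three stages:
every observed point is corrupted by isotropic Gaussian sensory noise of
std ρ; a per-model score interpolates linearly between the maximum log
likelihood (integration strength 0) and the full log marginal (integration
strength 1); the choice is read out deterministically (temperature 0), or
through a softmax with the given temperature, followed by a uniform lapse
mixture. The two integration endpoints reproduce the maximum-likelihood
and exact-Bayes observers decision-for-decision, and the interpolation is
monotone trial-wise, which pins the family's behavior between them; the
linear-in-log-space rule is the package's design choice for the
intermediate regime. The posterior-sampling observer (choice probability
equal to the exact posterior) is the natural "relative sensitivity 1"
reference: its choice curve against the evidence difference is the unit
logistic.

Decision-boundary maps place all N points of a trial at a grid location
(the centroid is then the location itself) and Monte-Carlo the choice;
the 0.5-level is estimated per map column by a logistic fit along y.
Sessions are scored both against the generating shape and against the
maximum-likelihood solution; the latter is deterministic, so it upper-bounds
any observer's score in expectation.

## Hierarchical sensitivity estimation

Choices are regressed on a constant (up/down bias) and the up-minus-down
differences of the maximum log likelihood and the four evidence terms.
Within a single variant, the dimensionality and volume differences are
constant in magnitude and flip sign only with the mirror coin — and are
exactly proportional to each other in the dimensionality variant — so the
canonical fit pools the four variant groups into one population: each term
is then pinned by the group(s) where it varies independently, and
participant-level coefficients are partially pooled. Zero-variance
predictors within a given fit are dropped and reported as NaN.

The model is logistic with participant coefficients β_j ~ Normal(μ, τ)
componentwise, weakly informative priors Normal(0, 5) on μ and
half-Normal(2.5) on τ after scaling each predictor by its pooled standard
deviation; reported coefficients are back-transformed to nats, so a
likelihood coefficient of 1 with relative sensitivities 1 is literally the
FIA-posterior observer. Relative sensitivities are computed ratio-per-draw
(population-mean draws at the population level, coefficient draws at the
participant level), with draws excluded when the likelihood coefficient is
within 1e-3 of zero (counted; a warning attaches beyond 1%). The
lapse-extended model mixes the logistic with a uniform choice,
P = λ_j/2 + (1 − λ_j)·logistic, with logit(λ_j) pooled under a
Normal(−3, 1.5) population mean and half-Normal(1) scale — centered on
small lapse rates, as expected for attentive observers.

Sampling uses the package's HMC: vectorized chains, analytic gradients,
non-centered hierarchy, and τ = softplus(w) rather than exp(w) — the
half-Normal prior's curvature in the sampled coordinate is then bounded,
which removes the integrator instabilities an exp parameterization shows at
large τ. Warmup follows the standard three-phase schedule (step-size-only
buffer, doubling memoryless mass windows, settling buffer) with dual
averaging toward 0.9 acceptance; trajectories are 32–48 jittered leapfrog
steps, long enough to traverse the weakly identified predictor-collinearity
ridges. Defaults: 4 chains, 1000 + 1000 iterations. A fit is "converged"
when split-R̂ < 1.01 for all population-level and participant-level
parameters and no post-warmup divergence (energy error > 1000) occurred;
non-converged fits refuse to emit summaries unless forced. WAIC is computed
from pointwise log predictive densities streamed in draw chunks; model
comparisons use the paired pointwise difference and its standard error, and
verify both fits saw identical responses.

## Synthetic cohorts

Two planting policies: *logistic* draws each participant's coefficient
vector around planted population means and generates choices from the
regression model itself (exact ground truth, no model mismatch — this is
the parameter-recovery instrument), and *observer* draws observer
parameters from a truncated-Gaussian population and runs full sessions
(exercises the nonlinear stimulus-to-choice path). The human-like planted
regime uses relative sensitivities {dimensionality 4.66, boundary 1.12,
volume 0.23, robustness 2.21} around a unit likelihood coefficient, with
heterogeneity scales {0.96, 0.10, 0.12, 0.12}. Everything derives from one
master seed through spawned seed sequences, including sampler seeds, so
cohorts are bitwise reproducible.

## What the synthetic data does and does not emulate

The generator matches the experiment's structure — four variants, group
sizes, trial counts, Jeffreys-sampled latent centers, fair-coin generating
shape, mirror randomization — and the interchange schema, so the fitting
pipeline runs unchanged on real choice tables. It does not model session
effects, learning across blocks (the experiment's end-of-block feedback was
designed to minimize these), reaction times, stimulus rendering, or
dropout. Passing recovery tests therefore demonstrates inference
correctness under the stated generative assumptions, not robustness to the
ways human data violate them (beyond what the lapse model and the
observer-policy cohorts probe).

## Problem sizes used in the checked results

Calibration evaluates 60k paired trials per σ probe; the headline
accuracy-gap simulation uses 100 observers × 500 trials per strategy per
variant. Parameter-recovery checks run at 12 participants × 150 trials
(full study scale is ~50 × 500 per variant); reference bands and pipeline
demonstrations use 3–6 participants per variant. These sizes were chosen so
the complete suite reruns in minutes while leaving every recovery check
comfortably powered at its stated tolerance.

## Known limitations

* Only the three manifold kinds with closed-form projections are supported;
  d ≥ 2 families and non-Gaussian noise are out of scope.
* Model priors are fixed equal; the evidence comparison exposes no prior
  weights.
* The HMC uses a diagonal mass matrix; exactly collinear predictor pairs
  (by design present in the dimensionality variant) leave a correlated
  ridge that costs sampling efficiency, paid for with longer trajectories.
* WAIC is the only model-comparison criterion implemented.
* The human-data ingestion path expects tables already converted to the
  package's design schema; a converter for the deposited raw format has to
  be written against the deposit itself.
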