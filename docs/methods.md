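# Methods

`jointvisit` fits a shared-parameter joint model for three linked processes
observed on irregularly sampled longitudinal data: a Gaussian marker, the
visiting (observation) process that decides *when* the marker is measured,
and competing terminal events that end observation.  This note records the
model, the numerical choices, and the design decisions that were genuinely
open, along with what the synthetic-data generator does and does not
emulate.

## Model

**Marker.**  A linear mixed model
`Y_i(t) = X_i(t)'β + Z_i(t)'b_i + ε_i(t)` with `b_i ~ N(0, D)` (dimension
`q`) and `ε_i(t) ~ N(0, σ²)`.  The latent ("true") marker value is
`m_i(t) = X_i(t)'β + Z_i(t)'b_i` and its slope `m_i'(t)` uses the basis'
analytic time derivatives when available, otherwise central differences
with step `1e-5·max(1, |t|)`.  The preset basis `{1, log(t+1), (t/10)³}`
(time in years) is the shape used for square-root CD4 trajectories after
treatment initiation: fast early rise, saturation, late curvature.

**Visiting process.**  Either a proportional-hazards model for the gap time
`u` since the most recent visit,

    h_v(u) = h_v0(u) · exp[γ_v'X̄_v(t_ij) + φ_v'g_v{Ȳ(t_ij)}
                           + α_v1 m_i(0) + α_v2 m_i'(t_ij + u)],

or a proportional-intensity model of the same form on calendar time.
`X̄_v` and `g_v{Ȳ}` are fixed-length features of the visit and marker
histories (most recent observed value, previous gap, visit count, mean gap,
current visit time, baseline covariates), constant between consecutive
visits.  The final gap (last visit to end of follow-up) is right-censored.
Because the model conditions on the *observed* marker history as well as
the random effects, it does not assume conditional independence between
marker and visiting given `b_i`.  When `α_v1 = α_v2 = 0` visiting is
(completely) at random and the visiting block separates from the rest of
the likelihood.

**Frailty.**  Optional `w_i ~ Gamma(1/η, 1/η)` (mean 1, variance η)
multiplying the visiting hazard/intensity in both event and cumulative
terms; it is marginalised in closed form (gamma mixture of the Poisson-type
conditional likelihood), and `η` is estimated on the log scale.  The
alternative reading in which the frailty enters only the cumulative term
was rejected as non-standard.

**Competing risks.**  One proportional cause-specific hazard per cause on
calendar time with the same linear-predictor structure; cause code 0 means
noninformative right censoring.  `α_sk ≠ 0` makes marker missingness after
the event nonignorable.

**Baselines.**  All log-baselines are cubic B-splines.  Interior knots sit
at equally spaced quantiles of the observed gap times (gap scale) or
visit/event times (calendar scale); boundary knots at 0 and the observed
maximum; defaults of 3 interior knots for the visiting baseline and 1 per
cause.  Outside the boundary the *log*-baseline continues linearly
(continuous value and first derivative) so optimisation stays finite for
excursions beyond the knots.

## Likelihood and estimation

The observed-data likelihood per subject factorises as the marginal
Gaussian law of the marker vector times the integral, against the
marker-only posterior `b_i | Y_i ~ N(μ_i, C_i)`, of the conditional
visiting and event likelihoods.  We use the standard conjugate form
`C_i⁻¹ = D⁻¹ + Z_i'Z_i/σ²`, `μ_i = C_i Z_i'(Y_i − X_iβ)/σ²`; a
Bayes-identity unit test pins this down.  Marker marginal densities are
computed via Cholesky solves of the `n_i × n_i` covariance, never explicit
inverses.

**Time integrals.**  Cumulative hazards are integrated with a fixed
15-point Gauss–Kronrod panel per smooth piece.  Pieces are inter-visit
intervals *further split at interior spline knots*: a cubic B-spline is
only C² at its knots and a single high-order panel across a knot loses
five to six digits, which is enough to destabilise quasi-Newton line
searches.  With knot-splitting the panel error is at rounding level.

**Random-effects integral.**  Pseudo-adaptive Gauss–Hermite quadrature:
standard tensor-grid GH nodes recentred and rescaled by `μ_i` and a factor
`B_i` with `B_i'B_i = C_i⁻¹`, recomputed from the current `θ_l` at every
objective evaluation.  Default 7 nodes per dimension (343 for `q = 3`),
with tensor weights below 1e-10 pruned; a scrambled-Sobol QMC alternative
(default 500 draws, seeded) is available for higher-dimensional random
effects.  All sums are log-space with max-shift.

**Score.**  The observed-data score is the weighted average of the
complete-data score over the quadrature nodes, with weights equal to the
normalised posterior ratios returned by the marginaliser.  The
complete-data derivatives are analytic for every block — including the
chain rule through the matrix-logarithm parametrisation of `D` (Daleckii–
Krein formula on the eigenbasis of `log D`) and the log transforms of `σ²`
and `η`.  For visiting/event parameters this gradient is *exactly* the
gradient of the discretised log-likelihood; for `θ_l` it ignores the
dependence of the node positions on `θ_l`, a discrepancy of the order of
the quadrature error (score-vs-finite-difference tests enforce 1e-4
relative agreement at 7 nodes per dimension).

**Optimisation.**  BFGS on the unconstrained packed scale (`β`, vech of
`log D`, `log σ²`, spline coefficients, feature coefficients, `α`'s,
`log η`), gradient tolerance 1e-5, with up to three restarts from the stop
point: a stale quasi-Newton Hessian occasionally fails its line search
("precision loss") while the true gradient is still large, and a fresh
Hessian recovers progress.  A fit is accepted as converged when scipy
reports success or the gradient sup-norm is below `1e-3·(1+|loglik|)`.

**Initialisation.**  Stage-wise: marker-only ML for `θ_l` (BFGS on the
same machinery with the hazard blocks absent; eigenvalues of the stage-1
`D` floored at `max(0.01, 1e-3·λ_max)` to keep the joint fit off the
variance boundary), constant-hazard (exponential ML) baselines via the
spline partition of unity, zeros for all feature and association
coefficients, `η = 0.1` when the frailty is enabled.

**Standard errors.**  Inverse of the Hessian of the negative
log-likelihood at the optimum, obtained by central finite differences of
the analytic score with step `1e-4·(1+|θ|)` per packed coordinate —
cheaper and more accurate than differencing the log-likelihood twice.
When a variance coordinate sits near its boundary the Hessian has flat
directions whose finite-difference eigenvalues are numerically zero or
slightly negative; eigenvalues are floored at `1e-8·λ_max` (honestly huge
SEs in no-information directions) provided the most negative eigenvalue
exceeds `−1e-5·λ_max`, otherwise the point is not a maximum and SEs are
withheld.
Wald 95% intervals are formed on the packed scale (hence log/matrix-log
scale for variance parameters, natural scale otherwise); the delta method
maps SEs for derived quantities such as the population marker value
`X(t)'β̂` at `t = 10` years.

**Reduced presets.**  "Ignore the visiting process" is the same code path
with the visiting block omitted; "ignore the observed marker values" drops
the `φ` features; the frailty can be switched off.  These are configuration
presets, not separate models.

## Synthetic-data generator

The generator produces exactly the study conditions the estimation code is
validated against.  Marker: `β = (17.20, 4.83, −2.80)` on the preset basis.
The random-effects covariance and residual variance are not part of the
published design; they were fixed once at

    D = [[16, −1.6, 0], [−1.6, 4, 0], [0, 0, 4]],  σ² = 4,

realistic for square-root CD4 (baseline SD 4 √cells/µL, moderate negative
intercept–slope correlation, residual SD 2).  Visiting: scenario I is a
gap-time model with features (last observed value `φ_v1 = 0.02`, current
visit time `γ_v1 = −0.02`, previous gap centred at 0.15 years
`γ_v2 = −1.50`) and associations `α_v1 = 0.02`, `α_v2 = 0.20`; scenario II
is a calendar-time intensity model with the previous-gap feature
(`γ_v1 = −1.00`) replacing the time trend.  Frailty variants drop the
previous-gap term and use `η = 0.4` (between "no remaining heterogeneity"
and the strong-heterogeneity regime).  Competing risks: cause 1 ("death")
with `φ_s11 = −0.20`, `γ_s11 = 0.50` on a Bernoulli(0.5) binary covariate,
`α_s11 = −0.05`, `α_s12 = −0.10`; cause 2 ("disengagement") with
`φ_s21 = −0.02`, previous-gap coefficient 1.40, binary-covariate
coefficient 0.50, `α_s21 = −0.05`, `α_s22 = −0.20`.  Administrative
censoring at 10 years; the marker is measured at the baseline visit
(`t = 0`) and at every generated visit with independent measurement error.

Baseline shapes are *log-linear in time* — deliberately inside the fitted
spline family, so the scaled-down recovery studies are exactly correctly
specified and any bias they show is attributable to the estimation method,
not baseline misfit.  Their scale constants were calibrated once so that
scenario I at N = 1000 yields about 11 visits per subject and cause event
rates near 11.3% and 14.6%: visiting `exp(−0.053 − 0.30u)` (scenario I),
`exp(−0.355 − 0.02t)` (scenario II), cause 1 `exp(0.10 + 0.05t)`
(`0.165` intercept under scenario II), cause 2 `exp(−5.98)` (`−6.13`
under scenario II); the frailty and strong-marker variants re-calibrate
only the visiting intercept (−0.655, −0.876 and −3.45 respectively).

Event and visit times are drawn by inverting the cumulative hazard:
composite Gauss–Kronrod panels (width ≤ 0.25 years, never straddling a
visit time) accumulate the integrated hazard and a bracketing root-finder
(Brent, absolute tolerance 1e-8) solves `∫ h = −log U`.  Cause labels are
drawn from the relative cause-specific hazards at the event time.  One
master seed spawns independent child streams per replication.

**What the generator does not emulate:** scheduled (protocol) visits mixed
with patient-initiated ones, covariate-dependent censoring, interval
censoring of the terminal events, serial correlation in the residuals, and
non-Gaussian marker noise.  Passing tests therefore demonstrate internal
validity of the estimator under the stated mechanisms, not robustness to
these real-data features.

## Simulation-study harness

`run_sim_study` simulates, fits, and aggregates per-parameter `True`, mean
estimate, bias, MSE, average model SE, Monte-Carlo SD, and 95% coverage,
plus a derived row for the population marker value at 10 years (truth
25.98).  Spline coefficients have no finite-dimensional truth (the
baseline is a free function whose knots are data-driven) and are excluded
from recovery metrics.  Replications that fail to converge are excluded
and counted; replication-level estimates are kept in the report.

Recovery of the variance components is summarised on the *natural* scale
(entries of `D`, `σ²`, `η`): in small samples the weakly identified
cubic-term random-effect variance occasionally collapses to the boundary,
and a near-zero eigenvalue maps toward −∞ on the matrix-log estimation
scale, destroying the mean there while the natural-scale estimates remain
bounded and, empirically, unbiased.  Coverage is evaluated with the Wald
intervals on the transformed scale, where they are constructed.

**Problem sizes.**  The full published design (600 replications of
N = 1000) is available through the CLI (`jointvisit simstudy --reps 600
--n 1000`).  The shipped test suite runs the same studies at reduced
scale — N = 100 subjects, 12 replications for the correctly specified
model, 8 for each comparison preset, 5 GH nodes per dimension — with all
tolerance bands computed from the replications' own Monte-Carlo standard
errors, so they widen accordingly.  At these sizes a `q = 3`
random-effects covariance is occasionally weakly identified (the
likelihood surface near the variance boundary is ill-conditioned); this is
intrinsic to small samples, which is why the basin-stability and recovery
checks run at N = 100 rather than smaller.

## Known limitations

* The visiting process uses a single time scale; combined gap + calendar
  dual-baseline models are out of scope.
* Current-value association `m_i(t)` is intentionally not offered; with
  the observed marker history also conditioned on, it is near-collinear
  with the retained terms and threatens identifiability.
* The score's node-motion approximation for `θ_l` makes extremely
  low-node quadrature (3 per dimension) unreliable for BFGS on hard
  surfaces; 5 or more nodes per dimension are recommended for fitting.
* Interval-censored terminal events and non-Gaussian markers are not
  supported.
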