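# Methods

`dsschoice` decides, from trial-by-trial behavior alone, whether binary
choices in discrete-sample-stimulus (DSS) tasks arise from temporal
integration of the evidence stream or from one of two non-integration
strategies. A DSS trial presents a sequence of brief samples, sample
`i` of trial `t` carrying a signed evidence value `S_ti`; the subject
reports a binary choice `R_t` (coded 1 = rightward = category A
throughout; positive evidence favors rightward). Because the
experimenter controls every sample, the mapping from the full evidence
vector to the choice can be modeled directly.

## The three choice models

**Temporal integration.** The choice probability is a logistic function
of a weighted sum of the samples,

    p(r_t) = sigma(beta0 + gamma_{s(t)} * sum_i beta_i S_ti),

with lateral bias `beta0`, per-position sensory weights `beta_i` and an
optional per-session gain `gamma` (for datasets spanning many sessions
with drifting performance). The per-position weights are a first-order
statistical surrogate for any generative accumulator: leak, attractor
dynamics or sticky bounds reshape the kernel but keep the model in this
family. Fitting is penalized maximum likelihood — independent N(0,
prior_sd²) priors on `beta0` and `beta` (default prior_sd = 1,
weakly-informative, keeps the Laplace covariance well defined) and
N(1, prior_sd²) on gains — by Newton ascent with step-halving. With
gains the problem is bilinear; we alternate two convex sub-problems
(`beta` with `gamma` fixed; one-dimensional per-session `gamma` steps
with `beta` fixed) until the log-posterior increment falls below 1e-9,
renormalizing to mean(gamma) = 1 exactly after every sweep to remove
the scale degeneracy. The reported log-likelihood excludes the prior,
so AIC = 2p − 2·loglik is likelihood-based. `posterior_cov` is the
inverse Hessian of the negative log posterior over (beta0, beta) at the
mode, with gains held at their estimate; it supplies kernel standard
errors and the sampling distribution for parametric bootstraps. A
probit link is available (`link="probit"`); the logit is the default.
Ragged sequences are indexed from sequence onset; positions beyond a
trial's length are masked out of every sum.

**Snapshot.** Each trial's choice depends on one attended sample (or a
window of K consecutive samples) drawn from a stimulus-independent
multinomial policy (pi_1..pi_n, pi_L, pi_R), the last two entries being
left/right lapses. Given attention to component i, the response
probability H_i is either deterministic (1/0/0.5 by the sign of the
attended evidence; a window uses the sign of its summed evidence) or
probabilistic, H_i = sigma(beta_i S_ti) (window: sigma of the
beta-weighted window sum). The marginal is the mixture
p(r_t) = sum_c pi_c H_c. The deterministic rule is the divergent-beta
limit of the probabilistic one. K = n with no lapses reproduces the
bias-free integration model exactly — kept available (behind an
explicit flag) as a cross-model identity check, while the strict
snapshot family is limited to K ≤ n−1.

Fitting is EM: the E-step computes responsibilities
z_tc ∝ pi_c H_c (rightward) or pi_c (1−H_c) (leftward); the M-step
updates pi in closed form (z averages, renormalized within the sample
components when lapses are clamped) and applies **one** Newton–Raphson
update per sensitivity parameter on the expected complete
log-likelihood. A single Newton step does not guarantee ascent, so the
step is halved (up to 10 times) against the *observed* log-likelihood
and reverted entirely if still decreasing — the pi update alone is then
a proper EM step, so monotonicity holds on every iteration (generalized
EM). Convergence is a log-likelihood increment below 1e-9; the best of
10 random initializations (flat-Dirichlet pi, N(0,1) beta) is returned.
Lapse handling: free, clamped to pi_L = pi_R = 0.01, or absent. For the
deterministic rule H is parameter-free, so trials are collapsed to
unique (H-row, choice) patterns with counts before iterating — exact,
and it makes EM cost independent of trial count. Components attending a
position beyond a ragged trial's length contribute H = 0.5 (attending a
nonexistent sample is a guess); renormalizing pi over existing samples
is the alternative we did not take, to keep pi interpretable across the
whole dataset.

**Extrema detection.** Each sample's evidence is corrupted by sensory
noise of SD `sigma`; the observer commits at the first sample whose
noisy evidence crosses ±theta, choosing the side of the crossing.
Writing Phi for the normal CDF, crossing and survival probabilities per
sample give the closed-form first-passage likelihood

    p = sum_i Phi((S_ti − theta)/sigma) * prod_{j<i} surv_j + default,
    surv_j = 1 − Phi((S_tj − theta)/sigma) − Phi((−S_tj − theta)/sigma),

with the default term ½·(full survival product) under the random-guess
rule, or Phi(S_tn / sigma)·(survival product over j < n) under the
last-sample rule. The n+1 path probabilities (commit at sample 1..n;
reach the end) are exposed separately and sum to 1 per trial — a law of
total probability used as a property test. Lapses enter as an outer
mixture p ← pi_R + (1 − pi_L − pi_R)·p_core, matching the conditional-
psychometric formula used elsewhere in the package. A varying-threshold
variant substitutes theta_i per position (n + 3 parameters). Fitting is
bounded L-BFGS-B over (theta, log sigma, pi_L, pi_R) — sigma on a log
scale for conditioning; bounds theta ∈ [0, 10·max|S|], sigma ∈
[1e-3, 10·sd(S)], lapses ∈ [0, 0.3] — with 10 random starts by default.
A finite-difference Hessian at the MLE provides a Laplace covariance
for parametric bootstraps; when the optimum pins a bound the Hessian is
not usable and the covariance is omitted (downstream analyses then fall
back to point simulation and say so).

For multi-session (monkey/rat-style) data the snapshot and extrema
models consume session-gain-scaled evidence `gamma_t S_ti`, with gains
taken from the integration fit; this is exposed as an explicit `gains`
argument rather than hidden state.

## Model comparison and validation statistics

AIC with the likelihood at the optimum; the comparison table reports
each fit's AIC, the difference to the best model and to the integration
model. Psychophysical kernels are plain (no-gain) logistic regressions
of choice on per-sample evidence with Laplace standard errors — the
same code path for observed and simulated choices. Psychometric curves
bin the session-modulated weighted evidence T_t = gamma_t·beta·S_t into
quantile bins (50 by default; 10 suits small human-scale datasets).
Boundary performance gives each non-integration family's best-case
accuracy: for the snapshot family, the best single position's
sign-agreement with the category (zero evidence counts as a coin flip);
for extrema detection, the noise-free lapse-free rule with the
threshold maximized over a 200-point grid on [0, max|S|].

## Integration maps

Each trial's weighted evidence is split into early
E_t = gamma_t·sum_{i ≤ floor(n_t/2)} beta_i S_ti and late L_t (the
remainder), so E + L equals the weighted total exactly (7 samples split
3 + 4). The integration map is the kernel-weighted proportion of
rightward choices on a regular (E, L) grid (spacing 0.1 over the
central 98% of the data): trials within the selection radius (default
2) receive Gaussian weights of SD 0.1 in their distance to the node. At
these defaults the radius cut is numerically inert (weights underflow
long before it), in which case the weight factorizes over the two axes
and the map is computed by chunked matrix products; the exact masked
computation is used whenever the radius is live. The density mask
counts trials within min(radius, 2.5·kernel SD) — the trials that
actually support a node — and hides nodes below `density_min`.

If choices depend only on E + L, isolines of the map are straight
diagonals; attending one part of the stimulus bends them toward the
axes. Straightness is quantified as the maximum perpendicular residual
of each isoline's points (levels 0.15/0.3/0.5/0.7/0.85, extracted with
scikit-image) from its least-squares line, in grid-spacing units. This
is an extreme-value statistic: on choice-sampled maps it needs both a
large trial count and a meaningful density floor before node-level
binomial noise stops masquerading as curvature. The diagnostic suite
runs it on 5·10⁵ simulated trials with a 2000-trial density floor,
where integration-generated choices sit well below the 2-grid-spacing
criterion; on noiseless maps (smoothing the generating probabilities
themselves) the residual is ~0.3.

Conditional psychometric curves slice the map by late-evidence bins
(width 0.5) and fit p = pi_R + (1 − pi_L − pi_R)·sigma(alpha·E + beta)
per bin by bounded MLE (lapses ∈ [0, 0.5], two sensitivity
initializations). Under integration the bias beta tracks the bin's L
linearly and lapses stay null; under non-integration the lapses grow
with |L| (the attended-elsewhere trials respond independently of E).
One identifiability caveat, verified empirically: with free alpha, bins
whose bias pushes one asymptote of the conditional curve outside the
sampled E-range have a bias/lapse likelihood ridge, and the *MLE
itself* can place several percent in a lapse. The null-lapse prediction
is therefore assessed on central bins where both asymptotes are
sampled; bias linearity is assessed over the full well-populated range.

Map agreement between data and a model simulation is the Pearson
correlation over jointly unmasked nodes of maps computed on a shared
grid from the same trials; uncertainty comes from resampling trials
with replacement (default 100 bootstraps) and recomputing both maps.
Competing models are compared by an unpaired test on their bootstrap
correlation sets.

## Disagree trials and subjective weights

Disagree trials are those where the sign of the largest-|S| sample
opposes the sign of the summed evidence — the trials where integration
and extrema detection predict opposite behavior. Exact-zero totals and
tied maxima of conflicting signs are excluded and counted (the
definition does not cover them); raw evidence is used, matching the
printed definition. The report gives the observed proportion of choices
aligned with the total evidence and, per candidate model, a parametric
bootstrap: parameters drawn from the Laplace posterior, choices
re-simulated, the proportion recomputed, percentile 95% CIs.

Subjective weighting relaxes the linear read-out to
p = sigma(beta0 + gamma_t·sum_i beta_i f(S_ti)) with an odd transfer
function f; f is linear under pure integration and saturates when
extreme samples are under-weighted. Estimation alternates (a) a
penalized logistic step in f's values at its evaluation points, holding
the linear weights fixed (f enters linearly through interpolation
weights), with (b) an integration refit on the f-transformed evidence;
mean(beta) = 1 and mean(gamma) = 1 are imposed exactly after every
sweep so f carries the scale and stays in evidence units. Oddness is
structural: f is parameterized on positive magnitudes and reflected,
with f(0) = 0. In discrete mode f is estimated at each observed
magnitude seen at least 10 times (rarer levels are unidentifiable;
values beyond the top retained level extrapolate linearly along the
last segment). In GP mode (continuous evidence), f lives on a grid of
25 positive nodes under the odd projection of a squared-exponential GP
prior, K_odd(x, x′) = k(x − x′) − k(x + x′) with length scale 0.1 and
variance 1, both fixed; the posterior mode is found by Newton with the
full prior precision. Standard errors come from the final f-step
Hessian.

## Neural analysis

Per neuron, a Poisson GLM with log link (statsmodels) regresses the
trial spike count on the per-sample evidence,
E[s_t] = exp(w0 + sum_i w_i S_ti); the preferred direction is the sign
of the summed weights. Neuron-weighted early/late evidence (samples 1–3
vs 4–7 for seven-sample designs) and baseline-normalized counts
s_t/exp(w0) pool across neurons into the neural integration map:
normalized counts histogrammed at 0.02 in (E, L) and smoothed with a
0.1-SD Gaussian (numerator and denominator smoothed separately, then
divided). Three simulators generate counts under the competing
hypotheses: the GLM generative process; an extrema-coding neuron whose
rate follows the behavioral threshold-crossing sample (scaled by half
the summed weights, signed by preference; baseline rate when no sample
crosses); and a snapshot-coding neuron attending one sample drawn from
a pmf proportional to its non-negative direction-signed GLM weights
(uniform, with a warning, if none is positive).

## Synthetic designs

The generators reproduce the three stimulus designs so every analysis
is testable end-to-end with known ground truth:

* **Monkey-style** — 7 integer pulses per trial, each drawn from a
  condition's Gaussian and rounded to the nearest integer; conditions
  drawn uniformly per trial. The original condition set is not
  published; the default is a symmetric 5-condition spread of means at
  unit variance (configurable, not canonical). Sessions come in blocks
  with true gains log-uniform on [0.5, 2] (stored in metadata for
  recovery tests). Category = sign of the condition mean; zero-mean
  conditions are labeled by the empirical sign of the summed pulses
  (random on an exact zero), matching reward-by-empirical-stimulus.
* **Human-style** — 5–10 gratings per trial (length uniform), doubled
  angle offsets 2(alpha − alpha0) drawn von Mises(0, kappa = 0.3)
  around the category's reference (45°/135°), and evidence
  S = 2·kappa·cos(2(alpha − alpha0_cw)) — the exact per-sample
  log-likelihood ratio, bounded in [−0.6, 0.6].
* **Rat-style** — 10 or 20 frames per trial; framewise evidence from a
  Beta on [−1, 1] (X = 2B − 1, shapes moment-matched to the condition's
  mean/SD) over the 7-mean × 5-SD grid; envelopes a_L = (1+S)/2,
  a_R = (1−S)/2 sum to 1 in every frame by construction. Boundary means
  ±1 admit only the point mass and are generated as such. A
  `constrained` flag reproduces the early-session regime where
  sequences were kept near their nominal evidence (rejection sampling
  on the empirical mean, tolerance half the mean-grid spacing, which
  induces weak anti-correlations between samples).

What the generators do **not** emulate: sequential dependencies across
trials (win-stay/lose-shift, history kernels), attention or motivation
drift within sessions beyond the multiplicative gain, sensory adaptation
between successive samples, and any reaction-time structure. Passing
recovery and signature tests on these synthetics therefore shows the
estimators and diagnostics are correct and well-calibrated under the
stated generative assumptions — not that real subjects satisfy them.

## Numerical conventions and problem sizes

Random state is `numpy.random.default_rng` seeded explicitly
everywhere; generators and simulators are bit-reproducible given a
seed. Likelihoods are clipped at 1e-300 (mixtures) or computed via
`log_expit` (logistic) to avoid underflow; survival products are exact
products of clipped non-negative terms (n ≤ 20 keeps them well above
underflow). Quantile bins break ties by stable trial order. The test
suite sizes its simulations to what the statistics need on one CPU:
5000-trial replicates (×100) for kernel coverage, 10⁴-trial replicates
(×100 per generator) for AIC model recovery, 2×10⁴ trials for snapshot
and extrema parameter recovery, 10⁵ noise draws per trial for the
Monte-Carlo oracle of the extrema likelihood, and 5×10⁵ trials for the
map-signature checks, with optimizer starts reduced (2–3) inside
repeated harnesses while user-facing defaults stay at 10.

## Known limitations

The integration Laplace covariance omits the gain block, so parametric
bootstraps hold gains fixed; gains are typically estimated from
thousands of trials per session and contribute little to the bootstrap
spread. The subjective-weight alternation is a coordinate-ascent MAP,
not a joint Laplace fit: convergence to the joint mode is monitored by
the data log-likelihood only. The snapshot probabilistic EM can be slow
near degenerate components (pi → 0 with diverging beta); such
components are frozen and flagged rather than pruned mid-run. The
varying-threshold extrema variant shares the scalar-sigma assumption;
per-position noise is not modeled.
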