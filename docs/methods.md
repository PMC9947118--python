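# Methods

## Data model and preprocessing

One observation is a tank group: one fish, or a small monospecific group
of up to 13 similar-sized individuals, held fasting in flow-through
seawater while excreted carbonate pellets are collected and titrated. Raw
chemistry enters through `carbonate_from_titration`: the acid consumed
minus the back-titrated base counts bicarbonate equivalents, and each
carbonate molecule yields two, hence the factor 0.5. Single-end-point
titration reads systematically high relative to double titration by a
calibration ratio of 1.08 (estimated from paired measurements of the same
samples); `apply_titration_correction` divides single-end-point rates by
this ratio so both protocols live on the double-titration scale. The
pipeline can be run corrected or uncorrected as a robustness check — the
default analysis models the method difference through the residual scale
instead (below).

Per-individual rates are totals over the sampling period divided by hours
and by group size. Group rates average out intra-tank variability, so
group observations carry frequency weight 2 against 1 for singletons;
weighting by actual group size would let the few large groups dominate.
Families with fewer than three independent observations are dropped
before modelling (`filter_min_observations`). Parrotfishes (tribe
Scarini) are treated as a family of their own because their carbonate
products differ from other wrasses'; the split is a configurable
tribe-to-pseudo-family table, not hard-coded taxonomy.

Species-level polymorph profiles are unweighted means of per-sample
visual composition estimates, renormalised to the simplex after
averaging (the estimates are approximate, so their mean need not sum to
one exactly). Polymorph-specific rates are the total rate times these
fractions, which preserves the total by construction.

Covariate transforms are fixed by the allometric form of the problem:
natural log for body mass and RIL (power-law scaling), square root for
AR, identity for temperature, salinity and sampling period. Designs are
standardised internally for sampling geometry; reported coefficients are
always back-transformed to natural scale.

## Total-excretion model

A multilevel distributional regression with Student-t observation noise
on the log rate. The t likelihood (estimated degrees of freedom,
Γ(2, 0.1) prior) guards the fit against the occasional extreme tank;
the log-link scale model `ln σ = γ_σ + β_σ·method` lets the noisier
single-end-point protocol have its own residual spread rather than
inflating everyone's. A mean-centred Levene test on posterior-mean
residuals grouped by method (`levene_method_test`) is the diagnostic that
motivates the distributional term. Priors are weakly informative:
N(0, 5) on location coefficients, t(3, 0, 2.5) on γ_σ, half-N(0, 5) on
the family SD τ — the half-normal is the non-negative reading of a
N(0, 5) prior on a scale parameter.

Derived quantities are per-draw transforms summarised afterwards, never
transforms of posterior means: Q10 = exp(10 β_T); percent changes across
an observed covariate range are 100·(exp(β·(g(hi)−g(lo)))−1) with g the
covariate transform. For convex maps the mean of the transform exceeds
the transform of the mean (Jensen), which is why a Q10 reported this way
is larger than exp(10·mean β) — the package deliberately reports the
former. Bayes R² is computed on the ln-rate scale as
var(η) / (var(η) + mean σ²·ν/(ν−2)); draws with ν ≤ 2 (infinite t
variance) fall back to the realised residual variance and are counted in
the output. Posterior-predictive coverage simulates replicate data with
the t noise included and reports the share of observations inside the
central interval.

## Mineralogy model

Each polymorph rate is hurdle-lognormal: a logistic regression on the
probability of a zero (no excretion of that mineral) with RIL,
temperature and family as predictors, and a lognormal for positive rates
with the same trait/environment predictors as the total model. Because
the lognormal has no mass at zero, the truncation denominator in the
positive branch is identically one and is omitted. Per-response
fixed-effect masks implement model reduction: the shipped default drops
RIL, AR and temperature from the LMC positive part and temperature from
the MHC positive part — the effects whose posterior SD exceeded their
posterior mean magnitude in the full fit. The generic rule is available
as `reduced_spec_from_fit`. The lognormal scale depends on titration
method per response, mirroring the total model.

The ten family intercepts (five positive-part, five hurdle) are jointly
multivariate normal: per-component scales with half-N(0, 5) priors and an
LKJ(1) (uniform) prior on the 10×10 correlation. The hurdle block of this
correlation is the quantity of ecological interest — which polymorphs
families co-produce. Because the hurdle models P(zero), "probability of
excretion" outputs are complements; within-block correlations are
invariant to flipping both margins, so only cross-block (rate-vs-hurdle)
entries change sign when reported on the excretion-probability scale.

## Sampling

No probabilistic-programming framework is used: both posteriors are
log-densities with hand-derived analytic gradients, sampled by an
in-package adaptive Hamiltonian Monte Carlo sampler. Design choices:

- **Parameterisation.** Everything positive is sampled on the log scale
  (ν, τ, σ intercepts are already log-link) with Jacobians included.
  Family effects are non-centred (u = τ·z, z ~ N(0,1)); in the
  mineralogy model the stacked effects are τ ⊙ (L z) with L the
  correlation Cholesky factor.
- **Correlation transform.** L is parameterised by canonical partial
  correlations z = tanh(x). Writing w = sqrt(1−z²), rows have the closed
  form L_ij = z_ij·Π_{k<j} w_ik, L_ii = Π_{k<i} w_ik, which makes the
  adjoint a short backward pass. The LKJ(η) density combined with the
  transform Jacobian collapses to Σ α_c·ln(1−z²) with α depending only on
  the column, so the prior gradient is simply −2αz. A property test
  checks the implied LKJ(1) pairwise marginal (Beta(3/2,3/2) variance 1/4
  at dimension 3) by sampling the prior.
- **Adaptation.** Dual averaging targets acceptance 0.8; a single Welford
  window (15%–80% of warm-up) estimates a diagonal mass matrix, after
  which step-size adaptation restarts. The leapfrog path length is drawn
  uniformly from {1, …, L_max} each transition (L_max 48 for the
  excretion model, 64 for the mineralogy model), which avoids resonance
  without tree building; a full no-U-turn tree was considered and
  rejected as harder to verify by hand for no measurable gain on these
  posteriors. Energy errors beyond 1000 or non-finite states are
  rejected and counted as divergences after warm-up.
- **Contract.** Default acceptance for a fit: split R-hat < 1.01,
  bulk ESS > 400, zero post-warm-up divergences (`PosteriorDraws.converged`).
  R-hat/ESS come from arviz.

Gradient correctness is enforced by finite-difference oracle tests for
both models and for the correlation backward pass; the sampler itself is
validated on a correlated Gaussian with known moments.

## Model selection

The candidate grid reproduces the build-up used for the compiled data:
intercept-only, mass-only, then mass plus either RIL or salinity (the two
are too collinear to co-occur; r ≈ −0.6 in the data and in the
generator), then every subset of {temperature, AR, sampling period} — 18
fixed structures, each with and without the family intercept, 36 models.
The enumeration (including whether intercept-only and mass-only are part
of the 18) is our reading of the construction description; it is recorded
in `CandidateGrid.provenance` so alternates can be swapped in. Comparison
is by PSIS-LOO on the weighted pointwise log-likelihood; the Pareto
smoothing uses arviz's `psislw` while elpd assembly, SEs of paired
differences and ranking (ties to fewer parameters) are in-package. An
exact leave-one-out oracle by n refits backs the acceptance test at
n = 20.

## Synthetic communities

The generator emulates the compiled dataset's conditions: 21 families ×
3 species, 175 tank groups; body mass log-uniform on [0.001, 11] kg per
observation; species-level RIL log-uniform on [0.33, 7.56] and AR uniform
on [0.76, 3.30]; temperature uniform on [23.0, 30.2] °C; salinity uniform
on [33.8, 36.6] drawn through a Gaussian copula against species log-RIL
(rank correlation −0.65, giving Pearson r ≈ −0.6 — the confounding
present in the real data); sampling periods log-uniform on [18, 169] h
(median ≈ 55 h against the observed 64 h); 61% singleton tanks, group
sizes 2–13 with probability ∝ 1/size²; three regions with one
(single-end-point) region holding ≈ 35% of species, so titration method
is confounded with region as in the field data. Default generating
parameters sit at the compiled-data point estimates (mass exponent 0.78,
RIL exponent −0.59, AR effect 0.71, temperature effect 0.05 °C⁻¹,
residual scales 0.39/0.80, family SD 0.35, ν = 15; polymorph mass
exponents 0.89/0.74/1.14/1.40/0.89). Hurdle intercepts are set from
target zero-shares at the average predictors (70/15/50/80/45% for
LMC/HMC/aragonite/MHC/ACMC, spanning the observed 14–83% range); the
steep HMC hurdle-RIL slope (−2.0 on the zero logit) places the
stationary point of (1−θ)·E[rate] inside the observed RIL range,
reproducing the right-skewed unimodal HMC marginal curve seen in real
fish. The family-effect correlation encodes the observed co-production
pattern (HMC-excreting families unlikely to excrete aragonite/LMC/MHC;
those three positively associated), projected to the nearest valid
correlation matrix.

What the generator does not emulate: within-species variation in RIL and
AR (species-level constants), phylogenetic trait structure beyond the
family intercept, observation-level composition variability (real
profiles are species means of per-sample estimates), diet effects
(measurements are from fasting fish), and any dependence of sampling
period on taxon. Passing recovery and calibration tests therefore
demonstrate correctness of the inference machinery under the stated
generative model, not robustness to these real-data features.

## Problem sizes and numerical choices

Tests and the acceptance script run reduced MCMC sizes chosen as the
smallest that keep diagnostics clean on these posteriors: typically 2
chains × 500–1000 post-warm-up draws for the excretion model and 2–3
chains × 300–450 draws for the mineralogy model, against the 4 × 3000 /
3 × 2000 defaults exposed by `fit` and `fit_mineralogy`. Replicated
checks (interval coverage over 20 refits, model-ranking frequency over 20
replicates) use the reduced sizes throughout. Interval-coverage checks on
single seeded fits use 99% intervals when several parameters are tested
jointly, keeping the family-wise false-alarm rate near 5%.

Degenerate inputs are rejected early: non-positive masses/RIL/AR, zero
sampling periods, over-titrated samples without back-correction,
off-simplex profiles, non-positive-definite covariances. An all-zero or
all-positive polymorph column leaves the hurdle intercept identified by
its prior only; the fit proceeds with a warning rather than failing.
Posterior summaries use equal-tailed quantile intervals throughout.

## Known limitations

The zero-noise limit of the excretion model exposes the usual funnel:
with residual SD ≈ 10⁻³ the sampler's adapted step size cannot follow
the likelihood all the way down, so σ̂ plateaus high and Bayes R² reads
≈ 0.99 rather than 1; at any realistic noise level this is immaterial.
PSIS-LOO inherits the usual caveat that high Pareto-k observations
(flagged at k > 0.7) make the approximation unreliable for those points.
The mineralogy model treats species composition profiles as fixed when
polymorph rates are built from totals; composition uncertainty is not
propagated. Salinity and sampling period are accepted as per-tank means.
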