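# ichthyocarb

Bayesian models of the drivers of intestinal carbonate excretion in reef
fishes — how much carbonate a fish excretes, and in which mineral forms.

Marine bony fishes continuously precipitate carbonate crystals in their
intestine as a by-product of osmoregulation and excrete them at rates that
matter for the ocean's inorganic carbon cycle. This package implements the
full inference pipeline for tank-based excretion measurements: titration
chemistry and per-individual rate aggregation, a weighted multilevel
distributional Student-t regression of total excretion on body mass,
relative intestinal length (RIL), caudal fin aspect ratio (AR) and
temperature, a multivariate hurdle-lognormal model of the five excreted
carbonate polymorphs (LMC, HMC, aragonite, MHC, ACMC) with correlated
family-level effects, PSIS-LOO model selection over a 36-model candidate
grid, and derived ecological quantities (Q10, range effects, prediction
surfaces). A synthetic community generator with the exact generative
structure of both models makes every stage testable without any data
download. It is aimed at fish ecophysiologists and biogeochemists working
with carbonate excretion data, and at anyone who needs a reference
implementation of these model families in plain numpy/scipy.

## The models

Total excretion, for observation *i* (a tank holding one fish or a small
monospecific group) in family *k*:

```
ln y_i  ~  Student-t(ν, η_i, σ_i)
η_i     =  γ₀ + β₁ ln M_i + β₂ ln RIL_i + β₃ √AR_i + β₄ T_i + u_k
u_k     ~  N(0, τ)
ln σ_i  =  γ_σ + β_σ · [method_i = single end point]
```

with priors N(0,5) on coefficients, half-N(0,5) on τ, t(3,0,2.5) on γ_σ and
Γ(2, 0.1) on ν. Group observations enter with frequency weight 2,
singletons with weight 1. The method-dependent scale absorbs the larger
residual spread of single-end-point titration.

Polymorph rates y_i^m (m = LMC, HMC, aragonite, MHC, ACMC) follow a hurdle
lognormal: zero with probability θ_i^m where
`logit θ_i^m = γ₀^m + β₁^m ln RIL + β₂^m T + v_k^m`, lognormal when
positive with a location built like η above (per-response fixed-effect
masks) and its own family deviation u_k^m. The ten family intercepts
(u¹..u⁵, v¹..v⁵) are jointly multivariate normal with half-N(0,5) scales
and an LKJ(1) correlation prior, capturing which polymorphs families
co-produce.

Both posteriors are sampled with an in-package adaptive Hamiltonian Monte
Carlo sampler (hand-derived analytic gradients, dual-averaging step size,
diagonal mass adaptation, non-centred family effects, canonical
partial-correlation transform for the correlation Cholesky factor).
Diagnostics (split R-hat, bulk ESS, divergence counts) come from arviz.

## Worked example

```python
import numpy as np
from ichthyocarb import (
    ExcretionModelSpec, PriorSet, fit, bayes_r2, ppc_coverage, q10,
    simulate_dataset,
)

ds, truth, raw = simulate_dataset(seed=11)   # 21 families, 175 tank groups
f = fit(ExcretionModelSpec(), PriorSet(), ds,
        chains=2, iter=1000, warmup=500, seed=7)

j = f.spec.location_terms.index("ln_mass")
beta_mass = f.draws.stacked("beta")[:, j]
print(f"mass exponent: {beta_mass.mean():.3f} "
      f"[{np.quantile(beta_mass, 0.025):.3f}, {np.quantile(beta_mass, 0.975):.3f}]")
beta_T = f.draws.stacked("beta")[:, f.spec.location_terms.index("temperature")]
print(f"Q10: {q10(beta_T).mean:.2f}")
print(f"Bayes R2: {bayes_r2(f)['mean']:.3f}")
print(f"95% PPC coverage: {ppc_coverage(f, seed=1):.3f}")
```

prints

```
mass exponent: 0.775 [0.750, 0.798]
Q10: 1.90
Bayes R2: 0.923
95% PPC coverage: 0.966
```

The generating mass exponent is 0.78: rates scale hypoallometrically, so
small fishes excrete disproportionately more carbonate per unit mass. The
Q10 is the multiplicative change in rate per 10 °C; the Bayes R² is
computed on the ln-rate scale; the coverage is the share of observations
inside their 95% posterior-predictive interval, t observation noise
included.

The same pipeline is available from the shell:

```
ichthyocarb simulate --out sim --seed 3
ichthyocarb preprocess --data sim --out kept
ichthyocarb fit-excretion --data kept --out fit --chains 4 --iter 4000
ichthyocarb report --out rep --seed 1
```

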