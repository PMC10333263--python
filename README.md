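# predband

**Bayesian training and prediction bands for non-identifiable ODE models.**

Mechanistic models in systems biology are usually *practically
non-identifiable*: noisy, limited data leave most parameters undetermined
even when the model structure is right. `predband` implements an alternative
to reducing such models until they become identifiable — train the full
model on whatever was measured, quantify what the posterior *can* predict,
and measure how each new experiment shrinks the plausible parameter space.

The package studies two fully in-silico systems:

* a **four-step signalling cascade** `S → K1 → K2 → K3 → K4` with negative
  feedback of strength `f1` from K4 onto step 1 (motif of MAPK / NF-κB / p53
  pathways), in four variants — nominal, *relaxed* (feedbacks `f2`, `f3` on
  steps 2-3 also free), *simplified* (two steps, K1 drives K4) and
  *no-feedback*;
* a **three-mass damped oscillator** (two springs, force on one end mass),
  the mechanical analogue.

## Model and method

Training data are generated from the model itself: trajectories are read out
on a regular grid (hourly / per second), cascade values are transformed with
`softlog(x) = log10(0.001 + x)`, and Gaussian noise with σ_error = 0.3 is
added independently to 3 replicates. The posterior over parameters θ is

    f(θ) ∝ P(θ) · ∏_k ∏_{t,r} N(m_{k,t,r} | y_k(t), σ_error)

where the product over variables `k` runs only over those *selected for
training*. Priors are LogNormal(μ=1, σ=3) clipped to (0, 10⁴] for the
cascade and uniform for the oscillator. Sampling is plain Metropolis–
Hastings (8 chains × 1.5 M steps at full scale, burn-in 0.25 M, every
1000th step retained → 10,000 samples) with a spherical Gaussian proposal of
σ = 0.2 in log-parameter space; a `scale_factor` shrinks all chain settings
proportionally for desk-scale runs. Convergence is monitored with
rank-normalised split R̂ and effective sample size.

Two kinds of output summarise what the trained model knows:

* **prediction bands** — point-wise medians and 80% quantile envelopes of
  the posterior trajectory ensemble under *new* stimulation protocols,
  optionally after multiplying a parameter by 10 (overexpression) or 1/10
  (inhibition);
* **principal multiplicative deviations** — PCA on natural logs of the
  posterior samples gives principal variances λᵢ; δᵢ = exp(√λᵢ) is the
  fold-change spread along the i-th principal direction (δ = 1: direction
  fully pinned; prior: δ ≈ exp(3) ≈ 20). Directions with δ < 1.5 count as
  *stiff*; measuring *n* variables pins ~*n* directions.

ODE integration uses an adaptive Dormand–Prince 5(4) pair (rtol 1e-6,
atol 1e-9) compiled with numba together with the whole MH loop, so a
desk-scale training run takes minutes, not hours.

## Worked example

```python
import numpy as np
from predband import (MCMCConfig, make_training_scenario, run_training,
                      predict_band, deviation_spectrum, count_stiff)
from predband.models import CASCADE_T_GRID, get_protocol

model, protocol, data = make_training_scenario("cascade_train")
post = run_training(model, data, ["K4"],
                    config=MCMCConfig(scale_factor=0.01, seed=1),
                    protocol=protocol)
band = predict_band(post, model, get_protocol("pulse_train"), CASCADE_T_GRID)
spec = deviation_spectrum(post)
print("median K4 band width:", round(band.median_width("K4"), 2))
print("delta_i:", np.round(spec.deviations, 2))
print("stiff directions:", count_stiff(spec))
```

prints (seed 1, scale 0.01):

```
median K4 band width: 0.17
delta_i: [16.78 11.91  8.58  6.66  4.48  3.28  2.55  1.7   1.18]
stiff directions: 1
```

The K4 band spans only ~0.2 decades — the trained variable is predicted
tightly under a protocol the model never saw — while the largest δᵢ stay
near the prior's ~20-fold spread; exactly one δᵢ has dropped below 1.5,
i.e. training on one variable pinned one combination of parameters
(activation/deactivation ratios), not any parameter itself. Equivalent
shell runs:

```bash
predband list-presets
predband run --preset fig2_K4 --scale 0.01 --out out/fig2_K4
predband pca --samples out/fig2_K4/posterior.csv
```

Numbers at desk scale wobble with seed and chain length; the examples/
scripts print the same quantities one capability at a time.

## Layout

| path | contents |
| --- | --- |
| `src/predband/models.py` | ODE systems, protocols, Dormand–Prince simulation |
| `src/predband/synthetic.py` | softlog transform, noise model, frozen scenarios |
| `src/predband/inference.py` | priors, likelihood, Metropolis–Hastings, R̂/ESS |
| `src/predband/analysis.py` | prediction bands, perturbations, PCA dimensionality |
| `src/predband/pipeline.py` | end-to-end experiment presets (YAML configs) |
| `src/predband/cli.py` | `predband` console entry point |
| `examples/` | one narrative script per capability |
| `docs/methods.md` | modelling and numerical choices in detail |
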