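# bluediff

Diffusion-based imputation of missing values in multivariate time series,
with a time-varying blend of white and structured **blue noise** in the
diffusion process.

Missing data pervades high-dimensional time series — ICU monitoring streams
with irregular charting, and above all time-course single-cell RNA-seq,
where technical dropout can hide well over half of all entries.  Conditional
denoising diffusion models impute by learning
`p(X^mis | X^obs, M, s)` for a record `X ∈ R^{K×L}` (K features, L time
points) with observation mask `M` and timestamps `s`, and they normally
corrupt data with isotropic white noise.  `bluediff` replaces that noise
with a step-dependent mixture

```
ε̃_t = γ_t ε_white + (1 − γ_t) ε_blue,
γ_t = σ(γ_start + (γ_end − γ_start)(t/T)^γ_τ),
```

so the coarse end of the chain is white-dominated (global structure) and the
fine end blue-dominated (local, high-frequency detail).  Blue noise —
spectral energy concentrated at high spatial frequencies — is generated by
simulated annealing of 50%-density binary masks toward a high-pass radial
spectrum, followed by Cholesky factorization of the mask-ensemble
covariance (`C' = L L^T`, `ε_blue = L z`).  Training minimizes the
conditional denoising objective

```
min_θ  E_{x0, ε̃, t} ‖ ε̃ − ε_θ(x_t^mis, t | x_0^obs) ‖²
```

with CSDI-style masked self-supervision, and imputation runs the reverse
chain from `N(0, I)`, producing a posterior sample stack scored by MAE/RMSE
(point) and CRPS (probabilistic).

The package is aimed at method developers and computational biologists who
want a self-contained, CPU-scale, fully reproducible implementation of the
structured-noise diffusion imputer: every component — annealer, Cholesky
sampler, blending schedule, diffusion core, denoiser (numpy, hand-derived
backpropagation), training loop, metrics — is in plain scientific Python.

## Worked example

```python
import numpy as np
from bluediff import (SyntheticConfig, simulate, apply_mcar_mask,
                      BlueNoiseDiffusionImputer, mae, rmse, crps_field,
                      mean_imputation)

data = simulate(SyntheticConfig(n_samples=20, K=4, L=24, seed=1))
masked, hidden = apply_mcar_mask(data, 0.3, np.random.default_rng(0))

model = BlueNoiseDiffusionImputer(n_iter=2000, n_masks=16, anneal_sweeps=2000,
                                  n_posterior_samples=10, random_state=0)
model.fit(masked)                      # anneal masks, build sampler, train
stack, completed = model.sample(masked)  # posterior stack + median estimate

truth = np.nan_to_num(data.values)
print(f"MAE  (diffusion): {mae(completed, truth, hidden):.3f}")
print(f"RMSE (diffusion): {rmse(completed, truth, hidden):.3f}")
print(f"CRPS (diffusion): {crps_field(stack, truth, hidden):.3f}")
print(f"MAE  (mean imputation): {mae(mean_imputation(masked), truth, hidden):.3f}")
```

Output:

```
MAE  (diffusion): 0.536
RMSE (diffusion): 0.682
CRPS (diffusion): 0.476
MAE  (mean imputation): 0.680
```

574 of 1920 observed entries were hidden at random (30%); the trained model
recovers them with ~21% lower MAE than per-feature mean substitution, and
the CRPS scores the full predictive distribution from the 10-draw posterior
stack.  `model.transform(masked)` returns the completed matrix directly
(observed entries are passed through untouched), and the estimator composes
with scikit-learn (`get_params` / `set_params` / `clone`).

A thin CLI wraps the same library: `bluediff simulate`, `generate-noise`,
`train`, `impute`, `evaluate`, `schedule` (see `bluediff --help`).

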