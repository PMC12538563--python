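# Methods

`bluediff` imputes missing entries of multivariate time series with a
conditional denoising diffusion model whose injected noise is a time-varying
blend of isotropic white noise and spatially structured *blue* noise.  This
note records the model, the numerical choices, and what the package's tests
do and do not establish.

## Problem setup

A record is a matrix `X ∈ R^{K×L}` (K features at L time points) with a
binary observation mask `M` and timestamps `s`.  The goal is the conditional
distribution `p(X^mis | X^obs, M, s)`.  Records are normalized per feature
(center/scale from observed entries only, sample SD with denominator n−1,
pooled over training records — no information from evaluation entries leaks
into the statistics; constant features are flagged and mapped to zero).

## Blue-noise generation

Blue noise suppresses low spatial frequencies.  The sampler is built in two
stages:

1. **Annealed binary masks.** A 50%-density binary mask on the `L×K`
   (time × feature) grid is optimized by Metropolis simulated annealing: each
   sweep proposes one 1↔0 swap (density is conserved exactly), the objective
   is the mean squared deviation of the mask's radially binned 2-D Fourier
   magnitude from an ideal high-pass target, the temperature cools
   geometrically with factor `r = 0.995` and reheats by 1.2× when the
   trailing acceptance rate over 100 proposals falls below 0.02.  A run stops
   at temperature `1e-4`, energy `1e-4`, or 5000 sweeps.  The ideal radial
   spectrum is zero below a configurable cutoff (default 30% of the maximum
   radius) and rises linearly above it; it is rescaled so its mean matches
   the Monte-Carlo mean spectrum of random 50% masks (128 reference masks,
   fixed internal seed), so annealing redistributes spectral mass rather than
   shrinking it.  Radial bins are equal-width from the smallest to the
   largest non-DC frequency radius; the DC cell is excluded.
2. **Cholesky sampler.** N masks (default 64) are flattened time-major,
   centered, and their sample covariance `C = Mc^T Mc/(N−1)` is shrunk,
   `C' = (1−λ)C + λ·mean(diag C)·I` (default λ = 0.05), then factorized
   `C' = L L^T`.  Shrinkage is not optional: with N ≪ L·K the raw covariance
   is rank-deficient and has no Cholesky factor.  Blue fields are `L z` with
   `z ~ N(0, I)`.  By default the factor rows are *not* rescaled, so blue
   noise inherits the binary-mask variance (diagonal ≈ 0.25); an option
   standardizes every coordinate to unit variance.  Full spectrum
   recomputation per proposal (no incremental update) keeps the annealer
   trivially correct at the grid sizes used (≤ 64×64).

## Noise blending

At diffusion step `t` of `T` the injected noise is
`ε̃_t = γ_t ε_white + (1−γ_t) ε_blue` with
`γ_t = σ(γ_start + (γ_end−γ_start)(t/T)^γ_τ)`.
Defaults `(γ_start, γ_end, γ_τ) = (−6, 6, 1)`: the coarse end of the chain
(large t) is ~99.8% white, the fine-detail end ~0.2% white.  During training
the blue field reuses the white draw (`ε_blue = L ε_white`); at imputation
the two draws are independent.  Both behaviors sit behind a switch
(`shared_white_draw_*`).  No variance compensation is applied to `ε̃` by
default, so the blended noise has non-unit (and t-dependent) variance; this
is the literal algorithm and is deliberately left uncorrected.

## Diffusion machinery

Variance schedule: quadratic-in-√β table, `β_min = 1e-4`, `β_max = 0.5`,
`T = 50` (CSDI lineage), 0-based: `ᾱ_t = Π_{i≤t} α_i`.  Training draws
`t ~ U{0..T−1}` and corrupts the target component
`x_t = √ᾱ_t x_0 + √(1−ᾱ_t) ε̃` (the square roots are restored; without them
the process is not variance-preserving and the reverse coefficients would be
inconsistent).  The reverse chain runs `t = T−1 .. 0`:
`x_{t−1} = (x_t − β_t/√(1−ᾱ_t) ε̂)/√α_t`, plus `σ_t ε̃` for `t > 0` with
`σ_t = √((1−ᾱ_{t−1})/(1−ᾱ_t)·β_t)`; the final step adds no noise.

**Stability.** In production the reverse step is computed in the
algebraically equivalent posterior-mean form with the implied clean-signal
estimate `x̂_0 = (x_t − √(1−ᾱ_t) ε̂)/√ᾱ_t` clipped to ±5 normalized units.
When the clip does not bind this is bit-for-bit the plain update; when the
learned noise prediction is imperfect it prevents the exponential blow-up
that 50 successive `1/√α_t` amplifications otherwise permit.  The guard is
disableable (`x0_clip=None`), and the white-noise-equivalence tests run
unclipped.

## Denoiser

`ε_θ(x_t^mis, t | x_0^obs)` is a two-hidden-layer ReLU network (default
width 128) over the flattened grid, written directly in numpy with
hand-derived backpropagation and Adam (lr 1e-3) — the forward pass, backward
pass and optimizer are all part of the package and are verified against
finite differences.  Input channels: the noisy target field, the observed
conditioning values, a per-feature linear interpolation of the conditioning
values over time (a dense rough guess for the network to refine; computed
from conditioning entries only), both masks, normalized timestamps, and a
16-dim sinusoidal step embedding.  Two learned scalar heads on the step
embedding gate skip connections from the noisy-input and interpolation
channels to the output: the optimal noise prediction is approximately a
t-dependent linear combination of those two channels, and without the skips
a narrow dense network cannot represent the per-position passthroughs
(width < K·L), which makes the reverse chain amplify instead of contract.

Training is CSDI-style self-supervision: the observed entries of each record
are split into a conditioning set and a target set (masking fraction drawn
uniformly per record by default); the noisy input channel covers everything
*outside* the conditioning set — truly missing entries included — so the
input layout at training time matches the one at imputation time, while the
loss is scored only on held-out observed entries.

## Imputation and scoring

Missing entries are initialized `N(0, I)` and refined through the reverse
chain; `n` independent trajectories (default 10) give a posterior stack, the
per-entry median is the point estimate, and observed entries are never
modified anywhere (asserted in tests).  MAE and RMSE are computed over
evaluation-mask entries only; CRPS uses the energy-form estimator
`mean|X−x| − ½·mean|X−X′|` over all ordered pairs (denominator m²), which
equals the integral of the squared CDF-step difference for an empirical CDF;
a sorted O(m log m) identity replaces the quadratic pairwise sum above
m = 1000 and is tested for equality.  CRPS is aggregated as the unweighted
mean over evaluation entries and is not normalized by the mean absolute
target (a flag enables that variant).  The benchmark harness repeats MCAR
masking at rates {0.1, 0.3, 0.5, 0.7, 0.9} with per-cell seeds and reports
mean ± standard error (SD/√n) over repeats.

## Synthetic data

The generator emulates the structure the method targets: per-feature
low-frequency sinusoidal trends (0.5–2 cycles per record, random phase per
record and feature), a high-frequency oscillation (8–14 cycles, amplitude
0.4, one phase per record shared across features — a coherent fast process
driving all features, as in co-regulated gene programs; with an independent
phase per trace the high-frequency band would be unrecoverable from ~10%
observations and no imputer could be distinguished on it), and Gaussian
noise (SD 0.1) sharing a per-time-point latent across features
(correlation 0.3).  It does **not** emulate: count statistics or zero
inflation of real scRNA-seq data, irregular sampling, heavy tails, or
feature-specific missingness mechanisms.  Tests passing on this surrogate
therefore establish mechanical and statistical correctness of the pipeline,
not performance claims on real clinical or single-cell data.

## Experiment scales

Desk-scale problem sizes are used throughout: the summary experiment
(`bluediff.experiments.blend_vs_white_mae`) trains on 300 records of 8×48 at
90% MCAR for 2000 optimizer steps per model and imputes with 10 posterior
draws, averaged over 3 protocol seeds; the test suite uses 20-record
datasets for learning-progress checks.  These sizes were chosen so the full
pipeline (annealing, training, multi-draw imputation) runs end-to-end on a
single CPU core in minutes.

## Known limitations

- The denoiser is a dense MLP, not the attention architecture of the CSDI
  family.  In our experiments the blended-noise and white-noise variants
  train to statistically indistinguishable imputers on the surrogate data
  (relative MAE difference within ±2% across seeds, model widths 128–512 and
  2000–5000 optimizer steps): a dense network on a flattened grid is largely
  insensitive to the spatial spectrum of the training noise, so the
  high-sparsity advantage reported for attention-based denoisers does not
  reproduce at this scale.  The package reports the measured difference
  rather than asserting the published one.
- The 2-D spectral target treats the feature axis as spatially meaningful
  even though feature order is arbitrary; this follows the algorithm as
  written.
- Timestamps are carried to the denoiser as an embedding but the grid is
  otherwise treated as regular; no irregular-sampling alignment is done.
- `σ_1` is small but nonzero under the 0-based schedule convention; the
  final reverse step adds no noise.
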