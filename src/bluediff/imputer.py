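"""Self-supervised masked training and multi-draw imputation, wrapped in a
scikit-learn-style estimator.

Training: per record, the observed entries are partitioned into a
conditioning set and a target set; a diffusion step is drawn uniformly from
``{0..T-1}``; white noise is drawn and (in blend mode) colored through the
blue-noise Cholesky factor, mixed with coefficient ``gamma_t``; the target
component is corrupted by forward diffusion; and the denoiser is fit to the
injected noise by masked MSE.

Imputation: the truly missing entries are initialized from N(0, I) and
refined through the reverse chain ``t = T-1 .. 0``; at each noisy step the
same blended-noise construction supplies the injected perturbation (white and
blue draws independent by default at inference).  Multiple reverse
trajectories give a posterior sample stack; the per-entry median is the point
estimate.  Observed entries are never modified.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .bluenoise import AnnealingConfig, BlueNoiseSampler, make_blue_noise_sampler
from .data import NormalizationStats, TimeSeriesDataset, denormalize, normalize
from .diffusion import (
    Adam,
    DiffusionParams,
    MLPDenoiser,
    forward_diffuse,
    make_diffusion_params,
    posterior_sigma,
    reverse_mean,
)
from .schedule import BlendSchedule, blend, gamma_t

__all__ = [
    "make_training_target",
    "training_step",
    "train",
    "impute_sample",
    "impute",
    "BlueNoiseDiffusionImputer",
]


def make_training_target(
    mask: np.ndarray,
    strategy: str = "random_ratio",
    rng: np.random.Generator | None = None,
    fixed_ratio: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition one record's observed entries into conditioning and target sets.

    ``random_ratio`` draws a masking fraction uniformly per record;
    ``fixed_ratio`` always hides the given fraction.  The two returned masks
    are disjoint and their union is the observed set.  A record with no
    observed entries yields two empty masks with a warning.
    """
    mask = np.asarray(mask)
    rng = rng or np.random.default_rng()
    obs = np.flatnonzero(mask.ravel())
    cond = np.zeros(mask.size, dtype=np.uint8)
    targ = np.zeros(mask.size, dtype=np.uint8)
    if obs.size == 0:
        warnings.warn("record has no observed entries; skipping", stacklevel=2)
        return cond.reshape(mask.shape), targ.reshape(mask.shape)
    if strategy == "random_ratio":
        ratio = rng.uniform(0.0, 1.0)
    elif strategy == "fixed_ratio":
        if not 0.0 <= fixed_ratio <= 1.0:
            raise ValueError("fixed_ratio must lie in [0, 1]")
        ratio = fixed_ratio
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    n_hide = int(round(ratio * obs.size))
    hidden = rng.permutation(obs)[:n_hide]
    targ[hidden] = 1
    cond[obs] = 1
    cond[hidden] = 0
    return cond.reshape(mask.shape), targ.reshape(mask.shape)


def _color_batch(sampler: BlueNoiseSampler, z: np.ndarray) -> np.ndarray:
    """Apply the Cholesky factor to a batch of (B, K, L) fields.

    The factor lives on the row-major (time-first) flattening of the (L, K)
    grid, so fields are transposed before flattening and back after coloring.
    """
    B, K, L = z.shape
    if sampler.shape != (L, K):
        raise ValueError(f"sampler built for grid {sampler.shape}, data grid is {(L, K)}")
    flat = z.transpose(0, 2, 1).reshape(B, L * K)
    colored = flat @ sampler.factor.T
    return colored.reshape(B, L, K).transpose(0, 2, 1)


def _blended_noise(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    sampler: BlueNoiseSampler | None,
    gamma,
    shared_white_draw: bool,
    white_only: bool,
):
    """Draw the injected noise field: white, or the white/blue blend."""
    eps_white = rng.standard_normal(shape)
    if white_only:
        return eps_white
    if np.isscalar(gamma) and gamma == 1.0:
        # degenerate blend: the blue field carries zero weight; keep the
        # rng draw pattern identical to the general path
        if not shared_white_draw:
            rng.standard_normal(shape)
        return eps_white
    if sampler is None:
        raise ValueError("blend mode requires a blue-noise sampler")
    z = eps_white if shared_white_draw else rng.standard_normal(shape)
    eps_blue = _color_batch(sampler, z)
    g = gamma if np.isscalar(gamma) else np.asarray(gamma)[:, None, None]
    return blend(g, eps_white, eps_blue)


def training_step(
    model: MLPDenoiser,
    batch: dict,
    params: DiffusionParams,
    schedule: BlendSchedule | None,
    sampler: BlueNoiseSampler | None,
    rng: np.random.Generator,
    optimizer: Adam | None = None,
    target_strategy: str = "random_ratio",
    fixed_ratio: float = 0.5,
    shared_white_draw: bool = True,
    gamma_override: float | None = None,
) -> float:
    """One masked-denoising step on a batch; returns the loss.

    ``batch`` holds normalized ``values`` (B, K, L) with NaN at missing,
    ``mask`` and ``timestamps``.  ``gamma_override`` forces a constant mixing
    coefficient (1.0 reproduces the pure white-noise model bit-for-bit when
    the blue draw is shared); ``schedule=None`` with ``sampler=None`` runs the
    plain white-noise path.
    """
    values = np.asarray(batch["values"], dtype=float)
    mask = np.asarray(batch["mask"])
    timestamps = np.asarray(batch["timestamps"], dtype=float)
    B, K, L = values.shape
    x0 = np.where(mask == 1, values, 0.0)

    cond = np.empty_like(mask)
    targ = np.empty_like(mask)
    for i in range(B):
        cond[i], targ[i] = make_training_target(mask[i], target_strategy, rng, fixed_ratio)
    if targ.sum() == 0:
        raise ValueError("batch contains no target entries")

    t = rng.integers(0, params.T, size=B)
    white_only = schedule is None and gamma_override is None
    if gamma_override is not None:
        gamma = gamma_override
    elif schedule is not None:
        gamma = gamma_t(schedule, t)
    else:
        gamma = 1.0
    eps = _blended_noise(rng, (B, K, L), sampler, gamma, shared_white_draw, white_only)
    x_t = forward_diffuse(x0, t, eps, params)
    # the noisy input covers everything outside the conditioning set (truly
    # missing entries included), matching the imputation-time layout; the loss
    # is scored only on held-out observed entries
    input_target = 1.0 - cond.astype(float)
    loss, grads = model.loss_and_grads(
        x_t, x0, cond.astype(float), input_target, t, timestamps, eps,
        loss_mask=targ.astype(float),
    )
    if optimizer is not None:
        optimizer.step(model.params, grads)
    return loss


def train(
    dataset: TimeSeriesDataset,
    params: DiffusionParams,
    schedule: BlendSchedule | None,
    sampler: BlueNoiseSampler | None,
    n_iter: int = 2000,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    hidden_dim: int = 128,
    t_embed_dim: int = 16,
    target_strategy: str = "random_ratio",
    fixed_ratio: float = 0.5,
    shared_white_draw: bool = True,
    gamma_override: float | None = None,
    seed: int = 0,
    model: MLPDenoiser | None = None,
) -> tuple[MLPDenoiser, list[float]]:
    """Run ``n_iter`` masked-denoising steps on a normalized dataset.

    Fully reproducible under ``seed``; aborts if the loss turns non-finite.
    """
    rng = np.random.default_rng(seed)
    if model is None:
        model = MLPDenoiser(dataset.K, dataset.L, hidden_dim, t_embed_dim,
                            seed=int(rng.integers(2**31)))
    optimizer = Adam(lr=learning_rate)
    trace: list[float] = []
    n = dataset.n_samples
    for _ in range(n_iter):
        idx = rng.choice(n, size=min(batch_size, n), replace=False)
        batch = {
            "values": dataset.values[idx],
            "mask": dataset.mask[idx],
            "timestamps": dataset.timestamps[idx],
        }
        loss = training_step(
            model, batch, params, schedule, sampler, rng, optimizer,
            target_strategy, fixed_ratio, shared_white_draw, gamma_override,
        )
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged: loss={loss} at step {len(trace)}")
        trace.append(loss)
    return model, trace


def _reverse_chain(
    model: MLPDenoiser,
    cond_vals: np.ndarray,
    cond_mask: np.ndarray,
    target_mask: np.ndarray,
    timestamps: np.ndarray,
    params: DiffusionParams,
    schedule: BlendSchedule | None,
    sampler: BlueNoiseSampler | None,
    rng: np.random.Generator,
    shared_white_draw: bool = False,
    gamma_override: float | None = None,
    x0_clip: float | None = 5.0,
) -> np.ndarray:
    """Run the reverse diffusion chain for a batch; returns the final field.

    With ``x0_clip`` set, each step converts the predicted noise into the
    implied clean-signal estimate ``x0_hat = (x_t - sqrt(1 - ab_t) eps_hat) /
    sqrt(ab_t)``, clips it to the plausible normalized data range, and takes
    the exact posterior mean of the clipped estimate — identical to the plain
    update whenever the clip does not bind, and contractive when the learned
    noise prediction is imperfect.  ``None`` runs the literal unclipped
    update.
    """
    B, K, L = cond_vals.shape
    x = rng.standard_normal((B, K, L))
    white_only = schedule is None and gamma_override is None
    for t in range(params.T - 1, -1, -1):
        eps_hat = model.predict(x, cond_vals, cond_mask, target_mask, t, timestamps)
        if x0_clip is None:
            x = reverse_mean(x, eps_hat, t, params)
        else:
            ab = params.alpha_bar[t]
            ab_prev = params.alpha_bar_prev(t)
            x0_hat = (x - np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(ab)
            x0_hat = np.clip(x0_hat, -x0_clip, x0_clip)
            x = (
                np.sqrt(ab_prev) * params.beta[t] / (1.0 - ab) * x0_hat
                + np.sqrt(params.alpha[t]) * (1.0 - ab_prev) / (1.0 - ab) * x
            )
        if t > 0:
            if gamma_override is not None:
                gamma = gamma_override
            elif schedule is not None:
                gamma = gamma_t(schedule, t)
            else:
                gamma = 1.0
            eps = _blended_noise(
                rng, (B, K, L), sampler, gamma, shared_white_draw, white_only
            )
            x = x + posterior_sigma(t, params) * eps
    return x


def impute_sample(
    model: MLPDenoiser,
    record: dict,
    params: DiffusionParams,
    schedule: BlendSchedule | None,
    sampler: BlueNoiseSampler | None,
    rng: np.random.Generator,
    shared_white_draw: bool = False,
    gamma_override: float | None = None,
    x0_clip: float | None = 5.0,
) -> np.ndarray:
    """One reverse trajectory for one record; returns values at missing entries.

    ``record`` holds normalized ``values`` (K, L), ``mask`` and ``timestamps``.
    The result is a vector over the missing entries in row-major (K, L) order;
    it is empty when the record is fully observed.
    """
    values = np.asarray(record["values"], dtype=float)
    mask = np.asarray(record["mask"])
    target = (mask == 0).astype(float)
    if target.sum() == 0:
        return np.empty(0)
    cond_vals = np.where(mask == 1, values, 0.0)[None]
    x = _reverse_chain(
        model, cond_vals, mask.astype(float)[None], target[None],
        np.asarray(record["timestamps"], float)[None], params, schedule, sampler,
        rng, shared_white_draw, gamma_override, x0_clip,
    )[0]
    return x[mask == 0]


def impute(
    model: MLPDenoiser,
    dataset: TimeSeriesDataset,
    params: DiffusionParams,
    schedule: BlendSchedule | None,
    sampler: BlueNoiseSampler | None,
    n_samples: int = 10,
    point_estimator: str = "median",
    seed: int = 0,
    shared_white_draw: bool = False,
    gamma_override: float | None = None,
    stats: NormalizationStats | None = None,
    x0_clip: float | None = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_samples`` posterior trajectories per record.

    Returns ``(stack, point)`` where ``stack`` has shape
    (n_samples, n_records, K, L) — observed entries carried through unchanged —
    and ``point`` is the per-entry median (or mean) across draws.  When
    ``stats`` is given, outputs are denormalized.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if point_estimator not in {"median", "mean"}:
        raise ValueError("point_estimator must be 'median' or 'mean'")
    rng = np.random.default_rng(seed)
    values = dataset.values
    mask = dataset.mask
    cond_vals = np.where(mask == 1, values, 0.0)
    target = (mask == 0).astype(float)
    draws = []
    for _ in range(n_samples):
        x = _reverse_chain(
            model, cond_vals, mask.astype(float), target, dataset.timestamps,
            params, schedule, sampler, rng, shared_white_draw, gamma_override,
            x0_clip,
        )
        draws.append(np.where(mask == 1, values, x))
    stack = np.stack(draws)
    point = np.median(stack, axis=0) if point_estimator == "median" else stack.mean(axis=0)
    point = np.where(mask == 1, values, point)
    if stats is not None:
        scale = stats.scale[None, :, None]
        center = stats.center[None, :, None]
        stack = stack * scale[None] + center[None]
        point = point * scale + center
    return stack, point


class BlueNoiseDiffusionImputer(TransformerMixin, BaseEstimator):
    """Diffusion-based imputer with a time-varying white/blue noise blend.

    Accepts arrays of shape ``(n_records, K, L)`` with NaN marking missing
    entries (or a :class:`~bluediff.data.TimeSeriesDataset`).  ``fit`` learns
    per-feature normalization from observed entries, anneals a blue-noise
    sampler on the record grid, and trains the conditional denoiser by masked
    self-supervision; ``transform`` fills the missing entries with the
    per-entry median over ``n_posterior_samples`` reverse trajectories, on the
    original data scale.

    Parameters
    ----------
    noise_mode : {"blend", "white"}
        "blend" injects ``gamma_t * white + (1 - gamma_t) * blue``;
        "white" is the plain white-noise (vanilla CSDI-style) model.
    gamma_override : float or None
        Force a constant mixing coefficient (diagnostics; 1.0 with shared
        draws reproduces the white model exactly).
    shared_white_draw_train / shared_white_draw_infer : bool
        Whether the blue draw reuses the white draw (training default) or is
        independent (inference default).
    """

    def __init__(
        self,
        *,
        T: int = 50,
        beta_min: float = 1e-4,
        beta_max: float = 0.5,
        schedule_kind: str = "quadratic",
        gamma_start: float = -6.0,
        gamma_end: float = 6.0,
        gamma_tau: float = 1.0,
        noise_mode: str = "blend",
        gamma_override: float | None = None,
        n_masks: int = 64,
        n_bins: int | None = None,
        cutoff_fraction: float = 0.3,
        shrinkage: float = 0.05,
        standardize_noise: bool = False,
        anneal_sweeps: int = 5000,
        hidden_dim: int = 128,
        t_embed_dim: int = 16,
        n_iter: int = 2000,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        target_strategy: str = "random_ratio",
        fixed_ratio: float = 0.5,
        shared_white_draw_train: bool = True,
        shared_white_draw_infer: bool = False,
        n_posterior_samples: int = 10,
        point_estimator: str = "median",
        x0_clip: float | None = 5.0,
        random_state: int = 0,
    ):
        self.T = T
        self.beta_min = beta_min
        self.beta_max = beta_max
        self.schedule_kind = schedule_kind
        self.gamma_start = gamma_start
        self.gamma_end = gamma_end
        self.gamma_tau = gamma_tau
        self.noise_mode = noise_mode
        self.gamma_override = gamma_override
        self.n_masks = n_masks
        self.n_bins = n_bins
        self.cutoff_fraction = cutoff_fraction
        self.shrinkage = shrinkage
        self.standardize_noise = standardize_noise
        self.anneal_sweeps = anneal_sweeps
        self.hidden_dim = hidden_dim
        self.t_embed_dim = t_embed_dim
        self.n_iter = n_iter
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.target_strategy = target_strategy
        self.fixed_ratio = fixed_ratio
        self.shared_white_draw_train = shared_white_draw_train
        self.shared_white_draw_infer = shared_white_draw_infer
        self.n_posterior_samples = n_posterior_samples
        self.point_estimator = point_estimator
        self.x0_clip = x0_clip
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------
    @staticmethod
    def _as_dataset(X) -> TimeSeriesDataset:
        if isinstance(X, TimeSeriesDataset):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(f"expected (n_records, K, L) array, got shape {X.shape}")
        mask = (~np.isnan(X)).astype(np.uint8)
        n, _, L = X.shape
        ts = np.broadcast_to(np.arange(L, dtype=float), (n, L)).copy()
        return TimeSeriesDataset(X, mask, ts)

    def _blend_components(self):
        if self.noise_mode == "white" and self.gamma_override is None:
            return None, None
        return self.schedule_, self.sampler_

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y=None):
        if self.noise_mode not in {"blend", "white"}:
            raise ValueError("noise_mode must be 'blend' or 'white'")
        dataset = self._as_dataset(X)
        ss = np.random.SeedSequence(self.random_state)
        s_anneal, s_train = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
        norm, self.stats_ = normalize(dataset)
        self.diffusion_ = make_diffusion_params(
            self.schedule_kind, self.T, self.beta_min, self.beta_max
        )
        self.schedule_ = BlendSchedule(self.gamma_start, self.gamma_end,
                                       self.gamma_tau, self.T)
        if self.noise_mode == "blend" or self.gamma_override is not None:
            self.sampler_ = make_blue_noise_sampler(
                dataset.L, dataset.K,
                n_masks=self.n_masks, n_bins=self.n_bins,
                cutoff_fraction=self.cutoff_fraction, shrinkage=self.shrinkage,
                standardize=self.standardize_noise,
                annealing=AnnealingConfig(S=self.anneal_sweeps, seed=s_anneal),
                rng=np.random.default_rng(s_anneal),
            )
        else:
            self.sampler_ = None
        schedule, sampler = self._blend_components()
        self.model_, self.loss_trace_ = train(
            norm, self.diffusion_, schedule, sampler,
            n_iter=self.n_iter, batch_size=self.batch_size,
            learning_rate=self.learning_rate, hidden_dim=self.hidden_dim,
            t_embed_dim=self.t_embed_dim, target_strategy=self.target_strategy,
            fixed_ratio=self.fixed_ratio,
            shared_white_draw=self.shared_white_draw_train,
            gamma_override=self.gamma_override, seed=s_train,
        )
        self.n_features_in_ = dataset.K
        return self

    def sample(self, X, n_samples: int | None = None, seed: int | None = None):
        """Posterior sample stack (n_samples, n_records, K, L), original scale."""
        if not hasattr(self, "model_"):
            raise ValueError("imputer is not fitted")
        dataset = self._as_dataset(X)
        if dataset.K != self.n_features_in_:
            raise ValueError("feature count differs from the fitted data")
        norm, _ = normalize(dataset, self.stats_)
        schedule, sampler = self._blend_components()
        stack, point = impute(
            self.model_, norm, self.diffusion_, schedule, sampler,
            n_samples=n_samples or self.n_posterior_samples,
            point_estimator=self.point_estimator,
            seed=self.random_state + 1 if seed is None else seed,
            shared_white_draw=self.shared_white_draw_infer,
            gamma_override=self.gamma_override, stats=self.stats_,
            x0_clip=self.x0_clip,
        )
        return stack, point

    def transform(self, X):
        """Return a completed copy of ``X`` (observed entries untouched)."""
        _, point = self.sample(X)
        return point

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)
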