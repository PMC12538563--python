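"""DDPM-style forward/reverse machinery and the conditional noise predictor.

Conventions (CSDI lineage): the variance schedule is a length-``T`` table
``beta[0..T-1]`` with ``alpha_t = 1 - beta_t`` and
``alpha_bar[t] = prod_{i<=t} alpha_i``.  Training samples a step
``t ~ U{0..T-1}`` and corrupts the target component as
``sqrt(alpha_bar_t) x0 + sqrt(1 - alpha_bar_t) eps``; the reverse chain runs
``t = T-1 .. 0`` with mean update
``(x_t - beta_t / sqrt(1 - alpha_bar_t) * eps_hat) / sqrt(alpha_t)`` and
posterior noise scale ``sigma_t = sqrt((1 - alpha_bar_{t-1}) / (1 - alpha_bar_t) * beta_t)``
for ``t >= 1`` (no noise is added at the final step).

The noise predictor ``eps_theta(x_t^mis, t | x_0^obs)`` is a fully connected
network written directly in numpy (forward pass, hand-derived backward pass,
Adam updates), conditioned on the observed values, the conditional/target
masks, the timestamps, and a sinusoidal embedding of the diffusion step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiffusionParams",
    "make_diffusion_params",
    "forward_diffuse",
    "reverse_mean",
    "posterior_sigma",
    "step_embedding",
    "MLPDenoiser",
    "Adam",
]


@dataclass
class DiffusionParams:
    """Tables beta / alpha / alpha_bar over ``T`` diffusion steps."""

    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray
    schedule_kind: str = "quadratic"

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (self.T,):
            raise ValueError("beta must have length T")
        if np.any(self.beta <= 0) or np.any(self.beta >= 1):
            raise ValueError("beta entries must lie in (0, 1)")
        if np.any(np.diff(self.alpha_bar) >= 0):
            raise ValueError("alpha_bar must be strictly decreasing")

    def alpha_bar_prev(self, t: int) -> float:
        """alpha_bar at step t-1, defined as 1 for t == 0."""
        return 1.0 if t == 0 else float(self.alpha_bar[t - 1])


def make_diffusion_params(
    kind: str = "quadratic", T: int = 50, beta_min: float = 1e-4, beta_max: float = 0.5
) -> DiffusionParams:
    """Tabulate the variance schedule.

    ``quadratic``: beta_t = (sqrt(beta_min) + t/(T-1) * (sqrt(beta_max) -
    sqrt(beta_min)))**2 — the CSDI default; ``linear``: evenly spaced.
    """
    if not 0.0 < beta_min < beta_max < 1.0:
        raise ValueError("require 0 < beta_min < beta_max < 1")
    if T < 1:
        raise ValueError("T must be >= 1")
    if T == 1:
        beta = np.array([beta_min])
    elif kind == "quadratic":
        root = np.sqrt(beta_min) + np.arange(T) / (T - 1) * (
            np.sqrt(beta_max) - np.sqrt(beta_min)
        )
        beta = root**2
    elif kind == "linear":
        beta = np.linspace(beta_min, beta_max, T)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    alpha = 1.0 - beta
    return DiffusionParams(
        T=T, beta=beta, alpha=alpha, alpha_bar=np.cumprod(alpha), schedule_kind=kind
    )


def forward_diffuse(
    x0: np.ndarray, t, noise: np.ndarray, params: DiffusionParams
) -> np.ndarray:
    """Corrupt ``x0`` to step ``t``: sqrt(ab_t) x0 + sqrt(1 - ab_t) noise.

    ``t`` may be a scalar or a per-sample integer array broadcast over leading
    batch dimensions.
    """
    x0 = np.asarray(x0, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if x0.shape != noise.shape:
        raise ValueError(f"shape mismatch {x0.shape} vs {noise.shape}")
    t = np.asarray(t)
    if np.any(t < 0) or np.any(t >= params.T):
        raise ValueError(f"step t must lie in [0, {params.T - 1}]")
    ab = params.alpha_bar[t]
    ab = np.reshape(ab, np.shape(ab) + (1,) * (x0.ndim - np.ndim(ab)))
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * noise


def reverse_mean(
    x_t: np.ndarray, eps_hat: np.ndarray, t: int, params: DiffusionParams
) -> np.ndarray:
    """Reverse-step mean: (x_t - beta_t / sqrt(1 - ab_t) * eps_hat) / sqrt(alpha_t)."""
    if not 0 <= t < params.T:
        raise ValueError(f"step t={t} out of range [0, {params.T - 1}]")
    x_t = np.asarray(x_t, dtype=float)
    eps_hat = np.asarray(eps_hat, dtype=float)
    if x_t.shape != eps_hat.shape:
        raise ValueError(f"shape mismatch {x_t.shape} vs {eps_hat.shape}")
    coeff = params.beta[t] / np.sqrt(1.0 - params.alpha_bar[t])
    return (x_t - coeff * eps_hat) / np.sqrt(params.alpha[t])


def posterior_sigma(t: int, params: DiffusionParams) -> float:
    """Posterior noise scale sqrt((1 - ab_{t-1}) / (1 - ab_t) * beta_t), t >= 1.

    The final reverse step (t = 0) adds no noise; asking for its sigma is an
    error rather than zero so the guard cannot be silently skipped.
    """
    if t < 1:
        raise ValueError("posterior sigma is defined for t >= 1 (final step adds no noise)")
    if t >= params.T:
        raise ValueError(f"step t={t} out of range")
    num = 1.0 - params.alpha_bar[t - 1]
    den = 1.0 - params.alpha_bar[t]
    return float(np.sqrt(num / den * params.beta[t]))


# ---------------------------------------------------------------------------
# denoiser
# ---------------------------------------------------------------------------


def step_embedding(t, dim: int = 16, max_steps: int = 10000) -> np.ndarray:
    """Sinusoidal embedding of integer diffusion steps; shape (..., dim)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    half = dim // 2
    freqs = max_steps ** (-np.arange(half) / max(half, 1))
    ang = t[..., None] * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=-1)


def _relu(x):
    return np.maximum(x, 0.0)


def _interp_channel(cond_vals: np.ndarray, cond_mask: np.ndarray,
                    timestamps: np.ndarray) -> np.ndarray:
    """Per-record, per-feature linear interpolation of conditioning values
    over time; zero where a trace has no conditioning entry."""
    B, K, L = cond_vals.shape
    out = np.zeros((B, K, L))
    for i in range(B):
        t = timestamps[i]
        for k in range(K):
            m = cond_mask[i, k] > 0
            if m.any():
                out[i, k] = np.interp(t, t[m], cond_vals[i, k, m])
    return out


class Adam:
    """Adaptive-moment gradient descent over a dict of parameter arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class DenoiserConfig:
    hidden_dim: int = 128
    t_embed_dim: int = 16


class MLPDenoiser:
    """Conditional noise predictor eps_theta(x_t^mis, t | x_0^obs).

    A two-hidden-layer ReLU network over the flattened grid.  Per-record input
    channels: the noisy target field (zeros off the target support), the
    observed conditioning values (zeros on the target support), a per-feature
    linear interpolation of the conditioning values over time (a dense rough
    guess for the network to refine, built from conditioning entries only so
    no target information leaks), the conditional mask, the target mask, the
    normalized timestamps, and a sinusoidal embedding of ``t``.  Output has the grid shape; the loss is the
    mean squared error against the injected noise over target entries only.

    A learned skip connection ``coef(t) * x_t`` (scalar coefficient from a
    linear head on the step embedding) is added to the network output: at
    high noise levels the optimal noise prediction is close to the noisy
    input itself, so the skip keeps the reverse chain contractive while the
    nonlinear part learns the data-dependent correction.
    """

    def __init__(self, K: int, L: int, hidden_dim: int = 128, t_embed_dim: int = 16,
                 seed: int = 0):
        self.K, self.L = K, L
        self.config = DenoiserConfig(hidden_dim=hidden_dim, t_embed_dim=t_embed_dim)
        d_in = 5 * K * L + L + t_embed_dim
        d_out = K * L
        h = hidden_dim
        rng = np.random.default_rng(seed)
        # He initialization
        self.params = {
            "W1": rng.standard_normal((d_in, h)) * np.sqrt(2.0 / d_in),
            "b1": np.zeros(h),
            "W2": rng.standard_normal((h, h)) * np.sqrt(2.0 / h),
            "b2": np.zeros(h),
            "W3": rng.standard_normal((h, d_out)) * np.sqrt(2.0 / h),
            "b3": np.zeros(d_out),
            # skip heads: coef(t) = emb_t @ w + b, applied to the noisy-input
            # and interpolation channels respectively
            "w_skip": np.zeros(t_embed_dim),
            "b_skip": np.array([0.7]),
            "w_skip2": np.zeros(t_embed_dim),
            "b_skip2": np.array([0.0]),
        }

    # -- feature assembly ---------------------------------------------------
    def _features(self, x_t, cond_vals, cond_mask, target_mask, t, timestamps):
        B = x_t.shape[0]
        KL = self.K * self.L
        for name, arr in (("x_t", x_t), ("cond_vals", cond_vals),
                          ("cond_mask", cond_mask), ("target_mask", target_mask)):
            if arr.shape != (B, self.K, self.L):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(B, self.K, self.L)}")
        if timestamps.shape != (B, self.L):
            raise ValueError("timestamps shape mismatch")
        s = timestamps / np.maximum(np.abs(timestamps).max(axis=1, keepdims=True), 1.0)
        emb = step_embedding(np.asarray(t), dim=self.config.t_embed_dim)
        emb = np.broadcast_to(emb.reshape(-1, self.config.t_embed_dim), (B, self.config.t_embed_dim)).copy()
        xt_flat = (x_t * target_mask).reshape(B, KL)
        interp_flat = _interp_channel(cond_vals, cond_mask, timestamps).reshape(B, KL)
        X = np.concatenate(
            [
                xt_flat,
                (cond_vals * cond_mask).reshape(B, KL),
                interp_flat,
                cond_mask.reshape(B, KL).astype(float),
                target_mask.reshape(B, KL).astype(float),
                s,
                emb,
            ],
            axis=1,
        )
        return X, xt_flat, interp_flat, emb

    def _forward(self, X, xt_flat, interp_flat, emb):
        z1 = X @ self.params["W1"] + self.params["b1"]
        h1 = _relu(z1)
        z2 = h1 @ self.params["W2"] + self.params["b2"]
        h2 = _relu(z2)
        coef = emb @ self.params["w_skip"] + self.params["b_skip"][0]
        coef2 = emb @ self.params["w_skip2"] + self.params["b_skip2"][0]
        out = (
            h2 @ self.params["W3"] + self.params["b3"]
            + coef[:, None] * xt_flat
            + coef2[:, None] * interp_flat
        )
        return out, (X, z1, h1, z2, h2, xt_flat, interp_flat, emb)

    def predict(self, x_t, cond_vals, cond_mask, target_mask, t, timestamps):
        """Predicted noise field, shape (B, K, L); deterministic in (theta, inputs)."""
        X, xt_flat, interp_flat, emb = self._features(
            np.asarray(x_t, float), np.asarray(cond_vals, float),
            np.asarray(cond_mask, float), np.asarray(target_mask, float),
            t, np.asarray(timestamps, float),
        )
        out, _ = self._forward(X, xt_flat, interp_flat, emb)
        return out.reshape(-1, self.K, self.L)

    def loss_and_grads(self, x_t, cond_vals, cond_mask, target_mask, t, timestamps,
                       eps_target, loss_mask=None):
        """Masked-MSE loss against the injected noise, with parameter gradients.

        ``target_mask`` shapes the input channels; ``loss_mask`` (default: the
        target mask) selects the entries actually scored, allowing the input
        target support to include truly missing entries whose noise target is
        unknown.
        """
        target_mask = np.asarray(target_mask, float)
        X, xt_flat, interp_flat, emb = self._features(
            np.asarray(x_t, float), np.asarray(cond_vals, float),
            np.asarray(cond_mask, float), target_mask, t, np.asarray(timestamps, float),
        )
        out, (Xc, z1, h1, z2, h2, xt_f, interp_f, emb_c) = self._forward(
            X, xt_flat, interp_flat, emb)
        B = out.shape[0]
        lm = target_mask if loss_mask is None else np.asarray(loss_mask, float)
        tm = lm.reshape(B, -1)
        denom = tm.sum()
        if denom == 0:
            raise ValueError("no target entries in batch")
        resid = (out - np.asarray(eps_target, float).reshape(B, -1)) * tm
        loss = float((resid**2).sum() / denom)
        d_out = 2.0 * resid / denom
        grads = {}
        d_coef = (d_out * xt_f).sum(axis=1)
        grads["w_skip"] = emb_c.T @ d_coef
        grads["b_skip"] = np.array([d_coef.sum()])
        d_coef2 = (d_out * interp_f).sum(axis=1)
        grads["w_skip2"] = emb_c.T @ d_coef2
        grads["b_skip2"] = np.array([d_coef2.sum()])
        grads["W3"] = h2.T @ d_out
        grads["b3"] = d_out.sum(axis=0)
        d_h2 = d_out @ self.params["W3"].T
        d_z2 = d_h2 * (z2 > 0)
        grads["W2"] = h1.T @ d_z2
        grads["b2"] = d_z2.sum(axis=0)
        d_h1 = d_z2 @ self.params["W2"].T
        d_z1 = d_h1 * (z1 > 0)
        grads["W1"] = Xc.T @ d_z1
        grads["b1"] = d_z1.sum(axis=0)
        return loss, grads

    def clone_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}
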