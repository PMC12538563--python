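"""Time-varying white/blue noise blending.

The mixing coefficient follows a sigmoid-warped power schedule over the
normalized diffusion step,

    gamma_t = sigmoid(gamma_start + (gamma_end - gamma_start) * (t / T)**gamma_tau),

and the injected noise is the convex-in-amplitude combination
``gamma_t * eps_white + (1 - gamma_t) * eps_blue``.  With the default
(gamma_start, gamma_end) = (-6, 6) the coarse end of the chain (large t) is
white-dominated and the fine-detail end (small t) blue-dominated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["BlendSchedule", "gamma_t", "blend"]


@dataclass
class BlendSchedule:
    gamma_start: float = -6.0
    gamma_end: float = 6.0
    gamma_tau: float = 1.0
    T: int = 50

    def __post_init__(self) -> None:
        if self.gamma_tau <= 0:
            raise ValueError("gamma_tau must be positive")
        if self.T < 1:
            raise ValueError("T must be >= 1")

    def __call__(self, t: int | np.ndarray) -> float | np.ndarray:
        return gamma_t(self, t)


def gamma_t(schedule: BlendSchedule, t):
    """Mixing coefficient at step ``t`` (scalar or array), strictly in (0, 1)."""
    t = np.asarray(t)
    if np.any(t < 0) or np.any(t > schedule.T):
        raise ValueError(f"step t must lie in [0, {schedule.T}]")
    frac = (t / schedule.T) ** schedule.gamma_tau
    out = expit(schedule.gamma_start + (schedule.gamma_end - schedule.gamma_start) * frac)
    return float(out) if out.ndim == 0 else out


def blend(gamma, white: np.ndarray, blue: np.ndarray) -> np.ndarray:
    """Elementwise ``gamma * white + (1 - gamma) * blue``.

    ``gamma`` may be a scalar or broadcastable array (per-sample coefficients).
    The degenerate cases gamma=1 / gamma=0 return the white / blue field
    bit-exactly.
    """
    white = np.asarray(white, dtype=float)
    blue = np.asarray(blue, dtype=float)
    if white.shape != blue.shape:
        raise ValueError(f"shape mismatch {white.shape} vs {blue.shape}")
    if np.isscalar(gamma) or np.ndim(gamma) == 0:
        if gamma == 1.0:
            return white.copy()
        if gamma == 0.0:
            return blue.copy()
    g = np.asarray(gamma, dtype=float)
    return g * white + (1.0 - g) * blue
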