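"""Independently coded plain-DDPM reference (white noise only), used as an
oracle against the package's machinery.  Kept deliberately separate from the
implementation: tables and updates are written from the textbook equations,
not imported from bluediff."""

import numpy as np


def ref_tables(T, beta_min, beta_max, kind="quadratic"):
    if T == 1:
        beta = np.array([beta_min])
    elif kind == "quadratic":
        beta = (
            np.sqrt(beta_min)
            + np.arange(T) / (T - 1) * (np.sqrt(beta_max) - np.sqrt(beta_min))
        ) ** 2
    else:
        beta = np.linspace(beta_min, beta_max, T)
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    return beta, alpha, alpha_bar


def ref_q_sample(x0, t, eps, alpha_bar):
    return np.sqrt(alpha_bar[t]) * x0 + np.sqrt(1.0 - alpha_bar[t]) * eps


def ref_reverse_trajectory(x_init, eps_fn, rng, beta, alpha, alpha_bar):
    """Reverse chain t = T-1 .. 0 with the standard DDPM update and posterior
    noise scale; ``eps_fn(x, t)`` supplies the noise prediction."""
    x = x_init.copy()
    T = len(beta)
    for t in range(T - 1, -1, -1):
        eps_hat = eps_fn(x, t)
        x = (x - beta[t] / np.sqrt(1.0 - alpha_bar[t]) * eps_hat) / np.sqrt(alpha[t])
        if t > 0:
            sigma = np.sqrt(
                (1.0 - alpha_bar[t - 1]) / (1.0 - alpha_bar[t]) * beta[t]
            )
            x = x + sigma * rng.standard_normal(x.shape)
    return x
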