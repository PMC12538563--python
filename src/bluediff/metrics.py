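"""Point and probabilistic imputation scoring, and the repeated-masking
benchmark harness.

MAE and RMSE are computed over evaluation-mask entries only.  CRPS uses the
energy-form estimator of the empirical predictive CDF,

    CRPS(F_m, x) = mean_i |X_i - x| - 1/2 mean_{i,j} |X_i - X_j|,

with the pairwise term over all ordered pairs (denominator m^2), which equals
the integral of the squared CDF-step difference exactly for an empirical CDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MaskingProtocol, TimeSeriesDataset, apply_mcar_mask

__all__ = [
    "mae",
    "rmse",
    "crps_empirical",
    "crps_field",
    "mean_imputation",
    "linear_interpolation",
    "EvaluationReport",
    "run_benchmark",
]


def _check_eval(pred, truth, eval_mask):
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    eval_mask = np.asarray(eval_mask)
    if pred.shape != truth.shape or pred.shape != eval_mask.shape:
        raise ValueError("pred, truth and eval_mask must share one shape")
    sel = eval_mask != 0
    if not sel.any():
        raise ValueError("evaluation mask selects no entries")
    return pred[sel], truth[sel]


def mae(pred, truth, eval_mask) -> float:
    """Mean absolute error over evaluation-mask entries."""
    p, t = _check_eval(pred, truth, eval_mask)
    return float(np.mean(np.abs(p - t)))


def rmse(pred, truth, eval_mask) -> float:
    """Root mean squared error over evaluation-mask entries."""
    p, t = _check_eval(pred, truth, eval_mask)
    return float(np.sqrt(np.mean((p - t) ** 2)))


def _mean_pairwise_abs(x: np.ndarray) -> float:
    """mean_{i,j} |x_i - x_j| over all ordered pairs (denominator m^2)."""
    m = x.size
    if m > 1000:
        # sorted O(m log m) identity: sum_{i<j}(x_(j) - x_(i)) via rank weights
        xs = np.sort(x)
        i = np.arange(m)
        total = np.sum((2 * i - m + 1) * xs)
        return float(2.0 * total / m**2)
    return float(np.abs(x[:, None] - x[None, :]).mean())


def crps_empirical(samples: np.ndarray, x: float) -> float:
    """Energy-form CRPS of an empirical forecast against one observation."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("need at least one forecast sample")
    term1 = float(np.mean(np.abs(samples - x)))
    return term1 - 0.5 * _mean_pairwise_abs(samples)


def crps_field(stack: np.ndarray, truth: np.ndarray, eval_mask: np.ndarray) -> float:
    """Unweighted mean CRPS over evaluation entries.

    ``stack`` has shape (m_draws, ...) matching ``truth`` after the first axis.
    """
    stack = np.asarray(stack, dtype=float)
    truth = np.asarray(truth, dtype=float)
    eval_mask = np.asarray(eval_mask)
    if stack.shape[1:] != truth.shape or truth.shape != eval_mask.shape:
        raise ValueError("shape mismatch between stack, truth and eval_mask")
    sel = eval_mask != 0
    if not sel.any():
        raise ValueError("evaluation mask selects no entries")
    S = stack[:, sel]  # (m, n_eval)
    m = S.shape[0]
    term1 = np.mean(np.abs(S - truth[sel][None, :]), axis=0)
    Ss = np.sort(S, axis=0)
    i = np.arange(m)[:, None]
    term2 = 2.0 * np.sum((2 * i - m + 1) * Ss, axis=0) / m**2
    return float(np.mean(term1 - 0.5 * term2))


# ---------------------------------------------------------------------------
# trivial reference imputers
# ---------------------------------------------------------------------------


def mean_imputation(dataset: TimeSeriesDataset) -> np.ndarray:
    """Fill missing entries with the per-feature observed mean."""
    out = dataset.values.copy()
    for k in range(dataset.K):
        obs = out[:, k, :][dataset.mask[:, k, :] == 1]
        fill = obs.mean() if obs.size else 0.0
        sub = out[:, k, :]
        sub[dataset.mask[:, k, :] == 0] = fill
    return out


def linear_interpolation(dataset: TimeSeriesDataset) -> np.ndarray:
    """Fill missing entries by per-record, per-feature linear interpolation
    over time (per-feature mean where a trace has no observed point)."""
    out = dataset.values.copy()
    feat_mean = np.zeros(dataset.K)
    for k in range(dataset.K):
        obs = dataset.values[:, k, :][dataset.mask[:, k, :] == 1]
        feat_mean[k] = obs.mean() if obs.size else 0.0
    for i in range(dataset.n_samples):
        t = dataset.timestamps[i]
        for k in range(dataset.K):
            m = dataset.mask[i, k] == 1
            if m.sum() == 0:
                out[i, k] = feat_mean[k]
            elif m.sum() == dataset.L:
                continue
            else:
                out[i, k, ~m] = np.interp(t[~m], t[m], dataset.values[i, k, m])
    return out


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Per (missing rate, metric) summary over repeated maskings."""

    rows: list[dict] = field(default_factory=list)

    def add(self, rate: float, metric: str, scores: list[float], seeds: list[int]):
        scores = np.asarray(scores, dtype=float)
        se = scores.std(ddof=1) / np.sqrt(len(scores)) if len(scores) > 1 else 0.0
        self.rows.append(
            {
                "missing_rate": rate,
                "metric": metric,
                "mean": float(scores.mean()),
                "se": float(se),
                "n_repeats": len(scores),
                "seeds": list(seeds),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def run_benchmark(
    model_factory,
    dataset: TimeSeriesDataset,
    protocol: MaskingProtocol,
    n_posterior_samples: int = 10,
) -> EvaluationReport:
    """Repeated-MCAR benchmark: mask, fit, impute, score.

    ``model_factory(seed)`` must return an unfitted estimator with
    ``fit`` and ``sample`` (a :class:`~bluediff.imputer.BlueNoiseDiffusionImputer`
    or anything honoring that contract).  For each rate and repeat a distinct
    masking seed is derived from the protocol seed; MAE/RMSE are scored on the
    point estimate and CRPS on the posterior stack, then summarized as mean
    and standard error per rate.
    """
    report = EvaluationReport()
    ss = np.random.SeedSequence(protocol.seed)
    children = ss.spawn(len(protocol.rates) * protocol.n_repeats)
    for ri, rate in enumerate(protocol.rates):
        scores = {"MAE": [], "RMSE": [], "CRPS": []}
        seeds = []
        for rep in range(protocol.n_repeats):
            child = children[ri * protocol.n_repeats + rep]
            seed = int(child.generate_state(1)[0] % 2**31)
            seeds.append(seed)
            rng = np.random.default_rng(seed)
            masked, eval_mask = apply_mcar_mask(dataset, rate, rng)
            model = model_factory(seed)
            model.fit(masked)
            stack, point = model.sample(masked, n_samples=n_posterior_samples)
            truth = np.nan_to_num(dataset.values)
            scores["MAE"].append(mae(point, truth, eval_mask))
            scores["RMSE"].append(rmse(point, truth, eval_mask))
            scores["CRPS"].append(crps_field(stack, truth, eval_mask))
        for metric, vals in scores.items():
            report.add(rate, metric, vals, seeds)
    return report
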