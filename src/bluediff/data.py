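"""Dataset container, delimited-text I/O, normalization, masking, and the
synthetic multivariate time-series generator.

A dataset is a stack of records, each a ``K x L`` matrix (``K`` features
observed at ``L`` time points) with a binary observation mask and a strictly
increasing timestamp vector.  Missing entries are carried as NaN internally and
never participate in any statistic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesDataset",
    "NormalizationStats",
    "MaskingProtocol",
    "SyntheticConfig",
    "read_dataset",
    "write_dataset",
    "normalize",
    "denormalize",
    "apply_mcar_mask",
    "simulate",
]


@dataclass
class TimeSeriesDataset:
    """Multivariate time series with explicit missingness.

    Parameters
    ----------
    values : ndarray of shape (n_samples, K, L)
        Data matrix per record; entries with ``mask == 0`` hold NaN.
    mask : ndarray of shape (n_samples, K, L)
        1 where the entry is observed, 0 where it is missing.
    timestamps : ndarray of shape (n_samples, L)
        Strictly increasing within each record; arbitrary time units.
    feature_names : list of str, length K
    """

    values: np.ndarray
    mask: np.ndarray
    timestamps: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D (n, K, L), got {self.values.shape}")
        if self.mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        self.mask = (self.mask != 0).astype(np.uint8)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.shape != (self.n_samples, self.L):
            raise ValueError(
                f"timestamps shape {self.timestamps.shape} != {(self.n_samples, self.L)}"
            )
        if self.n_samples and self.L > 1:
            if not np.all(np.diff(self.timestamps, axis=1) > 0):
                raise ValueError("timestamps must be strictly increasing per sample")
        if not self.feature_names:
            self.feature_names = [f"f{k}" for k in range(self.K)]
        if len(self.feature_names) != self.K:
            raise ValueError("feature_names length must equal K")
        # missing entries always carry the NaN sentinel
        self.values = np.where(self.mask == 1, self.values, np.nan)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]

    @property
    def L(self) -> int:
        return self.values.shape[2]

    def copy(self) -> "TimeSeriesDataset":
        return TimeSeriesDataset(
            self.values.copy(),
            self.mask.copy(),
            self.timestamps.copy(),
            list(self.feature_names),
        )


@dataclass
class NormalizationStats:
    """Per-feature center/scale computed from observed entries only."""

    center: np.ndarray  # (K,)
    scale: np.ndarray  # (K,), strictly positive
    constant: np.ndarray  # (K,) bool flags for constant features

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        self.constant = np.asarray(self.constant, dtype=bool)
        if not np.all(self.scale > 0):
            raise ValueError("scale must be strictly positive")


@dataclass
class MaskingProtocol:
    """Repeated MCAR masking protocol for benchmarking."""

    rates: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    mechanism: str = "MCAR"
    n_repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism != "MCAR":
            raise ValueError("only MCAR masking is supported")
        for r in self.rates:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class SyntheticConfig:
    """Generator settings for surrogate multivariate time series.

    Each feature trace is a smooth low-frequency sinusoidal trend plus a
    high-frequency oscillation plus additive Gaussian noise; the noise shares a
    per-time-point latent factor across features so inter-feature correlation
    is tunable via ``cross_feature_corr``.  Frequencies are in cycles per
    record length.  Trend phases are drawn per (record, feature) so records
    differ; the high-frequency phase is drawn once per record and shared
    across features (a coherent fast process driving all features, as in
    co-regulated gene programs), which keeps the high-frequency band
    collectively identifiable from sparse observations.
    """

    n_samples: int = 100
    K: int = 8
    L: int = 48
    trend_freqs: np.ndarray | None = None  # default: 0.5 .. 2 cycles
    trend_amps: np.ndarray | None = None  # default: 1.0
    hf_freqs: np.ndarray | None = None  # default: 8 .. 14 cycles
    hf_amps: np.ndarray | None = None  # default: 0.4
    cross_feature_corr: float = 0.3
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.K, self.L) < 1:
            raise ValueError("n_samples, K, L must be positive")
        if not 0.0 <= self.cross_feature_corr < 1.0:
            raise ValueError("cross_feature_corr must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        K = self.K
        if self.trend_freqs is None:
            self.trend_freqs = np.linspace(0.5, 2.0, K)
        if self.trend_amps is None:
            self.trend_amps = np.full(K, 1.0)
        if self.hf_freqs is None:
            self.hf_freqs = np.linspace(8.0, 14.0, K)
        if self.hf_amps is None:
            self.hf_amps = np.full(K, 0.4)
        for name in ("trend_freqs", "trend_amps", "hf_freqs", "hf_amps"):
            arr = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (K,))
            setattr(self, name, arr.copy())
        if not np.all(self.hf_freqs > self.trend_freqs):
            raise ValueError("hf_freqs must be strictly greater than trend_freqs")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ["sample", "feature", "time", "value"]


def _fmt(v) -> str:
    """Shortest round-trippable decimal form of a float."""
    return format(float(v), ".17g")


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_dataset(
    path: str | Path,
    layout: str = "long",
    sentinel: str = "",
    mask_path: str | Path | None = None,
    zeros_as_missing: bool = False,
) -> TimeSeriesDataset:
    """Read a dataset from delimited text.

    ``wide`` layout: one record per file; first column feature names, remaining
    column headers the timestamps, one row per feature.  ``long`` layout:
    columns (sample, feature, time, value), any number of records.  Missing
    entries are empty fields, ``sentinel``, or "NA"; alternatively a sidecar
    ``mask_path`` file of identical layout holds explicit 0/1 flags.
    ``zeros_as_missing`` additionally treats exact zeros as missing (scRNA-seq
    dropout convention).
    """
    path = Path(path)
    if layout not in {"wide", "long"}:
        raise ValueError(f"unknown layout {layout!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    missing_tokens = {"", "NA", sentinel}
    delim = _delimiter_for(path)

    if layout == "wide":
        values, mask, names, times = _read_wide(path, delim, missing_tokens)
        values, mask = values[None], mask[None]
        timestamps = times[None]
    else:
        values, mask, names, timestamps = _read_long(path, delim, missing_tokens)

    if mask_path is not None:
        side = read_dataset(mask_path, layout=layout)
        if side.values.shape != values.shape:
            raise ValueError("mask sidecar shape does not match data")
        mask = mask & (np.nan_to_num(side.values) != 0).astype(np.uint8)
    if zeros_as_missing:
        mask = mask & ~((np.nan_to_num(values) == 0) & (mask == 1))
    return TimeSeriesDataset(values, mask, timestamps, names)


def _parse_cell(tok: str, missing_tokens: set[str], where: str) -> float:
    tok = tok.strip()
    if tok in missing_tokens:
        return np.nan
    try:
        return float(tok)
    except ValueError as exc:
        raise ValueError(f"malformed value {tok!r} at {where}") from exc


def _read_wide(path: Path, delim: str, missing: set[str]):
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    times = np.array([_parse_cell(t, set(), f"{path}:1") for t in header[1:]])
    names, data = [], []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(f"{path}: line {i} has {len(row)} fields, expected {len(header)}")
        names.append(row[0])
        data.append([_parse_cell(tok, missing, f"{path}:{i}") for tok in row[1:]])
    values = np.asarray(data, dtype=float)
    mask = (~np.isnan(values)).astype(np.uint8)
    return values, mask, names, times


def _read_long(path: Path, delim: str, missing: set[str]):
    df = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    if list(df.columns[:4]) != _LONG_COLUMNS:
        raise ValueError(f"{path}: long layout requires columns {_LONG_COLUMNS}")
    if len(df) == 0:
        return (np.empty((0, 0, 0)), np.empty((0, 0, 0), dtype=np.uint8), [], np.empty((0, 0)))
    samples = list(dict.fromkeys(df["sample"]))
    names = list(dict.fromkeys(df["feature"]))
    times_by_sample = {}
    for s in samples:
        sub = df[df["sample"] == s]
        t = np.array(sorted({float(x) for x in sub["time"]}))
        times_by_sample[s] = t
    L = len(times_by_sample[samples[0]])
    for s, t in times_by_sample.items():
        if len(t) != L:
            raise ValueError(f"{path}: sample {s!r} has {len(t)} time points, expected {L}")
    K = len(names)
    values = np.full((len(samples), K, L), np.nan)
    mask = np.zeros((len(samples), K, L), dtype=np.uint8)
    timestamps = np.stack([times_by_sample[s] for s in samples])
    srow = {s: i for i, s in enumerate(samples)}
    frow = {f: k for k, f in enumerate(names)}
    tcol = {s: {t: j for j, t in enumerate(times_by_sample[s])} for s in samples}
    for idx, rec in enumerate(df.itertuples(index=False), start=2):
        i, k = srow[rec.sample], frow[rec.feature]
        j = tcol[rec.sample][float(rec.time)]
        v = _parse_cell(rec.value, missing, f"{path}:{idx}")
        values[i, k, j] = v
        mask[i, k, j] = 0 if np.isnan(v) else 1
    return values, mask, names, timestamps


def write_dataset(
    dataset: TimeSeriesDataset, path: str | Path, layout: str = "long", sentinel: str = ""
) -> None:
    """Write a dataset so that :func:`read_dataset` reproduces it exactly.

    Missing entries are written as ``sentinel`` (empty field by default).
    Wide layout only supports single-record datasets.
    """
    path = Path(path)
    delim = _delimiter_for(path)
    if layout == "wide":
        if dataset.n_samples > 1:
            raise ValueError("wide layout holds a single record per file")
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter=delim)
            times = dataset.timestamps[0] if dataset.n_samples else []
            w.writerow(["feature"] + [_fmt(t) for t in times])
            if dataset.n_samples:
                for k, name in enumerate(dataset.feature_names):
                    row = [name] + [
                        _fmt(v) if m else sentinel
                        for v, m in zip(dataset.values[0, k], dataset.mask[0, k])
                    ]
                    w.writerow(row)
    elif layout == "long":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter=delim)
            w.writerow(_LONG_COLUMNS)
            for i in range(dataset.n_samples):
                for k, name in enumerate(dataset.feature_names):
                    for j in range(dataset.L):
                        v = dataset.values[i, k, j]
                        tok = sentinel if dataset.mask[i, k, j] == 0 else _fmt(v)
                        w.writerow([i, name, _fmt(dataset.timestamps[i, j]), tok])
    else:
        raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize(
    dataset: TimeSeriesDataset, stats: NormalizationStats | None = None
) -> tuple[TimeSeriesDataset, NormalizationStats]:
    """Center/scale each feature using observed entries only.

    Statistics are pooled over all records (global per-feature), using the
    sample standard deviation (denominator ``n - 1``).  Constant features (or
    features with a single observed value) are flagged and given scale 1, so
    their observed entries map to zero.  Pass precomputed ``stats`` to apply a
    training-set normalization to held-out data without leakage.
    """
    if stats is None:
        K = dataset.K
        center = np.zeros(K)
        scale = np.ones(K)
        constant = np.zeros(K, dtype=bool)
        dead = []
        for k in range(K):
            obs = dataset.values[:, k, :][dataset.mask[:, k, :] == 1]
            if obs.size == 0:
                dead.append(dataset.feature_names[k])
                continue
            center[k] = obs.mean()
            sd = obs.std(ddof=1) if obs.size > 1 else 0.0
            if sd > 0:
                scale[k] = sd
            else:
                constant[k] = True
        if dead:
            raise ValueError(f"features with zero observed entries: {dead}")
        stats = NormalizationStats(center, scale, constant)
    if len(stats.center) != dataset.K:
        raise ValueError("stats feature count does not match dataset")
    out = dataset.copy()
    out.values = (out.values - stats.center[None, :, None]) / stats.scale[None, :, None]
    out.values = np.where(out.mask == 1, out.values, np.nan)
    return out, stats


def denormalize(dataset: TimeSeriesDataset, stats: NormalizationStats) -> TimeSeriesDataset:
    """Exact inverse of :func:`normalize` on all finite entries."""
    if len(stats.center) != dataset.K:
        raise ValueError("stats feature count does not match dataset")
    out = dataset.copy()
    out.values = out.values * stats.scale[None, :, None] + stats.center[None, :, None]
    out.values = np.where(out.mask == 1, out.values, np.nan)
    return out


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------


def apply_mcar_mask(
    dataset: TimeSeriesDataset, rate: float, rng: np.random.Generator
) -> tuple[TimeSeriesDataset, np.ndarray]:
    """Hide each currently observed entry independently with probability ``rate``.

    Returns the masked dataset and an evaluation mask marking exactly the
    newly hidden entries (ground truth stays in the input dataset, which is
    not modified).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate {rate} outside [0, 1]")
    draw = rng.random(dataset.values.shape)
    eval_mask = ((dataset.mask == 1) & (draw < rate)).astype(np.uint8)
    out = dataset.copy()
    out.mask = (out.mask & ~eval_mask).astype(np.uint8)
    out.values = np.where(out.mask == 1, out.values, np.nan)
    return out, eval_mask


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------


def simulate(config: SyntheticConfig) -> TimeSeriesDataset:
    """Generate a fully observed surrogate dataset.

    Trace for record ``i``, feature ``k``::

        x[i,k,l] = A_k sin(2 pi f_k l / L + phase) + a_k sin(2 pi F_k l / L + phase')
                   + noise_sd * (sqrt(c) g[i,l] + sqrt(1-c) e[i,k,l])

    with ``g`` a shared standard-normal latent per time point (cross-feature
    correlation ``c``) and independent ``e``.  Deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    n, K, L = config.n_samples, config.K, config.L
    l = np.arange(L)
    phase_lo = rng.uniform(0, 2 * np.pi, size=(n, K))
    phase_hi = np.broadcast_to(rng.uniform(0, 2 * np.pi, size=(n, 1)), (n, K)).copy()
    c = config.cross_feature_corr
    shared = rng.standard_normal((n, 1, L))
    own = rng.standard_normal((n, K, L))
    noise = config.noise_sd * (np.sqrt(c) * shared + np.sqrt(1.0 - c) * own)
    arg_lo = 2 * np.pi * config.trend_freqs[None, :, None] * l[None, None, :] / L
    arg_hi = 2 * np.pi * config.hf_freqs[None, :, None] * l[None, None, :] / L
    values = (
        config.trend_amps[None, :, None] * np.sin(arg_lo + phase_lo[:, :, None])
        + config.hf_amps[None, :, None] * np.sin(arg_hi + phase_hi[:, :, None])
        + noise
    )
    mask = np.ones_like(values, dtype=np.uint8)
    timestamps = np.broadcast_to(l.astype(float), (n, L)).copy()
    return TimeSeriesDataset(values, mask, timestamps)
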