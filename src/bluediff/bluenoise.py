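"""Blue-noise generation: simulated annealing of binary masks against an ideal
radial spectrum, covariance estimation over a mask ensemble, and Cholesky
sampling of correlated Gaussian blue-noise fields.

Blue noise concentrates spectral energy at high spatial frequencies.  Rather
than running the classic void-and-cluster ranking, binary 50%-density masks on
the ``L x K`` (time x feature) grid are annealed with a Metropolis rule toward
a high-pass radial target spectrum; the ensemble covariance of many such masks
is then shrunk toward a scaled identity, factorized (``C' = L L^T``), and used
to color standard-normal draws (``eps_blue = L z``).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnnealingConfig",
    "SpectrumTarget",
    "BinaryMask",
    "BlueNoiseSampler",
    "compute_radial_bins",
    "ideal_blue_spectrum",
    "radial_spectrum",
    "spectrum_energy",
    "anneal_mask",
    "build_sampler",
    "sample_blue",
    "make_blue_noise_sampler",
    "low_band_magnitude",
]


@dataclass
class AnnealingConfig:
    """Metropolis simulated-annealing settings for one mask.

    ``r`` is the geometric cooling factor applied once per sweep (default
    0.995, gradual cooling); the temperature is reheated by the fixed factor
    1.2 whenever the trailing acceptance rate drops below ``acceptance_floor``.
    A run stops when the temperature falls below ``T_final``, the spectral
    energy falls below ``energy_threshold``, or ``S`` sweeps elapse.
    """

    T_init: float = 1.0
    T_final: float = 1e-4
    r: float = 0.995
    S: int = 5000
    energy_threshold: float = 1e-4
    reheat_factor: float = 1.2
    acceptance_window: int = 100
    acceptance_floor: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.r < 1.0:
            raise ValueError("cooling factor r must lie in (0, 1)")
        if not self.T_final < self.T_init:
            raise ValueError("T_final must be below T_init")
        if self.S < 1 or self.acceptance_window < 1:
            raise ValueError("S and acceptance_window must be positive")


@dataclass
class SpectrumTarget:
    """Radial binning of the 2-D discrete-frequency grid, plus the ideal
    per-bin magnitude ``s_ideal`` once set.

    ``bin_assignment`` labels every frequency cell of an ``L x K`` grid with a
    radial bin index; the DC cell carries the reserved label ``-1`` and is
    excluded from all energies.
    """

    shape: tuple[int, int]
    n_bins: int
    bin_assignment: np.ndarray  # (L, K) int, -1 for the DC cell
    bin_radius: np.ndarray  # (n_bins,) representative (center) radius
    s_ideal: np.ndarray | None = None
    counts: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.bincount(
                self.bin_assignment[self.bin_assignment >= 0].ravel(),
                minlength=self.n_bins,
            )


@dataclass
class BinaryMask:
    """A 50%-density binary grid and its spectral energy."""

    grid: np.ndarray  # (L, K) of {0, 1}
    energy: float
    energy_initial: float | None = None

    @property
    def density(self) -> float:
        return float(self.grid.mean())


@dataclass
class BlueNoiseSampler:
    """Cholesky factor of a (regularized) mask-ensemble covariance.

    ``factor`` is lower-triangular over the row-major flattening of the
    ``(L, K)`` grid (time axis first).  With ``standardized`` the rows are
    rescaled so every output coordinate has unit marginal variance.
    """

    shape: tuple[int, int]
    factor: np.ndarray  # (L*K, L*K) lower-triangular
    shrinkage: float
    standardized: bool
    n_masks: int
    covariance_raw: np.ndarray = field(default=None, repr=False)  # C' before standardization

    @property
    def covariance(self) -> np.ndarray:
        """Covariance the factor actually reproduces (factor @ factor.T)."""
        return self.factor @ self.factor.T


# ---------------------------------------------------------------------------
# spectrum machinery
# ---------------------------------------------------------------------------


def compute_radial_bins(L: int, K: int, n_bins: int) -> SpectrumTarget:
    """Partition the 2-D frequency cells of an ``L x K`` grid into radial bins.

    Signed integer frequencies give each cell a Euclidean radius; non-DC cells
    are assigned to ``n_bins`` equal-width radial intervals spanning the
    smallest to the largest non-DC radius.  The DC cell gets label -1.
    """
    if L * K < 4:
        raise ValueError("grid must have at least 4 cells")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    u = np.fft.fftfreq(L) * L  # signed integer frequencies along time axis
    v = np.fft.fftfreq(K) * K
    radius = np.sqrt(u[:, None] ** 2 + v[None, :] ** 2)
    nonzero = np.sort(np.unique(radius[radius > 0]))
    if n_bins > len(nonzero):
        raise ValueError(f"n_bins {n_bins} exceeds {len(nonzero)} distinct non-DC radii")
    rmin, rmax = nonzero[0], nonzero[-1]
    width = (rmax - rmin) / n_bins if rmax > rmin else 1.0
    idx = np.floor((radius - rmin) / width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    idx[radius == 0] = -1
    centers = rmin + (np.arange(n_bins) + 0.5) * width
    return SpectrumTarget(shape=(L, K), n_bins=n_bins, bin_assignment=idx, bin_radius=centers)


def _mean_white_spectrum(target: SpectrumTarget, n_masks: int, rng: np.random.Generator):
    """Monte-Carlo mean radial magnitude of random 50%-density binary masks."""
    L, K = target.shape
    n_ones = (L * K) // 2
    acc = np.zeros(target.n_bins)
    for _ in range(n_masks):
        flat = np.zeros(L * K)
        flat[rng.permutation(L * K)[:n_ones]] = 1.0
        acc += radial_spectrum(flat.reshape(L, K), target)
    return acc / n_masks


def ideal_blue_spectrum(
    target: SpectrumTarget,
    cutoff_fraction: float = 0.3,
    n_reference_masks: int = 128,
    reference_seed: int = 12345,
) -> SpectrumTarget:
    """Attach a high-pass ramp ``s_ideal`` to a radial-bin skeleton.

    The ideal spectrum is zero below ``cutoff_fraction`` of the maximum radius
    and rises linearly with bin radius above it; it is rescaled so its mean
    over non-DC bins matches the Monte-Carlo mean radial magnitude of random
    50%-density masks of the same shape (so annealing redistributes rather
    than shrinks spectral mass).
    """
    if not 0.0 <= cutoff_fraction < 1.0:
        raise ValueError("cutoff_fraction must lie in [0, 1)")
    rmax = target.bin_radius[-1]
    ramp = np.maximum(0.0, target.bin_radius - cutoff_fraction * rmax)
    ref = _mean_white_spectrum(
        target, n_reference_masks, np.random.default_rng(reference_seed)
    )
    ramp *= ref.mean() / ramp.mean()
    return SpectrumTarget(
        shape=target.shape,
        n_bins=target.n_bins,
        bin_assignment=target.bin_assignment,
        bin_radius=target.bin_radius,
        s_ideal=ramp,
        counts=target.counts,
    )


def radial_spectrum(grid: np.ndarray, target: SpectrumTarget) -> np.ndarray:
    """Per-bin mean 2-D Fourier magnitude of the mean-centered grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.shape != target.shape:
        raise ValueError(f"grid shape {grid.shape} != target shape {target.shape}")
    mag = np.abs(np.fft.fft2(grid - grid.mean()))
    labels = target.bin_assignment
    sums = np.bincount(labels[labels >= 0].ravel(), weights=mag[labels >= 0].ravel(),
                       minlength=target.n_bins)
    return sums / target.counts


def spectrum_energy(s: np.ndarray, s_ideal: np.ndarray) -> float:
    """Mean squared per-bin deviation from the ideal spectrum."""
    s = np.asarray(s, dtype=float)
    s_ideal = np.asarray(s_ideal, dtype=float)
    if s.shape != s_ideal.shape:
        raise ValueError("spectrum length mismatch")
    return float(np.mean((s - s_ideal) ** 2))


# ---------------------------------------------------------------------------
# annealing
# ---------------------------------------------------------------------------


def anneal_mask(
    config: AnnealingConfig, target: SpectrumTarget, rng: np.random.Generator
) -> BinaryMask:
    """Anneal one 50%-density binary mask toward the ideal radial spectrum.

    Each sweep proposes a single 1<->0 swap (density is conserved exactly),
    accepts with the Metropolis rule, cools geometrically, and reheats when
    the trailing acceptance rate collapses.
    """
    if target.s_ideal is None:
        raise ValueError("target has no s_ideal; call ideal_blue_spectrum first")
    L, K = target.shape
    n = L * K
    n_ones = n // 2
    if n_ones == 0 or n_ones == n:
        raise ValueError("grid too small to hold both ones and zeros")
    flat = np.zeros(n)
    perm = rng.permutation(n)
    flat[perm[:n_ones]] = 1.0
    ones = list(perm[:n_ones])
    zeros = list(perm[n_ones:])
    grid = flat.reshape(L, K)

    energy = spectrum_energy(radial_spectrum(grid, target), target.s_ideal)
    energy_initial = energy
    T = config.T_init
    recent: deque[bool] = deque(maxlen=config.acceptance_window)

    for _ in range(config.S):
        i = rng.integers(len(ones))
        j = rng.integers(len(zeros))
        a, b = ones[i], zeros[j]
        grid.flat[a], grid.flat[b] = 0.0, 1.0
        e_new = spectrum_energy(radial_spectrum(grid, target), target.s_ideal)
        delta = e_new - energy
        if delta < 0 or rng.random() < np.exp(-delta / T):
            ones[i], zeros[j] = b, a
            energy = e_new
            recent.append(True)
        else:
            grid.flat[a], grid.flat[b] = 1.0, 0.0  # revert
            recent.append(False)
        T *= config.r
        if (
            len(recent) == config.acceptance_window
            and np.mean(recent) < config.acceptance_floor
        ):
            T *= config.reheat_factor
        if T < config.T_final or energy < config.energy_threshold:
            break
    return BinaryMask(grid=grid.astype(np.uint8), energy=energy, energy_initial=energy_initial)


# ---------------------------------------------------------------------------
# covariance + sampling
# ---------------------------------------------------------------------------


def build_sampler(
    masks: list[BinaryMask], shrinkage: float = 0.05, standardize: bool = True
) -> BlueNoiseSampler:
    """Estimate the mask-ensemble covariance and factorize it.

    Masks are flattened row-major with the time axis first (index
    ``l * K + k``), centered by the column mean, and the sample covariance
    ``C = Mc^T Mc / (N - 1)`` is shrunk toward a scaled identity,
    ``C' = (1 - lambda) C + lambda * mean(diag C) * I``, before Cholesky
    factorization.  Shrinkage is required in practice: with N well below
    ``L*K`` the raw covariance is rank-deficient.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 masks")
    shape = tuple(masks[0].grid.shape)
    for m in masks:
        if tuple(m.grid.shape) != shape:
            raise ValueError("all masks must share one shape")
    M = np.stack([m.grid.astype(float).ravel(order="C") for m in masks])
    Mc = M - M.mean(axis=0, keepdims=True)
    C = Mc.T @ Mc / (len(masks) - 1)
    diag_mean = float(np.trace(C)) / C.shape[0]
    # degenerate ensembles (zero covariance) still get a valid isotropic factor
    scale = diag_mean if diag_mean > 0 else 1.0
    C_reg = (1.0 - shrinkage) * C + shrinkage * scale * np.eye(C.shape[0])
    try:
        factor = np.linalg.cholesky(C_reg)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance factorization failed at shrinkage={shrinkage}; "
            "increase the shrinkage parameter"
        ) from exc
    if standardize:
        row_var = np.sum(factor**2, axis=1)
        scale = np.where(row_var > 0, np.sqrt(row_var), 1.0)
        factor = factor / scale[:, None]
    return BlueNoiseSampler(
        shape=shape,
        factor=factor,
        shrinkage=shrinkage,
        standardized=standardize,
        n_masks=len(masks),
        covariance_raw=C_reg,
    )


def sample_blue(sampler: BlueNoiseSampler, z: np.ndarray) -> np.ndarray:
    """Color a standard-normal vector: returns ``factor @ z`` as an (L, K) field.

    ``z`` may be a fresh draw (inference) or the flattened white-noise field
    already used elsewhere (training reuses the same draw).
    """
    z = np.asarray(z, dtype=float).ravel()
    n = sampler.shape[0] * sampler.shape[1]
    if z.size != n:
        raise ValueError(f"z has length {z.size}, expected {n}")
    return (sampler.factor @ z).reshape(sampler.shape)


def make_blue_noise_sampler(
    L: int,
    K: int,
    n_masks: int = 64,
    n_bins: int | None = None,
    cutoff_fraction: float = 0.3,
    shrinkage: float = 0.05,
    standardize: bool = True,
    annealing: AnnealingConfig | None = None,
    rng: np.random.Generator | None = None,
) -> BlueNoiseSampler:
    """Anneal ``n_masks`` blue-noise masks and build the Cholesky sampler."""
    if rng is None:
        rng = np.random.default_rng(annealing.seed if annealing else 0)
    if annealing is None:
        annealing = AnnealingConfig()
    if n_bins is None:
        n_bins = min(L, K)
    target = ideal_blue_spectrum(compute_radial_bins(L, K, n_bins), cutoff_fraction)
    masks = [anneal_mask(annealing, target, rng) for _ in range(n_masks)]
    return build_sampler(masks, shrinkage=shrinkage, standardize=standardize)


def low_band_magnitude(
    grid: np.ndarray, target: SpectrumTarget, fraction: float = 0.25
) -> float:
    """Mean radial magnitude over the lowest ``fraction`` of radial bins."""
    n_low = max(1, int(np.floor(target.n_bins * fraction)))
    return float(radial_spectrum(grid, target)[:n_low].mean())
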