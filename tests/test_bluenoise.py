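"""Radial binning, spectral energy, annealing and Cholesky sampling."""

import numpy as np
import pytest

from bluediff.bluenoise import (
    AnnealingConfig,
    BinaryMask,
    anneal_mask,
    build_sampler,
    compute_radial_bins,
    ideal_blue_spectrum,
    radial_spectrum,
    sample_blue,
    spectrum_energy,
)


@pytest.fixture(scope="module")
def target_8x8():
    return ideal_blue_spectrum(compute_radial_bins(8, 8, 6), cutoff_fraction=0.3)


class TestRadialBins:
    def test_2x2_grid_enumeration(self):
        t = compute_radial_bins(2, 2, 2)
        # radii {0, 1, 1, sqrt2}: DC reserved, radius-1 cells bin 0, corner bin 1
        assert t.bin_assignment[0, 0] == -1
        assert t.bin_assignment[0, 1] == 0
        assert t.bin_assignment[1, 0] == 0
        assert t.bin_assignment[1, 1] == 1

    def test_square_grid_transpose_symmetry(self):
        t = compute_radial_bins(8, 8, 5)
        np.testing.assert_array_equal(t.bin_assignment, t.bin_assignment.T)

    def test_every_non_dc_cell_assigned_once(self):
        t = compute_radial_bins(6, 10, 4)
        assert (t.bin_assignment == -1).sum() == 1
        assert ((t.bin_assignment >= 0) | (t.bin_assignment == -1)).all()
        assert t.counts.sum() == 59

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            compute_radial_bins(2, 2, 5)


class TestIdealSpectrum:
    def test_zero_cutoff_strictly_increasing(self):
        t = ideal_blue_spectrum(compute_radial_bins(8, 8, 6), cutoff_fraction=0.0)
        assert np.all(np.diff(t.s_ideal) > 0)
        assert np.all(t.s_ideal > 0)

    def test_high_cutoff_zeroes_low_bins(self):
        t = ideal_blue_spectrum(compute_radial_bins(16, 16, 10), cutoff_fraction=0.9)
        n_zero = int(np.sum(t.s_ideal == 0))
        assert n_zero >= 8

    def test_rescaled_to_white_mask_mean_power(self, rng):
        t = ideal_blue_spectrum(compute_radial_bins(8, 8, 6))
        acc = np.zeros(t.n_bins)
        n_mc = 200
        for _ in range(n_mc):
            flat = np.zeros(64)
            flat[rng.permutation(64)[:32]] = 1.0
            acc += radial_spectrum(flat.reshape(8, 8), t)
        ref = acc / n_mc
        assert abs(t.s_ideal.mean() / ref.mean() - 1.0) < 0.02


class TestRadialSpectrum:
    def test_constant_mask_zero_spectrum(self, target_8x8):
        s = radial_spectrum(np.ones((8, 8)), target_8x8)
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_parseval(self, rng, target_8x8):
        g = (rng.random((8, 8)) < 0.5).astype(float)
        centered = g - g.mean()
        total = np.sum(np.abs(np.fft.fft2(centered)) ** 2)
        assert np.isclose(total, g.size * centered.var() * g.size)

    def test_swap_matches_full_recompute(self, rng, target_8x8):
        g = (rng.random((8, 8)) < 0.5).astype(float)
        s0 = radial_spectrum(g, target_8x8)
        g2 = g.copy()
        a = tuple(np.argwhere(g == 1)[0])
        b = tuple(np.argwhere(g == 0)[0])
        g2[a], g2[b] = 0.0, 1.0
        s1 = radial_spectrum(g2, target_8x8)
        # equals an independent direct transform of the swapped mask
        direct = radial_spectrum(g2.copy(), target_8x8)
        np.testing.assert_allclose(s1, direct)
        assert np.any(s1 != s0)

    def test_shape_mismatch(self, target_8x8):
        with pytest.raises(ValueError, match="shape"):
            radial_spectrum(np.ones((4, 4)), target_8x8)


class TestSpectrumEnergy:
    def test_equal_gives_zero_and_offset_gives_square(self, rng):
        s = rng.random(7)
        assert spectrum_energy(s, s) == 0.0
        assert np.isclose(spectrum_energy(s + 0.3, s), 0.09)

    def test_matches_direct_mse(self, rng):
        a, b = rng.random(11), rng.random(11)
        assert np.isclose(spectrum_energy(a, b), np.mean((a - b) ** 2))


class TestAnnealing:
    def test_density_conserved_and_energy_reported(self, target_8x8, rng):
        cfg = AnnealingConfig(S=300, seed=0)
        m = anneal_mask(cfg, target_8x8, rng)
        assert m.grid.sum() == 32
        assert m.energy >= 0 and m.energy_initial is not None

    def test_energy_decreases_across_seeds(self, target_8x8):
        wins = 0
        n = 10
        for s in range(n):
            m = anneal_mask(AnnealingConfig(S=800), target_8x8,
                            np.random.default_rng(s))
            wins += m.energy < m.energy_initial
        assert wins >= 9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AnnealingConfig(r=1.5)
        with pytest.raises(ValueError):
            AnnealingConfig(T_init=1e-5, T_final=1.0)


class TestSampler:
    def test_two_antithetic_masks_covariance(self):
        # rows (0,1) and (1,0): centered covariance [[.5,-.5],[-.5,.5]]
        m1 = BinaryMask(grid=np.array([[0], [1]], dtype=np.uint8), energy=0.0)
        m2 = BinaryMask(grid=np.array([[1], [0]], dtype=np.uint8), energy=0.0)
        s = build_sampler([m1, m2], shrinkage=0.0, standardize=False)
        np.testing.assert_allclose(s.covariance_raw,
                                   [[0.5, -0.5], [-0.5, 0.5]], atol=1e-12)

    def test_known_cholesky_factor(self):
        C = np.array([[4.0, 2.0], [2.0, 3.0]])
        L = np.linalg.cholesky(C)
        np.testing.assert_allclose(L, [[2, 0], [1, np.sqrt(2)]])
        np.testing.assert_allclose(L @ L.T, C)

    def test_identical_masks_need_shrinkage(self):
        g = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        masks = [BinaryMask(grid=g.copy(), energy=0.0) for _ in range(2)]
        with pytest.raises(np.linalg.LinAlgError):
            build_sampler(masks, shrinkage=0.0, standardize=False)
        s = build_sampler(masks, shrinkage=0.1, standardize=False)
        # zero ensemble covariance: factor is a scaled identity
        assert np.allclose(s.factor, s.factor[0, 0] * np.eye(4))

    def test_factor_reproduces_regularized_covariance(self, rng):
        masks = [
            BinaryMask(grid=(rng.random((6, 4)) < 0.5).astype(np.uint8), energy=0.0)
            for _ in range(12)
        ]
        s = build_sampler(masks, shrinkage=0.05, standardize=False)
        err = np.linalg.norm(s.covariance - s.covariance_raw) / np.linalg.norm(
            s.covariance_raw
        )
        assert err < 1e-8
        assert np.allclose(s.factor, np.tril(s.factor))

    def test_sample_blue_identity_and_zero(self, rng):
        masks = [
            BinaryMask(grid=(rng.random((3, 3)) < 0.5).astype(np.uint8), energy=0.0)
            for _ in range(8)
        ]
        s = build_sampler(masks, shrinkage=0.05, standardize=False)
        assert sample_blue(s, np.zeros(9)).shape == (3, 3)
        np.testing.assert_array_equal(sample_blue(s, np.zeros(9)), 0.0)
        s_id = s
        s_id.factor = np.eye(9)
        z = rng.standard_normal(9)
        np.testing.assert_array_equal(sample_blue(s_id, z), z.reshape(3, 3))
        with pytest.raises(ValueError, match="length"):
            sample_blue(s, np.zeros(5))
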