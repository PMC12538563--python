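"""Dataset container, I/O round trips, normalization and MCAR masking."""

import numpy as np
import pytest
from scipy import stats as sps

from bluediff.data import (
    NormalizationStats,
    SyntheticConfig,
    TimeSeriesDataset,
    apply_mcar_mask,
    denormalize,
    normalize,
    read_dataset,
    simulate,
    write_dataset,
)


class TestDatasetInvariants:
    def test_mask_shape_must_match(self, rng):
        with pytest.raises(ValueError, match="mask shape"):
            TimeSeriesDataset(rng.random((2, 3, 4)), np.ones((2, 3, 5)),
                              np.broadcast_to(np.arange(4.0), (2, 4)).copy())

    def test_timestamps_must_increase(self, rng):
        ts = np.tile(np.array([0.0, 2.0, 1.0, 3.0]), (2, 1))
        with pytest.raises(ValueError, match="increasing"):
            TimeSeriesDataset(rng.random((2, 3, 4)), np.ones((2, 3, 4)), ts)

    def test_missing_entries_hold_nan(self, ragged_dataset):
        assert np.isnan(ragged_dataset.values[ragged_dataset.mask == 0]).all()
        assert np.isfinite(ragged_dataset.values[ragged_dataset.mask == 1]).all()


class TestFileIO:
    def test_wide_missing_cell_count(self, tmp_path):
        p = tmp_path / "wide.csv"
        p.write_text("feature,0,1,2\ng1,1.0,,3.0\ng2,4.0,5.0,6.0\n")
        ds = read_dataset(p, layout="wide")
        assert ds.K == 2 and ds.L == 3
        assert ds.mask.sum() == 5

    def test_long_no_missing_tokens_gives_full_mask(self, tmp_path):
        p = tmp_path / "long.csv"
        rows = ["sample,feature,time,value"]
        for s in range(2):
            for f in ("a", "b"):
                for t in range(3):
                    rows.append(f"{s},{f},{t},{s + t * 0.5}")
        p.write_text("\n".join(rows) + "\n")
        ds = read_dataset(p, layout="long")
        assert ds.mask.all()
        assert ds.values.shape == (2, 2, 3)

    @pytest.mark.parametrize("layout", ["wide", "long"])
    def test_round_trip_exact(self, tmp_path, ragged_dataset, layout):
        ds = ragged_dataset
        if layout == "wide":
            ds = TimeSeriesDataset(ds.values[:1], ds.mask[:1], ds.timestamps[:1],
                                   ds.feature_names)
        p = tmp_path / "rt.csv"
        write_dataset(ds, p, layout=layout)
        back = read_dataset(p, layout=layout)
        np.testing.assert_array_equal(back.mask, ds.mask)
        np.testing.assert_array_equal(
            back.values[back.mask == 1], ds.values[ds.mask == 1]
        )
        np.testing.assert_allclose(back.timestamps, ds.timestamps)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("feature,0,1\ng1,1.0,oops\n")
        with pytest.raises(ValueError, match="malformed"):
            read_dataset(p, layout="wide")

    def test_inconsistent_length_raises(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("feature,0,1,2\ng1,1.0,2.0\n")
        with pytest.raises(ValueError, match="fields"):
            read_dataset(p, layout="wide")

    def test_zeros_as_missing_option(self, tmp_path):
        p = tmp_path / "z.csv"
        p.write_text("feature,0,1\ng1,0.0,2.0\n")
        assert read_dataset(p, layout="wide").mask.sum() == 2
        assert read_dataset(p, layout="wide", zeros_as_missing=True).mask.sum() == 1

    def test_empty_dataset_writes_header_only(self, tmp_path):
        ds = TimeSeriesDataset(np.empty((0, 0, 0)), np.empty((0, 0, 0)),
                               np.empty((0, 0)), [])
        p = tmp_path / "empty.csv"
        write_dataset(ds, p, layout="long")
        assert p.read_text().strip() == "sample,feature,time,value"


class TestNormalize:
    def test_observed_moments_and_sd_convention(self, ragged_dataset):
        norm, stats = normalize(ragged_dataset)
        for k in range(norm.K):
            obs = norm.values[:, k, :][norm.mask[:, k, :] == 1]
            assert abs(obs.mean()) < 1e-12
            assert abs(obs.std(ddof=1) - 1.0) < 1e-12
        # two-point feature: center is the mean, scale the n-1 sample SD
        vals = np.array([[[2.0, 4.0]]])
        ds = TimeSeriesDataset(vals, np.ones_like(vals), np.arange(2.0)[None])
        _, st = normalize(ds)
        assert st.center[0] == 3.0
        assert np.isclose(st.scale[0], np.sqrt(2.0))

    def test_constant_feature_flagged_zeroed(self):
        vals = np.full((3, 1, 4), 7.0)
        ds = TimeSeriesDataset(vals, np.ones_like(vals),
                               np.broadcast_to(np.arange(4.0), (3, 4)).copy())
        norm, stats = normalize(ds)
        assert stats.constant[0]
        assert stats.scale[0] == 1.0
        assert np.all(norm.values == 0.0)

    def test_fully_missing_feature_raises(self, rng):
        vals = rng.random((2, 2, 3))
        mask = np.ones_like(vals, dtype=np.uint8)
        mask[:, 1, :] = 0
        ds = TimeSeriesDataset(vals, mask, np.broadcast_to(np.arange(3.0), (2, 3)).copy())
        with pytest.raises(ValueError, match="f1"):
            normalize(ds)

    def test_denormalize_round_trip(self, ragged_dataset):
        norm, stats = normalize(ragged_dataset)
        back = denormalize(norm, stats)
        obs = ragged_dataset.mask == 1
        np.testing.assert_allclose(back.values[obs], ragged_dataset.values[obs],
                                   rtol=1e-12, atol=1e-12)

    def test_identity_stats_leave_values(self, ragged_dataset):
        stats = NormalizationStats(np.zeros(3), np.ones(3), np.zeros(3, bool))
        out = denormalize(ragged_dataset, stats)
        obs = ragged_dataset.mask == 1
        np.testing.assert_array_equal(out.values[obs], ragged_dataset.values[obs])

    def test_feature_count_mismatch(self, ragged_dataset):
        stats = NormalizationStats(np.zeros(5), np.ones(5), np.zeros(5, bool))
        with pytest.raises(ValueError, match="feature count"):
            denormalize(ragged_dataset, stats)


class TestMcarMask:
    def test_rate_zero_is_identity(self, small_dataset, rng):
        masked, em = apply_mcar_mask(small_dataset, 0.0, rng)
        assert em.sum() == 0
        np.testing.assert_array_equal(masked.mask, small_dataset.mask)

    def test_rate_one_hides_everything(self, small_dataset, rng):
        masked, em = apply_mcar_mask(small_dataset, 1.0, rng)
        assert em.sum() == small_dataset.mask.sum()
        assert masked.mask.sum() == 0

    def test_counts_conserved_and_no_double_hiding(self, ragged_dataset, rng):
        masked, em = apply_mcar_mask(ragged_dataset, 0.4, rng)
        assert (em & (ragged_dataset.mask == 0)).sum() == 0
        assert masked.mask.sum() + em.sum() == ragged_dataset.mask.sum()

    def test_hidden_count_binomial(self, rng):
        vals = rng.standard_normal((10, 10, 100))
        ds = TimeSeriesDataset(vals, np.ones_like(vals),
                               np.broadcast_to(np.arange(100.0), (10, 100)).copy())
        _, em = apply_mcar_mask(ds, 0.5, rng)
        lo, hi = sps.binom.ppf([0.0005, 0.9995], 10000, 0.5)
        assert lo <= em.sum() <= hi

    def test_rate_out_of_range(self, small_dataset, rng):
        with pytest.raises(ValueError):
            apply_mcar_mask(small_dataset, 1.5, rng)


class TestSimulate:
    def test_noise_free_limit_is_pure_sinusoid(self):
        cfg = SyntheticConfig(n_samples=3, K=2, L=64, noise_sd=0.0,
                              trend_freqs=np.array([2.0, 3.0]),
                              hf_amps=np.zeros(2), seed=3)
        ds = simulate(cfg)
        # spectrum of each trace concentrates at the configured trend frequency
        for i in range(3):
            for k in range(2):
                mag = np.abs(np.fft.rfft(ds.values[i, k]))
                assert np.argmax(mag) == int(cfg.trend_freqs[k])

    def test_seed_determinism(self):
        a = simulate(SyntheticConfig(n_samples=4, K=3, L=16, seed=9))
        b = simulate(SyntheticConfig(n_samples=4, K=3, L=16, seed=9))
        np.testing.assert_array_equal(a.values, b.values)

    def test_zero_corr_noise_uncorrelated(self):
        cfg = SyntheticConfig(n_samples=1, K=2, L=5000, trend_amps=np.zeros(2),
                              hf_amps=np.zeros(2), cross_feature_corr=0.0,
                              noise_sd=1.0, seed=4)
        ds = simulate(cfg)
        r = np.corrcoef(ds.values[0, 0], ds.values[0, 1])[0, 1]
        assert abs(r) < 0.1

    def test_positive_corr_detected(self):
        cfg = SyntheticConfig(n_samples=1, K=2, L=5000, trend_amps=np.zeros(2),
                              hf_amps=np.zeros(2), cross_feature_corr=0.6,
                              noise_sd=1.0, seed=4)
        ds = simulate(cfg)
        r = np.corrcoef(ds.values[0, 0], ds.values[0, 1])[0, 1]
        assert r > 0.4

    def test_band_separation_enforced(self):
        with pytest.raises(ValueError, match="strictly greater"):
            SyntheticConfig(K=2, trend_freqs=np.array([5.0, 5.0]),
                            hf_freqs=np.array([4.0, 6.0]))
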