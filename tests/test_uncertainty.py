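"""Percentile volumes, calibration, and uncertainty sampling."""

import numpy as np
import pytest

from physeg.nn.unet import NetworkConfig, build_network
from physeg.uncertainty import (
    CalibrationModel,
    SampleStack,
    fit_calibration,
    het_sample,
    mc_sample,
    percentile_volumes,
    uncertainty_grid,
    volume_interval,
)


def random_stack(rng, T=6, C=3, shape=(4, 4, 4)):
    raw = rng.random((T, C) + shape)
    return SampleStack(raw / raw.sum(axis=1, keepdims=True))


class TestPercentileVolumes:
    def test_hand_oracle_two_voxels(self):
        # voxel A samples (0.2, 0.6), voxel B samples (0.4, 0.2) for class 0
        s = np.zeros((2, 2, 2, 1, 1))
        s[0, 0, 0] = 0.2
        s[1, 0, 0] = 0.6
        s[0, 0, 1] = 0.4
        s[1, 0, 1] = 0.2
        s[:, 1] = 1.0 - s[:, 0]
        pv = percentile_volumes(SampleStack(s))
        np.testing.assert_allclose(pv.volumes[0], [0.4, 1.0])

    def test_identical_samples_give_constant_volumes(self):
        probs = np.random.default_rng(0).dirichlet(np.ones(3), size=(4, 4, 4))
        probs = np.moveaxis(probs, -1, 0)
        stack = SampleStack(np.stack([probs] * 5))
        pv = percentile_volumes(stack)
        common = probs.sum(axis=(1, 2, 3))
        for t in range(5):
            np.testing.assert_allclose(pv.volumes[:, t], common)

    def test_matches_explicit_per_voxel_sort(self, rng):
        """Sort-then-sum agrees with a brute-force per-voxel loop (the
        sort is exact; sums agree to accumulation precision)."""
        for _ in range(100):
            stack = random_stack(rng)
            pv = percentile_volumes(stack)
            T, C = stack.T, stack.n_classes
            ref = np.zeros((C, T))
            for c in range(C):
                flat = stack.samples[:, c].reshape(T, -1)
                for v in range(flat.shape[1]):
                    ref[c] += np.sort(flat[:, v])
            np.testing.assert_allclose(pv.volumes, ref, rtol=0, atol=1e-10)

    def test_monotone_for_random_stacks(self, rng):
        for _ in range(20):
            pv = percentile_volumes(random_stack(rng, T=9))
            assert np.all(np.diff(pv.volumes, axis=1) >= 0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="T >= 2"):
            SampleStack(np.ones((1, 1, 2, 2, 2)))


class TestSampling:
    def test_het_sample_zero_sigma_identical(self, rng):
        logits = rng.normal(size=(3, 4, 4, 4))
        stack = het_sample(logits, np.zeros_like(logits), T=4, rng=rng)
        for t in range(1, 4):
            np.testing.assert_array_equal(stack.samples[t], stack.samples[0])

    def test_het_sample_large_sigma_dominates_volume_variance(self):
        """With noise on one class only, that class's volume varies most
        (2-voxel toy)."""
        logits = np.zeros((3, 2, 1, 1))
        sigma = np.zeros((3, 2, 1, 1))
        sigma[0] = 3.0
        stack = het_sample(logits, sigma, T=500, rng=np.random.default_rng(0))
        vols = stack.samples.sum(axis=(2, 3, 4))  # (T, C)
        # p1 = p2 = (1 - p0)/2 exactly, so var(V1) = var(V0)/4
        assert vols[:, 0].var() > vols[:, 1].var()
        assert vols[:, 1].var() == pytest.approx(vols[:, 0].var() / 4, rel=0.2)

    def test_het_sample_seeded_reproducible(self):
        logits = np.zeros((2, 2, 2, 2))
        sigma = np.ones_like(logits)
        a = het_sample(logits, sigma, 3, np.random.default_rng(5))
        b = het_sample(logits, sigma, 3, np.random.default_rng(5))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_mc_sample_stack_size_and_reproducibility(self, rng):
        net = build_network(
            NetworkConfig.smoke(base_channels=2, physics_width=3,
                                dropout_rate=0.3)
        )
        img = rng.normal(size=(8, 8, 8))
        pv = np.array([2.0, 0.9, 0.14, 0.41])
        a = mc_sample(net, img, pv, T=5, rng=np.random.default_rng(1))
        assert a.samples.shape == (5, 4, 8, 8, 8)
        b = mc_sample(net, img, pv, T=5, rng=np.random.default_rng(1))
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples[0], a.samples[1])

    def test_mc_sample_zero_dropout_gives_identical_samples(self, rng):
        net = build_network(
            NetworkConfig.smoke(base_channels=2, physics_width=3,
                                dropout_rate=0.0,
                                first_layer_dropout_rate=0.0)
        )
        img = rng.normal(size=(8, 8, 8))
        pv = np.array([2.0, 0.9, 0.14, 0.41])
        stack = mc_sample(net, img, pv, T=3, rng=np.random.default_rng(1))
        for t in range(1, 3):
            np.testing.assert_array_equal(stack.samples[t], stack.samples[0])

    def test_mc_sample_requires_two_samples(self, rng):
        net = build_network(NetworkConfig.smoke(base_channels=2,
                                                physics_width=3))
        with pytest.raises(ValueError, match="T >= 2"):
            mc_sample(net, rng.normal(size=(8, 8, 8)),
                      np.zeros(4), T=1, rng=rng)


def synthetic_percentiles(rng, n_subjects, T=50, bias=0.0, spread=1.0):
    """Percentile volumes around known true volumes: per-subject sampled
    volumes are the truth plus (optionally biased) Gaussian noise."""
    from physeg.uncertainty import PercentileVolumes

    pvs, truths = [], []
    for _ in range(n_subjects):
        centre = rng.uniform(20, 40)
        scale = spread * rng.uniform(0.5, 1.5)
        vols = np.sort(centre + bias + scale * rng.standard_normal(T))
        # the truth is one more draw from the same predictive law, so a
        # calibrated sampler has uniformly distributed truth quantiles
        true_vol = centre + scale * rng.standard_normal()
        pvs.append(PercentileVolumes(vols.reshape(1, T)))
        truths.append(np.array([true_vol]))
    return pvs, truths


class TestCalibration:
    def test_identity_map_for_calibrated_sampler(self):
        rng = np.random.default_rng(0)
        pvs, truths = synthetic_percentiles(rng, 100)
        model = fit_calibration(pvs, truths)
        p = np.linspace(0, 1, 101)
        assert np.abs(model(p, 0) - p).max() < 0.08

    def test_overdispersed_sampler_compresses_map(self):
        """If all true volumes sit at the median of their samples, the
        fitted map compresses nominal percentiles toward the centre and
        the calibrated 50% interval shrinks."""
        rng = np.random.default_rng(1)
        from physeg.uncertainty import PercentileVolumes

        pvs, truths = [], []
        for _ in range(40):
            true_vol = rng.uniform(20, 40)
            noise = 5.0 * rng.standard_normal(50)
            # centre the samples on the truth: its quantile is always ~0.5
            vols = np.sort(true_vol + noise - np.median(noise))
            pvs.append(PercentileVolumes(vols.reshape(1, 50)))
            truths.append(np.array([true_vol]))
        model = fit_calibration(pvs, truths)
        lo, hi = model(0.25, 0), model(0.75, 0)
        assert hi - lo < 0.5  # narrower than the nominal 0.5 band
        iv_cal = volume_interval(pvs[0], model, level=0.5)
        iv_raw = volume_interval(pvs[0], None, level=0.5)
        assert iv_cal[0, 1] - iv_cal[0, 0] < iv_raw[0, 1] - iv_raw[0, 0]

    def test_requires_three_subjects(self):
        rng = np.random.default_rng(2)
        pvs, truths = synthetic_percentiles(rng, 2)
        with pytest.raises(ValueError, match="3 validation subjects"):
            fit_calibration(pvs, truths)

    def test_out_of_range_truth_warns_and_clamps(self):
        rng = np.random.default_rng(3)
        pvs, truths = synthetic_percentiles(rng, 5)
        truths[0] = np.array([1000.0])
        with pytest.warns(UserWarning, match="outside"):
            model = fit_calibration(pvs, truths)
        assert np.all(np.diff(model.values[0]) >= 0)

    def test_calibrated_coverage_on_fresh_stacks(self):
        """Fit on 50 synthetic subjects; the calibrated 50% interval
        covers the truth in about half of 500 fresh trials."""
        rng = np.random.default_rng(4)
        pvs, truths = synthetic_percentiles(rng, 50, bias=1.0)
        model = fit_calibration(pvs, truths)
        fresh, fresh_truths = synthetic_percentiles(rng, 500, bias=1.0)
        covered = 0
        for pv, tv in zip(fresh, fresh_truths):
            lo, hi = volume_interval(pv, model, level=0.5)[0]
            covered += lo <= tv[0] <= hi
        assert abs(covered / 500 - 0.5) <= 0.07


class TestVolumeInterval:
    def test_identical_samples_collapse_interval(self):
        probs = np.random.default_rng(0).dirichlet(np.ones(3), size=(3, 3, 3))
        probs = np.moveaxis(probs, -1, 0)
        stack = SampleStack(np.stack([probs] * 6))
        iv = volume_interval(stack, None, level=0.5)
        np.testing.assert_allclose(iv[:, 0], iv[:, 1])

    def test_identity_calibration_matches_quantile_lookup(self, rng):
        stack = random_stack(rng, T=50)
        pv = percentile_volumes(stack)
        iv = volume_interval(pv, None, level=0.5)
        for c in range(3):
            assert iv[c, 0] == pytest.approx(pv.volume_at(0.25, c))
            assert iv[c, 1] == pytest.approx(pv.volume_at(0.75, c))

    def test_intervals_nest_across_levels(self, rng):
        pv = percentile_volumes(random_stack(rng, T=20))
        inner = volume_interval(pv, None, level=0.3)
        outer = volume_interval(pv, None, level=0.9)
        assert np.all(outer[:, 0] <= inner[:, 0] + 1e-12)
        assert np.all(outer[:, 1] >= inner[:, 1] - 1e-12)

    def test_invalid_level_rejected(self, rng):
        pv = percentile_volumes(random_stack(rng))
        with pytest.raises(ValueError, match="level"):
            volume_interval(pv, None, level=1.5)


class TestUncertaintyGrid:
    def test_grid_shape_and_zero_width_for_deterministic_net(self, mpm32):
        net = build_network(
            NetworkConfig.smoke(base_channels=2, physics_width=3,
                                dropout_rate=0.0,
                                first_layer_dropout_rate=0.0)
        )
        grid = {"ti_ms": [600.0, 1200.0], "ptd_ms": [700.0, 1500.0]}
        table = uncertainty_grid(
            net, mpm32, grid, T=4, rng=np.random.default_rng(0)
        )
        assert len(table) == 4 * 3  # 2x2 grid, 3 tissues
        assert set(table["tissue"]) == {"csf", "gm", "wm"}
        np.testing.assert_allclose(table["width"], 0.0, atol=1e-9)

    def test_empty_grid_rejected(self, mpm32):
        net = build_network(NetworkConfig.smoke(base_channels=2,
                                                physics_width=3))
        with pytest.raises(ValueError, match="empty"):
            uncertainty_grid(net, mpm32, {"ti_ms": []}, T=4,
                             rng=np.random.default_rng(0))
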