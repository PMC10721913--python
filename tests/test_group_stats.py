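import numpy as np
import pytest
from scipy import ndimage

from eegmvpa import (
    ConditionPair,
    SimulationConfig,
    TFCEParams,
    build_permutation_null,
    decode_timecourse,
    extract_clusters,
    generate_study,
    group_tfce,
    paired_accuracy_difference,
    repeat_and_average_zmaps,
    tfce_transform,
    z_from_null,
)
from eegmvpa.group_stats import ZMap


def brute_force_tfce(values, E=0.5, H=2.0, dh=None, n_steps=100):
    """Independent loop-over-heights TFCE with explicit component search."""
    values = np.asarray(values, dtype=float)
    if dh is None:
        dh = (max(values.max(), 0.0) - min(values.min(), 0.0)) / n_steps
    out = np.zeros_like(values)
    for signed in (values, -values):
        sign = 1.0 if signed is values else -1.0
        vmax = signed.max()
        if vmax <= 0 or dh <= 0:
            continue
        n_h = int(np.floor(vmax / dh + 1e-9))
        for i in range(1, n_h + 1):
            h = i * dh
            mask = signed >= h
            labels, n_comp = ndimage.label(mask)
            for comp in range(1, n_comp + 1):
                members = labels == comp
                extent = members.sum()
                out[members] += sign * extent**E * h**H * dh
    return out


class TestTFCE:
    def test_zero_map_maps_to_zero(self):
        np.testing.assert_array_equal(tfce_transform(np.zeros(20)), np.zeros(20))

    def test_isolated_peak_riemann_sum(self):
        # single point of height v: TFCE -> v^(H+1)/(H+1) as dh -> 0
        v = 3.0
        x = np.zeros(11)
        x[5] = v
        out = tfce_transform(x, TFCEParams())
        assert out[5] == pytest.approx(v**3 / 3.0, rel=0.02)
        assert np.all(out[np.arange(11) != 5] == 0.0)

    def test_constant_map_closed_form(self):
        c, n = 2.0, 7
        params = TFCEParams()
        out = tfce_transform(np.full(n, c), params)
        dh = c / params.n_steps
        heights = dh * np.arange(1, params.n_steps + 1)
        expected = np.sum(n**params.E * heights**params.H * dh)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_1d_maps(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal(30) * 0.1
        np.testing.assert_allclose(
            tfce_transform(x), brute_force_tfce(x), atol=1e-9
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_on_random_2d_maps(self, seed):
        r = np.random.default_rng(100 + seed)
        x = r.standard_normal((12, 12)) * 0.1
        np.testing.assert_allclose(
            tfce_transform(x), brute_force_tfce(x), atol=1e-9
        )

    def test_odd_in_argument(self, rng):
        x = rng.standard_normal(25) * 0.05
        np.testing.assert_allclose(
            tfce_transform(-x), -tfce_transform(x), atol=1e-12
        )

    def test_monotone_in_pointwise_height(self, rng):
        x = np.abs(rng.standard_normal(20)) * 0.1
        bigger = x.copy()
        bigger[7] += 0.05
        params = TFCEParams(dh=0.001)
        assert np.all(
            tfce_transform(bigger, params) >= tfce_transform(x, params) - 1e-12
        )

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            tfce_transform(np.array([0.0, np.nan]))


class TestZFromNull:
    def test_exceeding_all_100_null_maxima_gives_233(self, rng):
        null_max = rng.uniform(0.0, 1.0, 100)
        null_min = -rng.uniform(0.0, 1.0, 100)
        observed = np.array([2.0, 0.5 * null_max.min()])
        zmap = z_from_null(observed, null_max, null_min)
        assert zmap.z[0] == pytest.approx(2.33, abs=0.005)

    def test_middle_observed_value_nonpositive_plus_tail(self, rng):
        null_max = np.linspace(1.0, 2.0, 100)
        null_min = -np.linspace(1.0, 2.0, 100)
        observed = np.array([0.0])       # below all maxima, above all minima
        zmap = z_from_null(observed, null_max, null_min)
        assert zmap.z[0] <= 0.0
        assert abs(zmap.z[0]) < 1.96

    def test_strong_negative_observed_gives_negative_ceiling(self, rng):
        null_max = np.linspace(1.0, 2.0, 100)
        null_min = -np.linspace(1.0, 2.0, 100)
        zmap = z_from_null(np.array([-5.0]), null_max, null_min)
        assert zmap.z[0] == pytest.approx(-2.33, abs=0.005)

    def test_monotone_in_observed_value(self, rng):
        null_max = rng.uniform(0.5, 1.5, 50)
        null_min = -rng.uniform(0.5, 1.5, 50)
        observed = np.linspace(-3.0, 3.0, 101)
        z = z_from_null(observed, null_max, null_min).z
        assert np.all(np.diff(z) >= -1e-12)

    def test_n_perm_1_deterministic(self):
        z1 = z_from_null(np.array([1.0]), np.array([0.5]), np.array([-0.5]))
        z2 = z_from_null(np.array([1.0]), np.array([0.5]), np.array([-0.5]))
        assert z1.z[0] == z2.z[0]


class TestPermutationNull:
    @staticmethod
    def _null_datasets(seed, n_subjects=6):
        cfg = SimulationConfig(
            n_subjects=n_subjects, n_trials_per_condition=24,
            conditions=("a", "b"), n_scalp_channels=8, sfreq=40.0,
            epoch_window=(-100.0, 400.0), seed=seed,
        )
        return [ds for ds, _ in generate_study(cfg)]

    def _subject_maps_fn(self, datasets, pair):
        def fn(rng):
            return np.stack(
                [
                    decode_timecourse(
                        ds, pair, k=8, n_repetitions=1, seed=0,
                        permute_labels_rng=rng,
                    ).accuracies[0]
                    for ds in datasets
                ]
            )
        return fn

    def test_observed_max_within_null_range_on_null_data(self):
        # on label-exchangeable data the observed maximum should usually
        # fall inside the permutation null's range
        inside = 0
        n_runs = 8
        for seed in range(n_runs):
            datasets = self._null_datasets(seed)
            pair = ConditionPair("a", "b")
            maps = np.stack(
                [
                    decode_timecourse(ds, pair, k=8, n_repetitions=1, seed=0)
                    .accuracies[0]
                    for ds in datasets
                ]
            )
            observed = group_tfce(maps)
            null_max, null_min = build_permutation_null(
                self._subject_maps_fn(datasets, pair), n_perm=30, seed=seed
            )
            if observed.max() <= null_max.max() and observed.min() >= null_min.min():
                inside += 1
        assert inside >= n_runs - 2

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            build_permutation_null(
                lambda rng: np.zeros((1, 5)), n_perm=2, seed=0
            )


class TestRepeatAverage:
    def test_identical_repetitions_average_to_themselves(self):
        z = np.array([0.0, 2.3, 1.0])
        fn = lambda rep: ZMap(z=z.copy(), times=np.arange(3.0)).finalize()
        out = repeat_and_average_zmaps(fn, n_repetitions=5)
        np.testing.assert_allclose(out.z, z)

    def test_single_repetition_is_identity(self, rng):
        z = rng.standard_normal(10)
        fn = lambda rep: ZMap(z=z.copy(), times=np.arange(10.0)).finalize()
        out = repeat_and_average_zmaps(fn, n_repetitions=1)
        np.testing.assert_allclose(out.z, z)

    def test_averaging_reduces_variance(self, rng):
        def noisy_fn(rep):
            r = np.random.default_rng([7, rep])
            return ZMap(z=r.standard_normal(50), times=np.arange(50.0)).finalize()

        single = noisy_fn(0).z.var()
        avg = repeat_and_average_zmaps(noisy_fn, n_repetitions=20).z.var()
        assert avg < single


class TestPairedDifference:
    def test_identically_distributed_inputs_rarely_significant(self):
        any_sig = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            acc_a = 0.5 + 0.02 * r.standard_normal((8, 30))
            acc_b = 0.5 + 0.02 * r.standard_normal((8, 30))
            zmap = paired_accuracy_difference(
                acc_a, acc_b, np.arange(30.0), n_perm=50, seed=seed
            )
            any_sig += int(zmap.mask.any())
        assert any_sig <= 3

    def test_real_difference_recovered_with_sign(self, rng):
        times = np.arange(0.0, 300.0, 10.0)
        acc_a = 0.5 + 0.01 * rng.standard_normal((10, 30))
        acc_b = acc_a.copy()
        window = (times >= 100.0) & (times < 200.0)
        acc_a[:, window] += 0.1
        zmap = paired_accuracy_difference(acc_a, acc_b, times, n_perm=60, seed=1)
        assert zmap.mask[window].all()
        assert zmap.z[window].min() > 1.96
        assert not zmap.mask[~window].any()

    def test_swapping_inputs_negates_z_exactly(self, rng):
        acc_a = 0.5 + 0.05 * rng.standard_normal((6, 20))
        acc_b = 0.5 + 0.05 * rng.standard_normal((6, 20))
        times = np.arange(20.0)
        z_ab = paired_accuracy_difference(acc_a, acc_b, times, n_perm=40, seed=9)
        z_ba = paired_accuracy_difference(acc_b, acc_a, times, n_perm=40, seed=9)
        np.testing.assert_allclose(z_ab.z, -z_ba.z, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            paired_accuracy_difference(
                np.zeros((4, 10)), np.zeros((4, 12)), np.arange(10.0)
            )


class TestExtractClusters:
    def test_empty_when_nothing_significant(self):
        assert extract_clusters(np.zeros(10), np.arange(10.0)) == []

    def test_contiguity_splits_clusters(self):
        z = np.array([0.0, 2.3, 2.3, 0.0, 2.3])
        clusters = extract_clusters(z, np.arange(5.0) * 4.0)
        assert len(clusters) == 2
        assert clusters[0].onset == 4.0
        assert clusters[0].offset == 8.0
        assert clusters[1].onset == 16.0

    def test_peak_bookkeeping_with_accuracy(self):
        z = np.array([0.0, 2.0, 2.5, 2.1, 0.0])
        acc = np.array([0.5, 0.55, 0.62, 0.58, 0.5])
        (c,) = extract_clusters(z, np.arange(5.0), accuracy=acc)
        assert c.peak_z == 2.5
        assert c.peak_accuracy == 0.62
        assert c.sign == 1

    def test_negative_clusters_reported_with_sign(self):
        z = np.array([0.0, -2.3, -2.5, 0.0])
        (c,) = extract_clusters(z, np.arange(4.0))
        assert c.sign == -1
        assert c.peak_z == -2.5

    def test_2d_four_connectivity(self):
        z = np.zeros((5, 5))
        z[1, 1] = 2.5
        z[2, 2] = 2.5     # diagonal neighbor: separate cluster
        clusters = extract_clusters(z, np.arange(5.0), times_test=np.arange(5.0))
        assert len(clusters) == 2
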