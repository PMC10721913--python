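import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from eegmvpa import (
    ConditionPair,
    EffectSpec,
    SimulationConfig,
    cross_classify_timecourse,
    decode_timecourse,
    generate_subject,
    lda_fit,
    make_balanced_folds,
    make_topography,
    temporal_generalization,
    zscore_train_apply,
)


class TestZScore:
    def test_train_as_its_own_test_is_standardized(self, rng):
        X = rng.standard_normal((20, 5)) * 3.0 + 1.0
        train_z, test_z = zscore_train_apply(X, X)
        np.testing.assert_allclose(test_z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(test_z.std(axis=0), 1.0, atol=1e-10)

    def test_constant_feature_flagged_not_fatal(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 4.0
        train_z, test_z = zscore_train_apply(X, X)
        np.testing.assert_allclose(train_z[:, 1], 0.0)

    def test_matches_per_feature_formula(self, rng):
        train = rng.standard_normal((10, 4)) * 2.0 + 0.5
        test = rng.standard_normal((5, 4))
        train_z, test_z = zscore_train_apply(train, test)
        mu, sd = train.mean(axis=0), train.std(axis=0)
        np.testing.assert_allclose(train_z, (train - mu) / sd, atol=1e-12)
        np.testing.assert_allclose(test_z, (test - mu) / sd, atol=1e-12)


class TestLDA:
    def test_one_d_boundary_between_class_means(self):
        X = np.array([[0.0], [1.0], [4.0], [5.0]])
        y = np.array([0, 0, 1, 1])
        model = lda_fit(X, y, shrinkage=0.0)
        # decision flips at (m0 + m1)/2 = 2.5
        assert model.decision(np.array([[2.5]]))[0] == pytest.approx(0.0, abs=1e-10)
        assert model.predict(np.array([[2.4], [2.6]])).tolist() == [0, 1]

    def test_two_d_closed_form(self, rng):
        # identity covariance, means (0,0) and (2,0): boundary x1 = 1
        X0 = rng.standard_normal((2000, 2))
        X1 = rng.standard_normal((2000, 2)) + [2.0, 0.0]
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], 2000)
        model = lda_fit(X, y, shrinkage=0.0)
        w = model.w / np.abs(model.w[0])
        assert w[0] == pytest.approx(2.0 / 1.0, rel=0.2) or w[0] == pytest.approx(
            1.0, rel=0.2
        )
        assert abs(w[1] / w[0]) < 0.1
        boundary = -model.b / model.w[0]
        assert boundary == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_discriminant(self, seed):
        """Explicitly inverted shrunk covariance reproduces the predictions."""
        r = np.random.default_rng(seed)
        X = r.standard_normal((40, 6)) + np.repeat([0, 1], 20)[:, None]
        y = np.repeat([0, 1], 20)
        lam = 0.1
        model = lda_fit(X, y, shrinkage=lam)
        mu0, mu1 = X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)
        Xc = np.vstack([X[y == 0] - mu0, X[y == 1] - mu1])
        S = Xc.T @ Xc / (len(X) - 2)
        S_shr = (1 - lam) * S + lam * np.trace(S) / 6 * np.eye(6)
        w = np.linalg.inv(S_shr) @ (mu1 - mu0)
        b = -w @ (mu0 + mu1) / 2
        Xt = r.standard_normal((30, 6))
        np.testing.assert_array_equal(
            model.predict(Xt), (Xt @ w + b > 0).astype(int)
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sklearn_with_balanced_classes(self, seed):
        r = np.random.default_rng(seed)
        X = r.standard_normal((40, 6)) + np.repeat([0, 1], 20)[:, None] * 0.5
        y = np.repeat([0, 1], 20)
        model = lda_fit(X, y, shrinkage=0.2)
        sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.2).fit(X, y)
        Xt = r.standard_normal((30, 6))
        np.testing.assert_array_equal(model.predict(Xt), sk.predict(Xt))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            lda_fit(rng.standard_normal((10, 3)), np.zeros(10, dtype=int))


class TestBalancedFolds:
    def test_128_trials_k10_uses_120_per_class(self):
        labels = np.repeat(["hands", "animals"], 128)
        folds = make_balanced_folds(labels, 10, seed=0)
        assert (folds >= 0).sum() == 240
        for f in range(10):
            sel = folds == f
            assert (labels[sel] == "hands").sum() == 12
            assert (labels[sel] == "animals").sum() == 12

    def test_k_equal_class_count_is_leave_one_per_class_out(self):
        labels = np.repeat(["a", "b"], 5)
        folds = make_balanced_folds(labels, 5, seed=1)
        for f in range(5):
            assert (folds == f).sum() == 2

    def test_deterministic_given_seed(self):
        labels = np.repeat(["a", "b"], 30)
        np.testing.assert_array_equal(
            make_balanced_folds(labels, 10, seed=3),
            make_balanced_folds(labels, 10, seed=3),
        )

    def test_class_smaller_than_k_rejected(self):
        labels = np.array(["a"] * 5 + ["b"] * 20)
        with pytest.raises(ValueError, match="fewer than k"):
            make_balanced_folds(labels, 10, seed=0)


def high_snr_subject(seed=3, amplitude=4.0, conditions=("hands", "animals")):
    cfg = SimulationConfig(
        n_subjects=1, n_trials_per_condition=32, conditions=conditions,
        n_scalp_channels=10, sfreq=100.0, epoch_window=(-100.0, 400.0),
        noise_sd=1.0, seed=seed, amplitude_jitter_frac=0.0,
        effects=(
            EffectSpec(("hands",), (100.0, 300.0), amplitude, topography=5),
        ),
    )
    return generate_subject(cfg, 0)[0]


class TestDecodeTimecourse:
    def test_high_snr_effect_window_decodes_strongly(self):
        ds = high_snr_subject()
        tc = decode_timecourse(
            ds, ConditionPair("hands", "animals"), k=8, n_repetitions=2, seed=1
        )
        inside = (tc.times >= 120.0) & (tc.times < 280.0)
        outside = tc.times < 80.0
        assert tc.mean_accuracy[inside].min() > 0.9
        assert abs(tc.mean_accuracy[outside].mean() - 0.5) < 0.1

    def test_null_labels_decode_at_chance(self):
        # permuted labels: grand-mean accuracy within binomial noise of 0.5
        accs = []
        for seed in range(12):
            cfg = SimulationConfig(
                n_subjects=1, n_trials_per_condition=32, conditions=("a", "b"),
                n_scalp_channels=8, sfreq=40.0, epoch_window=(-100.0, 400.0),
                seed=seed,
            )
            ds, _ = generate_subject(cfg, 0)
            tc = decode_timecourse(
                ds, ConditionPair("a", "b"), k=10, n_repetitions=2, seed=seed
            )
            accs.append(tc.mean_accuracy.mean())
        assert abs(np.mean(accs) - 0.5) < 0.02

    def test_deterministic_given_seed(self):
        ds = high_snr_subject()
        a = decode_timecourse(ds, ConditionPair("hands", "animals"), k=5,
                              n_repetitions=2, seed=7)
        b = decode_timecourse(ds, ConditionPair("hands", "animals"), k=5,
                              n_repetitions=2, seed=7)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)

    def test_label_permutation_changes_result_not_models_of_truth(self):
        ds = high_snr_subject()
        rng = np.random.default_rng(0)
        tc = decode_timecourse(
            ds, ConditionPair("hands", "animals"), k=8, n_repetitions=1,
            seed=1, permute_labels_rng=rng,
        )
        inside = (tc.times >= 120.0) & (tc.times < 280.0)
        assert tc.mean_accuracy[inside].mean() < 0.75

    def test_accuracy_monotone_in_snr(self):
        peaks = []
        for amp in (0.3, 1.0, 4.0):
            ds = high_snr_subject(seed=9, amplitude=amp)
            tc = decode_timecourse(
                ds, ConditionPair("hands", "animals"), k=8, n_repetitions=2,
                seed=2,
            )
            peaks.append(tc.mean_accuracy.max())
        assert peaks[0] <= peaks[1] <= peaks[2]


def shared_pattern_subject(seed=4, amplitude=3.0):
    cfg = SimulationConfig(
        n_subjects=1, n_trials_per_condition=32,
        conditions=("hands", "tools", "animals"), n_scalp_channels=10,
        sfreq=100.0, epoch_window=(-100.0, 400.0), seed=seed,
        amplitude_jitter_frac=0.0,
        effects=(
            EffectSpec(("hands", "tools"), (250.0, 350.0), amplitude,
                       topography=8),
        ),
    )
    return generate_subject(cfg, 0)[0]


class TestCrossClassification:
    def test_shared_pattern_generalizes_only_inside_window(self):
        ds = shared_pattern_subject()
        cc = cross_classify_timecourse(
            ds, ConditionPair("tools", "animals"), "hands",
            n_repetitions=2, seed=5,
        )
        inside = (cc.times >= 270.0) & (cc.times < 330.0)
        outside = cc.times < 200.0
        assert cc.mean_accuracy[inside].min() > 0.8
        assert abs(cc.mean_accuracy[outside].mean() - 0.5) < 0.1

    def test_exchangeable_test_condition_scores_near_half(self):
        cfg = SimulationConfig(
            n_subjects=1, n_trials_per_condition=32,
            conditions=("a", "b", "c"), n_scalp_channels=8, sfreq=40.0,
            epoch_window=(-100.0, 400.0), seed=6,
        )
        ds, _ = generate_subject(cfg, 0)
        cc = cross_classify_timecourse(
            ds, ConditionPair("a", "b"), "c", n_repetitions=2, seed=3
        )
        assert abs(cc.mean_accuracy.mean() - 0.5) < 0.05

    def test_test_condition_must_be_disjoint(self):
        ds = shared_pattern_subject()
        with pytest.raises(ValueError, match="disjoint"):
            cross_classify_timecourse(
                ds, ConditionPair("tools", "animals"), "tools"
            )


class TestTemporalGeneralization:
    def test_diagonal_equals_cross_classification_exactly(self):
        ds = shared_pattern_subject()
        pair = ConditionPair("tools", "animals")
        cc = cross_classify_timecourse(ds, pair, "hands", n_repetitions=3, seed=9)
        tg = temporal_generalization(ds, pair, "hands", n_repetitions=3, seed=9)
        np.testing.assert_array_equal(tg.diagonal, cc.accuracies)

    def test_stationary_pattern_gives_square_block(self):
        ds = shared_pattern_subject(amplitude=4.0)
        tg = temporal_generalization(
            ds, ConditionPair("tools", "animals"), "hands",
            n_repetitions=2, seed=1,
        )
        times = tg.times
        inside = (times >= 270.0) & (times < 330.0)
        outside = times < 200.0
        block = tg.mean_values[np.ix_(inside, inside)]
        off = tg.mean_values[np.ix_(inside, outside)]
        assert block.min() > 0.8
        assert abs(off.mean() - 0.5) < 0.1

    def test_orthogonal_topographies_do_not_generalize_across_windows(self):
        topo_a = make_topography(1, 10)
        r = np.random.default_rng(2)
        v = r.standard_normal(10)
        topo_b = v - (v @ topo_a) * topo_a
        topo_b /= np.linalg.norm(topo_b)
        cfg = SimulationConfig(
            n_subjects=1, n_trials_per_condition=32,
            conditions=("hands", "tools", "animals"), n_scalp_channels=10,
            sfreq=100.0, epoch_window=(-100.0, 400.0), seed=11,
            amplitude_jitter_frac=0.0,
            effects=(
                EffectSpec(("hands", "tools"), (0.0, 100.0), 4.0,
                           topography=tuple(topo_a)),
                EffectSpec(("hands", "tools"), (250.0, 350.0), 4.0,
                           topography=tuple(topo_b)),
            ),
        )
        ds, _ = generate_subject(cfg, 0)
        tg = temporal_generalization(
            ds, ConditionPair("tools", "animals"), "hands",
            n_repetitions=2, seed=4,
        )
        w1 = (tg.times >= 20.0) & (tg.times < 80.0)
        w2 = (tg.times >= 270.0) & (tg.times < 330.0)
        cross_block = tg.mean_values[np.ix_(w1, w2)]
        assert abs(cross_block.mean() - 0.5) < 0.1
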