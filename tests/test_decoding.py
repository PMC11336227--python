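import numpy as np
import pytest
from scipy import stats

from prestim.decoding import (DecodeConfig, binomial_accuracy_test,
                              binomial_pit, build_features,
                              cross_decode_subject, decode_features,
                              fit_svm_grid, group_lopocv,
                              group_lopocv_features, group_ttest_vs_chance,
                              peak_accuracy, previous_label_control_features,
                              summarize_previous_control, zscore_features)
from prestim.tfr import TimeFreqRep

from .conftest import make_tfr


def labelled_tfr(n_per_class=20, n_channels=4, n_freqs=6, separation=0.0,
                 seed=0, times=None):
    """Raw-power TFR whose first channel/frequency carries a class difference."""
    rng = np.random.default_rng(seed)
    if times is None:
        times = np.arange(-1000.0, -199.0, 50.0)
    n = 2 * n_per_class
    power = rng.uniform(1.0, 2.0, size=(n, n_channels, n_freqs, len(times)))
    labels = np.array(["negative", "positive"] * n_per_class)
    power[labels == "negative", 0, 0, :] += separation
    return make_tfr(power, times=times), labels


class TestBuildFeatures:
    def test_shape_is_trials_by_channels_freqs(self):
        tfr, labels = labelled_tfr(n_channels=3, n_freqs=5)
        X, y, freqs = build_features(tfr, labels, DecodeConfig())
        assert X.shape == (40, 15)
        assert len(freqs) == 5

    def test_rejects_unbalanced_classes(self):
        tfr, labels = labelled_tfr()
        labels = labels.copy()
        labels[0] = "positive"
        with pytest.raises(ValueError, match="equalized"):
            build_features(tfr, labels, DecodeConfig())

    def test_rejects_unknown_labels(self):
        tfr, labels = labelled_tfr()
        labels = labels.copy()
        labels[:2] = ["neutral", "neutral"]
        with pytest.raises(ValueError, match="negative/positive"):
            build_features(tfr, labels, DecodeConfig())

    def test_rejects_db_power(self):
        tfr, labels = labelled_tfr()
        db = TimeFreqRep(tfr.power, tfr.freqs, tfr.times, tfr.channels,
                         unit="dB", baseline=(-1500.0, -500.0))
        with pytest.raises(ValueError, match="raw"):
            build_features(db, labels, DecodeConfig())

    def test_no_post_onset_leakage(self):
        # bins whose 500 ms analysis window reaches t >= 0 never contribute:
        # perturbing them leaves the features identical
        times = np.arange(-1000.0, 1001.0, 50.0)
        tfr, labels = labelled_tfr(times=times)
        X, _, _ = build_features(tfr, labels, DecodeConfig())
        perturbed = tfr.power.copy()
        reaches_onset = times + tfr.window_length / 2.0 > 0.0
        perturbed[..., reaches_onset] *= 100.0
        tfr2 = make_tfr(perturbed, times=times)
        X2, _, _ = build_features(tfr2, labels, DecodeConfig())
        np.testing.assert_array_equal(X, X2)

    def test_window_entirely_post_onset_raises(self):
        with pytest.raises(ValueError):
            DecodeConfig(window=(-100.0, 0.0))


class TestBinomialStats:
    def test_matches_bruteforce_tail_sum(self):
        from math import comb
        for n in (5, 17, 40):
            for k in range(n + 1):
                p, _ = binomial_accuracy_test(k / n, n)
                want = sum(comb(n, j) for j in range(k, n + 1)) / 2.0 ** n
                assert np.isclose(p[0], want, rtol=1e-12)

    def test_mask_thresholds_at_five_percent(self):
        p, mask = binomial_accuracy_test([0.9, 0.5], [20, 20])
        assert mask[0] and not mask[1]

    def test_non_integer_count_raises(self):
        with pytest.raises(ValueError, match="integer"):
            binomial_accuracy_test(0.513, 20)

    def test_pit_is_uniform_under_null(self):
        rng = np.random.default_rng(0)
        n_test = rng.integers(20, 60, size=2000)
        ks = rng.binomial(n_test, 0.5)
        u = binomial_pit(ks / n_test, n_test, rng=np.random.default_rng(1))
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_pit_detects_shifted_accuracies(self):
        rng = np.random.default_rng(2)
        n_test = np.full(500, 40)
        ks = rng.binomial(n_test, 0.7)
        u = binomial_pit(ks / n_test, n_test, rng=np.random.default_rng(3))
        assert stats.kstest(u, "uniform").pvalue < 1e-6


class TestPeakAndGroupStats:
    def _result(self, accs, mask):
        accs = np.asarray(accs, dtype=float)
        from prestim.decoding import DecodeResult
        return DecodeResult(accs, np.full(accs.shape, 20), np.zeros_like(accs),
                            np.asarray(mask))

    def test_peak_prefers_masked_max(self):
        res = self._result([0.9, 0.7, 0.6], [False, True, True])
        assert peak_accuracy(res) == 0.7

    def test_peak_falls_back_to_global_max(self):
        res = self._result([0.9, 0.7], [False, False])
        assert peak_accuracy(res) == 0.9

    def test_group_t_matches_scipy(self):
        peaks = [0.6, 0.7, 0.55, 0.65, 0.8]
        t, df, p = group_ttest_vs_chance(peaks)
        want = stats.ttest_1samp(peaks, 0.5)
        assert np.isclose(t, want.statistic) and np.isclose(p, want.pvalue)
        assert df == 4

    def test_group_t_zero_variance_flagged(self):
        t, df, p = group_ttest_vs_chance([0.6, 0.6, 0.6])
        assert np.isnan(t) and np.isnan(p) and df == 2


class TestSvmGrid:
    def test_perfectly_separable_data(self):
        tfr, labels = labelled_tfr(separation=50.0, seed=1)
        X, y, _ = build_features(tfr, labels, DecodeConfig())
        model = fit_svm_grid(X, y, DecodeConfig())
        assert (model.predict(X) == y).all()
        assert model.best_params_["C"] in DecodeConfig().C_grid

    def test_single_class_raises(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            fit_svm_grid(X, ["negative"] * 10, DecodeConfig())

    def test_deterministic_under_seed(self):
        tfr, labels = labelled_tfr(separation=0.5, seed=2)
        X, y, _ = build_features(tfr, labels, DecodeConfig(seed=5))
        a = fit_svm_grid(X, y, DecodeConfig(seed=5))
        b = fit_svm_grid(X, y, DecodeConfig(seed=5))
        assert a.best_params_ == b.best_params_
        np.testing.assert_array_equal(a.cv_results_["mean_test_score"],
                                      b.cv_results_["mean_test_score"])


class TestCrossDecoding:
    def test_strong_shared_effect_decodes_above_chance(self):
        tfr1, y1 = labelled_tfr(separation=5.0, seed=3)
        tfr2, y2 = labelled_tfr(n_per_class=15, separation=5.0, seed=4)
        res = cross_decode_subject(tfr1, y1, tfr2, y2, DecodeConfig())
        assert res.accuracies[0] > 0.8
        assert res.n_test[0] == 30
        assert res.train_experiment == 1 and res.test_experiment == 2

    def test_per_frequency_mode_gives_one_accuracy_per_frequency(self):
        tfr1, y1 = labelled_tfr(n_freqs=4, separation=5.0, seed=5)
        tfr2, y2 = labelled_tfr(n_freqs=4, n_per_class=10, separation=5.0,
                                seed=6)
        cfg = DecodeConfig(mode="per_frequency")
        res = cross_decode_subject(tfr1, y1, tfr2, y2, cfg)
        assert res.accuracies.shape == (4,)
        assert len(res.freqs) == 4
        # the effect lives at the first frequency only
        assert res.accuracies[0] == res.accuracies.max()
        assert res.accuracies[0] > 0.8

    def test_chance_when_no_effect(self):
        tfr1, y1 = labelled_tfr(separation=0.0, seed=7)
        tfr2, y2 = labelled_tfr(n_per_class=25, separation=0.0, seed=8)
        res = cross_decode_subject(tfr1, y1, tfr2, y2, DecodeConfig())
        # well inside the binomial 99% band for n = 50
        assert abs(res.accuracies[0] - 0.5) < 0.2


class TestZScore:
    def test_zero_mean_unit_sd(self):
        X = np.random.default_rng(0).normal(3.0, 2.0, size=(30, 5))
        Z = zscore_features(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_constant_feature_maps_to_zero(self):
        X = np.ones((10, 2))
        Z = zscore_features(X)
        np.testing.assert_array_equal(Z, 0.0)


class TestGroupLopocv:
    def _subjects(self, n_subjects, separation, seed=0):
        out = []
        for i in range(n_subjects):
            tfr1, y1 = labelled_tfr(n_per_class=12, separation=separation,
                                    seed=seed + 2 * i)
            tfr2, y2 = labelled_tfr(n_per_class=8, separation=separation,
                                    seed=seed + 2 * i + 1)
            cfg = DecodeConfig()
            X1, _, _ = build_features(tfr1, y1, cfg)
            X2, _, _ = build_features(tfr2, y2, cfg)
            out.append((X1, y1, X2, y2))
        return out

    def test_one_accuracy_per_subject(self):
        subs = self._subjects(4, separation=2.0)
        results, peaks = group_lopocv_features(subs, DecodeConfig())
        assert len(results) == 4 and len(peaks) == 4
        for res, (_, _, _, y2) in zip(results, subs):
            assert res.n_test[0] == len(y2)

    def test_shared_effect_decodes_above_chance(self):
        subs = self._subjects(5, separation=3.0, seed=100)
        _, peaks = group_lopocv_features(subs, DecodeConfig())
        assert peaks.mean() > 0.6

    def test_needs_three_subjects(self):
        subs = self._subjects(2, separation=1.0)
        with pytest.raises(ValueError, match="3 subjects"):
            group_lopocv_features(subs, DecodeConfig())

    def test_tfr_level_warns_on_missing_experiment(self):
        tfr1, y1 = labelled_tfr(n_per_class=10, separation=2.0, seed=20)
        items = [(tfr1, y1, tfr1, y1)] * 3 + [(tfr1, y1, None, None)]
        with pytest.warns(UserWarning, match="missing an experiment"):
            results, peaks = group_lopocv(items, DecodeConfig())
        assert len(peaks) == 3


class TestPreviousLabelControl:
    def test_alternating_labels_give_complementary_accuracies(self):
        # deterministic alternation: previous label is the complement of the
        # current one, so a previous-label decoder scored on current labels
        # attains 1 - (current-label accuracy)
        rng = np.random.default_rng(0)
        n = 60
        current = np.array(["negative", "positive"] * (n // 2))
        previous = np.array(["positive", "negative"] * (n // 2))
        X = rng.normal(size=(n, 8))
        X[current == "negative", 0] += 20.0  # separable on the current label
        out = previous_label_control_features(X, current, previous,
                                              DecodeConfig(seed=1))
        acc_prev, acc_cur = out
        assert acc_cur > 0.95
        assert np.isclose(acc_prev, 1.0 - 1.0)  # predicts the complement

    def test_current_label_effect_with_iid_previous(self):
        rng = np.random.default_rng(1)
        n = 80
        current = rng.permutation(np.array(["negative", "positive"] * (n // 2)))
        previous = rng.permutation(current)
        X = rng.normal(size=(n, 6))
        X[current == "negative", 0] += 3.0
        out = previous_label_control_features(X, current, previous,
                                              DecodeConfig(seed=2))
        acc_prev, acc_cur = out
        assert acc_cur > 0.8
        assert 0.3 < acc_prev < 0.7

    def test_too_few_trials_returns_none_with_warning(self):
        X = np.zeros((8, 3))
        labels = np.array(["negative", "positive"] * 4)
        with pytest.warns(UserWarning, match="skipped"):
            out = previous_label_control_features(X, labels, labels,
                                                  DecodeConfig())
        assert out is None

    def test_summary_paired_t_matches_scipy(self):
        pairs = [(0.5, 0.7), (0.45, 0.8), (0.55, 0.75), (0.5, 0.6)]
        out = summarize_previous_control(pairs)
        want = stats.ttest_rel([p[1] for p in pairs], [p[0] for p in pairs])
        assert np.isclose(out["t"], want.statistic)
        assert np.isclose(out["p"], want.pvalue)
        assert out["df"] == 3

    def test_summary_needs_two_subjects(self):
        with pytest.raises(ValueError):
            summarize_previous_control([(0.5, 0.6)])


class TestDecodeConfigValidation:
    def test_rejects_empty_or_negative_grid(self):
        with pytest.raises(ValueError):
            DecodeConfig(C_grid=())
        with pytest.raises(ValueError):
            DecodeConfig(C_grid=(-1.0,))

    def test_rejects_unknown_mode(self):
        with pytest.raises(ValueError):
            DecodeConfig(mode="banana")
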