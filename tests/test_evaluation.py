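"""Cross-validation planning, metrics, significance and robustness."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from stcca import nn
from stcca.data import EEGTrialSet, LeakageError
from stcca.evaluation import (
    accuracy_summary,
    channel_dropout_eval,
    confusion_and_f1,
    count_flops,
    count_parameters,
    fit_fold_zscore,
    loso_split,
    n_dropout_channels,
    stratified_kfold,
    wilcoxon_signed_rank,
)


class TestStratifiedKFold:
    def test_benchmark_subject_split_400_train_100_test(self):
        labels = np.repeat([1, 2, 3, 4], 125)  # 500 trials, balanced
        plan = stratified_kfold(labels, 5, seed=0)
        assert len(plan) == 5
        for train, test in plan:
            assert len(train) == 400 and len(test) == 100
            counts = np.bincount(labels[test])[1:]
            assert (counts == 25).all()
            assert len(np.intersect1d(train, test)) == 0
            assert len(np.union1d(train, test)) == 500

    def test_minimal_stratification(self):
        labels = np.repeat([1, 2], 5)
        plan = stratified_kfold(labels, 5, seed=1)
        for train, test in plan:
            assert len(train) == 8 and len(test) == 2
            assert sorted(labels[test]) == [1, 2]

    def test_class_smaller_than_fold_count_rejected(self):
        labels = np.array([1] * 3 + [2] * 10)
        with pytest.raises(ValueError, match="class 1"):
            stratified_kfold(labels, 5, seed=0)

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_per_class_test_counts_within_one(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(1, 4, size=60)
        labels[:15] = [1, 2, 3] * 5  # ensure enough per class
        plan = stratified_kfold(labels, 3, seed=seed)
        for c in (1, 2, 3):
            per_fold = [np.sum(labels[test] == c) for _, test in plan]
            assert max(per_fold) - min(per_fold) <= 1


class TestLoso:
    def test_one_fold_per_subject(self):
        subjects = np.array(["a"] * 4 + ["b"] * 6 + ["c"] * 2)
        plan = loso_split(subjects)
        assert len(plan) == 3
        test_sizes = sorted(len(test) for _, test in plan)
        assert test_sizes == [2, 4, 6]
        all_test = np.concatenate([test for _, test in plan])
        assert sorted(all_test) == list(range(12))

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            loso_split(["s1"] * 5)


class TestAccuracySummary:
    def test_constant_and_single_fold(self):
        assert accuracy_summary([45] * 5) == (45.0, 0.0)
        assert accuracy_summary([30]) == (30.0, 0.0)

    def test_population_divisor_example(self):
        mu, sigma = accuracy_summary([40, 45, 50, 45, 45])
        assert mu == pytest.approx(45.0)
        assert sigma == pytest.approx(3.1623, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy_summary([])

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_formulas(self, accs):
        mu, sigma = accuracy_summary(accs)
        n = len(accs)
        mu_bf = sum(accs) / n
        sigma_bf = (sum((a - mu_bf) ** 2 for a in accs) / n) ** 0.5
        assert mu == pytest.approx(mu_bf, abs=1e-9)
        assert sigma == pytest.approx(sigma_bf, abs=1e-9)


class TestConfusionF1:
    def test_perfect_prediction(self):
        true = np.repeat([1, 2, 3, 4], 5)
        cm, f1 = confusion_and_f1(true, true, 4)
        np.testing.assert_array_equal(cm, 5 * np.eye(4))
        assert f1 == pytest.approx(1.0)

    def test_binary_hand_example(self):
        # TP=2, FP=1, FN=1, TN=2 for class 1
        true = np.array([1, 1, 1, 2, 2, 2])
        pred = np.array([1, 1, 2, 1, 2, 2])
        cm, f1 = confusion_and_f1(true, pred, 2)
        np.testing.assert_array_equal(cm, [[2, 1], [1, 2]])
        assert f1 == pytest.approx(2 / 3, abs=1e-9)

    def test_collapsed_predictions_macro_point_one(self):
        true = np.repeat([1, 2, 3, 4], 5)
        pred = np.ones_like(true)
        _, f1 = confusion_and_f1(true, pred, 4)
        assert f1 == pytest.approx(0.1, abs=1e-9)  # (0.4 + 0 + 0 + 0) / 4

    def test_row_sums_equal_per_class_counts(self, rng):
        true = rng.integers(1, 5, size=40)
        pred = rng.integers(1, 5, size=40)
        cm, _ = confusion_and_f1(true, pred, 4)
        np.testing.assert_array_equal(cm.sum(axis=1), np.bincount(true, minlength=5)[1:])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_and_f1([1, 2], [1], 2)


class TestChannelDropout:
    def test_rounding_rule(self):
        assert n_dropout_channels(0.05, 128) == 6   # round(6.4) = 6
        assert n_dropout_channels(0.10, 128) == 13  # round(12.8) = 13
        assert n_dropout_channels(0.05, 8) == 1     # minimum of 1
        assert n_dropout_channels(0.0, 128) == 0

    def test_fraction_zero_is_identity(self, small_trialset):
        baseline = lambda x: np.ones(len(x), dtype=int)
        acc0 = channel_dropout_eval(baseline, small_trialset, 0.0, seed=0)
        expected = np.mean(small_trialset.labels == 1)
        assert acc0 == pytest.approx(expected)

    def test_fraction_one_rejected(self, small_trialset):
        with pytest.raises(ValueError):
            channel_dropout_eval(lambda x: np.ones(len(x)), small_trialset,
                                 1.0, seed=0)

    def test_zeroed_channels_reach_predictor(self, small_trialset):
        seen = {}

        def spy(x):
            seen["zeroed"] = int(np.sum(np.all(x == 0, axis=(0, 2))))
            return np.ones(len(x), dtype=int)

        channel_dropout_eval(spy, small_trialset, 0.25, seed=1)
        assert seen["zeroed"] == 2  # round(0.25 * 8)


def enumeration_wilcoxon(d):
    """Literal 2^n sign-enumeration oracle for the two-sided p-value."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sstats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    eps = 1e-9
    cdf = np.mean(ws <= w_obs + eps)
    sf = np.mean(ws >= w_obs - eps)
    return min(1.0, 2 * min(cdf, sf))


class TestWilcoxon:
    def test_all_positive_differences_n6(self):
        b = np.arange(6, dtype=float)
        a = b + 1
        assert wilcoxon_signed_rank(a, b) == pytest.approx(2 / 64, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_full_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        d = np.round(rng.standard_normal(n), 2)
        d[d == 0] = 0.5
        p_impl = wilcoxon_signed_rank(d, np.zeros(n))
        assert p_impl == pytest.approx(enumeration_wilcoxon(d), abs=1e-10)

    def test_agrees_with_scipy_exact_on_tie_free_data(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(12)
        ours = wilcoxon_signed_rank(a, b)
        ref = sstats.wilcoxon(a, b, alternative="two-sided",
                              method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_two_sided_symmetry(self, rng):
        a = rng.standard_normal(9)
        b = rng.standard_normal(9)
        assert wilcoxon_signed_rank(a, b) == pytest.approx(
            wilcoxon_signed_rank(b, a), abs=1e-12)

    def test_large_n_uses_normal_approximation(self, rng):
        a = rng.standard_normal(40)
        b = a + 0.5 + rng.standard_normal(40)
        ours = wilcoxon_signed_rank(a, b)
        ref = sstats.wilcoxon(a, b, alternative="two-sided",
                              method="approx", correction=False).pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="discriminative"):
            wilcoxon_signed_rank(np.ones(6), np.ones(6))


class TestCounting:
    def test_single_affine_map(self):
        lin = nn.Linear(4, 2, np.random.default_rng(0))
        assert count_parameters(lin) == 10

    def test_monotone_under_module_removal(self):
        from stcca.model import ModelConfig
        from stcca.training import build_model

        base = dict(n_classes=4, channels=8, timepoints=64,
                    sampling_rate=256, k=8, h=2, fc_hidden=16)
        full = build_model(ModelConfig(**base), seed=0)
        trimmed = build_model(ModelConfig(**base, variant="no_gfem"), seed=0)
        assert count_parameters(trimmed) < count_parameters(full)

    def test_count_invariant_to_mode(self):
        lin = nn.Linear(4, 2, np.random.default_rng(0))
        n_eval = count_parameters(lin.eval())
        n_train = count_parameters(lin.train())
        assert n_eval == n_train == 10

    def test_flops_positive_and_ordered(self):
        from stcca.model import ModelConfig

        base = dict(n_classes=4, channels=8, timepoints=64,
                    sampling_rate=256, k=8, h=2, fc_hidden=16)
        cca = count_flops(ModelConfig(**base, fusion="cca"))
        summ = count_flops(ModelConfig(**base, fusion="sum"))
        assert cca > summ > 0


class TestLeakageGuard:
    def test_overlapping_indices_trip_guard(self, small_trialset):
        with pytest.raises(LeakageError, match="z-score"):
            fit_fold_zscore(small_trialset, np.arange(0, 12), np.arange(10, 20))

    def test_disjoint_indices_fit_train_only(self, small_trialset):
        stats = fit_fold_zscore(small_trialset, np.arange(0, 10),
                                np.arange(10, 20))
        from stcca.preprocessing import zscore_fit

        expected = zscore_fit(small_trialset.subset(np.arange(0, 10)))
        np.testing.assert_array_equal(stats.mean, expected.mean)
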