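import numpy as np
import pytest

from hairpinmi import evaluation as ev
from hairpinmi.evaluation import (
    ConfusionCounts,
    ablation_harness,
    compute_metrics,
    information_gain,
    jackknife,
    kfold,
    pr_auc,
    roc_auc,
)
from hairpinmi.model import HairpinClassifier

from oracles import aupr_all_thresholds, auc_mann_whitney, metrics_direct


FAST_SVM = dict(gamma=0.05, C=10.0)  # small-sample-friendly operating point


def blob_data(n_pos=15, n_neg=15, sep=6.0, d=4, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n_neg, d)), rng.normal(sep, 1, (n_pos, d))])
    y = np.array([0] * n_neg + [1] * n_pos)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


class TestComputeMetrics:
    def test_perfect_classifier(self):
        r = compute_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (r.se, r.sp, r.pr, r.acc, r.f1, r.mcc) == (1, 1, 1, 1, 1, 1)

    def test_hand_derived_mixed_counts(self):
        r = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=2, fn=2))
        assert r.se == pytest.approx(0.6)
        assert r.sp == pytest.approx(2 / 3)
        assert r.pr == pytest.approx(0.75)
        assert r.acc == pytest.approx(0.625)
        assert r.mcc == pytest.approx(4 / np.sqrt(240))

    def test_class_swap_preserves_acc_and_abs_mcc(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 40, size=4)
            if tp + tn + fp + fn == 0:
                continue
            a = compute_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            b = compute_metrics(ConfusionCounts(int(tn), int(tp), int(fn), int(fp)))
            assert a.acc == pytest.approx(b.acc)
            assert abs(a.mcc) == pytest.approx(abs(b.mcc))

    def test_identities_against_direct_formulas(self, rng):
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 50, size=4))
            if tp + tn + fp + fn == 0:
                continue
            r = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
            expected = metrics_direct(tp, tn, fp, fn)
            got = {"SE": r.se, "SP": r.sp, "PR": r.pr, "F1": r.f1, "ACC": r.acc, "MCC": r.mcc}
            for k in expected:
                assert got[k] == pytest.approx(expected[k]), k
            assert -1 <= r.mcc <= 1
            if r.se + r.pr > 0:
                assert r.f1 == pytest.approx(2 * r.se * r.pr / (r.se + r.pr))

    def test_zero_denominator_reports_zero_with_flag(self):
        with pytest.warns(UserWarning, match="zero denominator"):
            r = compute_metrics(ConfusionCounts(tp=0, tn=4, fp=0, fn=0))
        assert r.se == 0.0 and r.pr == 0.0
        assert "SE" in r.undefined_metrics

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestRocAuc:
    def test_perfect_separation(self):
        _, a = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert a == 1.0

    def test_equals_mann_whitney_on_small_inputs(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 21))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            # coarse scores force plenty of ties
            scores = rng.integers(0, 5, size=n).astype(float)
            _, a = roc_auc(scores, labels)
            assert a == pytest.approx(auc_mann_whitney(scores, labels))

    def test_random_scores_near_half(self, rng):
        n = 10000
        labels = rng.integers(0, 2, size=n)
        scores = rng.normal(size=n)
        _, a = roc_auc(scores, labels)
        assert a == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestPrAuc:
    def test_perfect_separation(self):
        _, a = pr_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert a == 1.0

    def test_matches_all_thresholds_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 51))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                continue
            scores = np.round(rng.normal(size=n), 1)
            _, a = pr_auc(scores, labels)
            assert a == pytest.approx(aupr_all_thresholds(list(scores), list(labels)))

    def test_uninformative_scores_approach_prevalence(self, rng):
        n, pi = 4000, 0.2
        labels = (rng.random(n) < pi).astype(int)
        scores = rng.normal(size=n)
        _, a = pr_auc(scores, labels)
        assert a == pytest.approx(labels.mean(), abs=0.05)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0.1, 0.9], [0, 0])


class TestJackknife:
    def test_protocol_has_n_rounds_aggregating_to_n(self):
        X, y = blob_data(5, 5)
        res = jackknife(X, y, estimator=HairpinClassifier(**FAST_SVM))
        assert res.counts.total == 10

    def test_identical_feature_vectors_no_better_than_chance(self):
        # information-free limit: with all feature vectors identical the
        # classifier cannot beat chance (leave-one-out in fact drives ACC
        # to 0 here: each round's majority class is the held-out sample's
        # opposite — the well-known LOO anti-correlation artifact)
        X = np.ones((20, 3))
        y = np.array([0, 1] * 10)
        res = jackknife(X, y, estimator=HairpinClassifier(**FAST_SVM))
        assert res.acc <= 0.5

    def test_separable_data_scores_high(self):
        X, y = blob_data(10, 10, sep=8.0)
        res = jackknife(X, y, estimator=HairpinClassifier(**FAST_SVM))
        assert res.acc >= 0.9

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            jackknife(np.zeros((2, 2)), np.array([0, 1]))


class TestKfold:
    def test_fold_sizes_differ_by_at_most_one(self):
        X, y = blob_data(11, 12, seed=3)
        res = kfold(X, y, k=5, seed=0, estimator=HairpinClassifier(**FAST_SVM))
        sizes = [f.counts.total for f in res.per_fold]
        assert len(sizes) == 5 and max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 23

    def test_deterministic_given_seed(self):
        X, y = blob_data(8, 8, sep=1.0, seed=6)
        a = kfold(X, y, k=4, seed=9, estimator=HairpinClassifier(**FAST_SVM))
        b = kfold(X, y, k=4, seed=9, estimator=HairpinClassifier(**FAST_SVM))
        assert a.as_dict() == b.as_dict()

    def test_k_equal_n_reduces_to_jackknife(self):
        X, y = blob_data(6, 6, sep=8.0, seed=2)
        a = kfold(X, y, k=12, seed=0, estimator=HairpinClassifier(**FAST_SVM))
        b = jackknife(X, y, estimator=HairpinClassifier(**FAST_SVM))
        assert a.as_dict() == b.as_dict()

    def test_k_larger_than_n_rejected(self):
        X, y = blob_data(2, 2)
        with pytest.raises(ValueError):
            kfold(X, y, k=10)


class TestInformationGain:
    def test_label_copy_feature_is_one_bit(self):
        y = np.array([0, 1] * 100)
        X = y.reshape(-1, 1).astype(float)
        [score] = information_gain(X, y, n_bins=2)
        assert score.ig == pytest.approx(1.0)
        assert score.rank == 1

    def test_independent_feature_near_zero(self, rng):
        n = 2000
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 1))
        [score] = information_gain(X, y)
        assert score.ig < 0.02

    def test_ranks_are_a_permutation_descending_in_ig(self, rng):
        X = rng.normal(size=(100, 6))
        y = (X[:, 0] > 0).astype(int)
        scores = information_gain(X, y)
        assert sorted(s.rank for s in scores) == list(range(1, 7))
        igs = [s.ig for s in sorted(scores, key=lambda s: s.rank)]
        assert igs == sorted(igs, reverse=True)
        assert all(s.ig >= -1e-12 for s in scores)

    def test_quantile_bins_invariant_under_monotone_transform(self, rng):
        n = 300
        y = rng.integers(0, 2, size=n)
        x = rng.normal(size=n) + y
        a = information_gain(x.reshape(-1, 1), y, n_bins=5, strategy="quantile")
        b = information_gain(np.exp(x).reshape(-1, 1), y, n_bins=5, strategy="quantile")
        assert a[0].ig == pytest.approx(b[0].ig)

    def test_normalized_top_score_is_one(self, rng):
        X = rng.normal(size=(200, 4))
        y = (X[:, 1] + 0.2 * rng.normal(size=200) > 0).astype(int)
        scores = information_gain(X, y, normalize=True)
        assert max(s.ig for s in scores) == pytest.approx(1.0)

    def test_constant_label_rejected(self):
        with pytest.raises(ValueError):
            information_gain(np.zeros((5, 2)), np.zeros(5))


@pytest.fixture(scope="module")
def benchmark():
    import hairpinmi as hm

    cfg = hm.SyntheticConfig(n_pos=12, n_neg=12, seed=4)
    recs = hm.make_benchmark(cfg)
    X = hm.MutualInformationFeaturizer().fit(recs).transform(recs)
    y = np.array([r.label for r in recs])
    return X, y


class TestAblation:
    def test_four_subset_report_layout(self, benchmark):
        X, y = benchmark
        table = ablation_harness(
            X, y,
            subsets=[("PSFMI",), ("SSFMI",), ("PSFMI", "MFE"), ("SSFMI", "MFE")],
            protocol="kfold", k=4, seed=0,
        )
        assert list(table["features"]) == ["PSFMI", "SSFMI", "PSFMI+MFE", "SSFMI+MFE"]
        assert {"SE", "SP", "ACC", "MCC", "AUC", "AUPR"} <= set(table.columns)
        assert list(table["n_features"]) == [34, 20, 35, 21]

    def test_full_set_beats_mfe_alone(self, benchmark):
        X, y = benchmark
        table = ablation_harness(
            X, y, subsets=[("PSFMI", "SSFMI", "MFE"), ("MFE",)],
            protocol="kfold", k=4, seed=0,
        )
        full, mfe = table.iloc[0], table.iloc[1]
        assert full["ACC"] >= mfe["ACC"]

    def test_deterministic(self, benchmark):
        X, y = benchmark
        kw = dict(subsets=[("SSFMI",)], protocol="kfold", k=4, seed=7)
        assert ablation_harness(X, y, **kw).equals(ablation_harness(X, y, **kw))

    def test_kernel_comparison_rows(self, benchmark):
        X, y = benchmark
        table = ablation_harness(
            X, y, subsets=[("PSFMI", "SSFMI", "MFE")], protocol="kfold", k=4,
            kernels=["linear", "poly", "rbf", "sigmoid"],
        )
        assert list(table["kernel"]) == ["linear", "poly", "rbf", "sigmoid"]

    def test_empty_subset_rejected(self, benchmark):
        X, y = benchmark
        with pytest.raises(ValueError):
            ablation_harness(X, y, subsets=[()])

    def test_unknown_block_rejected(self, benchmark):
        X, y = benchmark
        with pytest.raises(ValueError, match="unknown feature block"):
            ablation_harness(X, y, subsets=[("TRIPLET",)])
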