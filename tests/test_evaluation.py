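"""Metrics and validation procedures against independent oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crsdetect.evaluation import (
    ConfusionMatrix,
    confound_attribution,
    confusion,
    flag_outliers,
    loso,
    rates,
    roc_auc,
    split_dataset,
    split_sizes,
)


def pairwise_auc(scores, labels):
    """Mann-Whitney oracle: P(score_pos > score_neg), ties count 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestSplit:
    def test_study_partition_sizes(self):
        assert split_sizes(1054) == (632, 211, 211)

    def test_exact_division(self):
        assert split_sizes(10) == (6, 2, 2)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            split_sizes(100, (0.5, 0.2, 0.2))

    @given(n=st.integers(3, 2000), seed=st.integers(0, 100))
    def test_partition_is_disjoint_and_exhaustive(self, n, seed):
        parts = split_dataset(n, seed=seed)
        all_idx = np.concatenate(parts)
        assert len(all_idx) == n
        assert len(np.unique(all_idx)) == n  # disjoint
        assert sum(len(p) for p in parts) == n

    @given(seed=st.integers(0, 50))
    def test_stratified_split_preserves_class_proportions(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 4, 400)
        parts = split_dataset(labels, seed=seed)
        for j, part in enumerate(parts):
            for cls in range(4):
                n_cls = (labels == cls).sum()
                got = (labels[part] == cls).sum()
                want = split_sizes(n_cls)[j]
                assert abs(got - want) <= 1

    def test_seeded_and_deterministic(self):
        a = split_dataset(100, seed=4)
        b = split_dataset(100, seed=4)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion([0, 1, 1, 0], [0, 1, 1, 0], ["a", "b"])
        np.testing.assert_array_equal(cm.counts, [[2, 0], [0, 2]])

    def test_all_predicted_positive_half_true(self):
        truth = [1] * 5 + [0] * 5
        pred = [1] * 10
        cm = confusion(truth, pred, ["neg", "pos"])
        tp, fp, fn, tn = cm.binary_cells("pos")
        assert tp == fp == 5 and fn == tn == 0

    def test_16_class_shape(self):
        rng = np.random.default_rng(0)
        names = [f"g{i}" for i in range(16)]
        cm = confusion(rng.integers(0, 16, 200), rng.integers(0, 16, 200), names)
        assert cm.counts.shape == (16, 16)
        assert cm.n == 200

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0], ["a", "b"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(np.array([[1, -1], [0, 2]]), ("a", "b"))


class TestRates:
    def test_hand_arithmetic_toy_matrix(self):
        # TP=9, FN=1, FP=1, TN=9 → TPR=0.9, FPR=0.1, F1=0.9
        cm = ConfusionMatrix(np.array([[9, 1], [1, 9]]), ("neg", "pos"))
        # rows = true; positive class row is index 1: TP=cm[1,1]=9, FN=cm[1,0]=1
        r = rates(cm, "pos")
        assert r["tpr"] == pytest.approx(0.9)
        assert r["fpr"] == pytest.approx(0.1)
        assert r["f1"] == pytest.approx(0.9)

    def test_perfect_classifier(self):
        cm = ConfusionMatrix(np.array([[10, 0], [0, 10]]), ("neg", "pos"))
        r = rates(cm, "pos")
        assert r["f1"] == 1.0 and r["fpr"] == 0.0

    def test_zero_denominator_convention(self):
        # nothing predicted positive, nothing is positive → precision=0, F1=0
        cm = ConfusionMatrix(np.array([[10, 0], [0, 0]]), ("neg", "pos"))
        r = rates(cm, "pos")
        assert r["precision"] == 0.0 and r["f1"] == 0.0

    def test_f1_monotone_in_tp(self):
        def f1_of(tp):
            cm = ConfusionMatrix(np.array([[50, 5], [3, tp]]), ("neg", "pos"))
            return rates(cm, "pos")["f1"]

        values = [f1_of(tp) for tp in (1, 5, 20, 80)]
        assert values == sorted(values)

    def test_one_vs_rest_reduction_16_class(self):
        counts = np.zeros((16, 16), dtype=int)
        counts[np.arange(16), np.arange(16)] = 10
        counts[3, 7] = 2  # class 3 sometimes predicted as 7
        cm = ConfusionMatrix(counts, tuple(f"g{i}" for i in range(16)))
        r = rates(cm, "g7")
        assert r["tpr"] == 1.0
        assert r["precision"] == pytest.approx(10 / 12)


class TestRocAuc:
    def test_perfectly_separated_scores(self):
        roc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(1.0)

    def test_all_scores_equal_gives_half(self):
        roc = roc_auc([0.5] * 8, [1, 0] * 4)
        assert roc.auc == pytest.approx(0.5)

    def test_endpoints_and_monotone_fpr(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        roc = roc_auc(scores, labels)
        np.testing.assert_allclose(roc.points[0], [0, 0])
        np.testing.assert_allclose(roc.points[-1], [1, 1])
        assert (np.diff(roc.points[:, 0]) >= 0).all()

    def test_hand_listed_pairs_match_pairwise_oracle(self):
        scores = [0.9, 0.7, 0.7, 0.4, 0.3, 0.1]
        labels = [1, 1, 0, 1, 0, 0]
        roc = roc_auc(scores, labels)
        assert roc.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-10)

    @given(seed=st.integers(0, 200), n=st.integers(4, 300))
    def test_trapezoid_equals_mann_whitney(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n)  # force ties
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        roc = roc_auc(scores, labels)
        assert roc.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-10)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class _RecordingClassifier:
    """Spy: remembers training rows, predicts the majority training label."""

    def __init__(self, log):
        self.log = log

    def fit(self, x, y):
        self.log.append(x.copy())
        self.majority = int(np.bincount(y).argmax())
        return self

    def predict(self, x):
        return np.full(len(x), self.majority)


class TestLoso:
    def _toy(self):
        # feature value encodes the participant index
        pids = np.repeat([f"P{i}" for i in range(4)], 10)
        x = np.repeat(np.arange(4), 10).astype(float)[:, None]
        y = np.tile([0, 1], 20)
        return x, y, pids

    def test_fold_structure_and_no_leakage(self):
        x, y, pids = self._toy()
        log = []
        report = loso(x, y, pids, model_factory=lambda: _RecordingClassifier(log))
        assert len(report.per_participant_accuracy) == 4
        assert len(log) == 4  # one fold per participant
        for fold, pid in enumerate(["P0", "P1", "P2", "P3"]):
            held_out_value = float(pid[1])
            assert held_out_value not in log[fold][:, 0]

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            loso(np.zeros((5, 1)), [0, 1, 0, 1, 0], ["A"] * 5, model_factory=object)

    def test_high_noise_participant_flagged_as_outlier(self):
        # cohort where one participant's features are pure noise: the
        # nearest-centroid fold for that participant collapses to chance
        from sklearn.neighbors import NearestCentroid

        rng = np.random.default_rng(0)
        xs, ys, ps = [], [], []
        for i in range(6):
            y = np.tile([0, 1], 15)
            mean = np.where(y[:, None] == 1, 3.0, -3.0)
            noise_sd = 40.0 if i == 5 else 0.5
            xs.append(mean + rng.normal(0, noise_sd, (30, 1)))
            ys.append(y)
            ps.extend([f"P{i}"] * 30)
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        report = loso(x, y, ps, model_factory=NearestCentroid)
        worst = min(report.per_participant_accuracy, key=report.per_participant_accuracy.get)
        assert worst == "P5"
        assert "P5" in report.outliers


class TestOutliers:
    def test_mean_pm_one_sd_rule(self):
        accs = {"a": 0.9, "b": 0.9, "c": 0.9, "d": 0.5}
        # mean 0.8, sample SD 0.2 → only d (< 0.6) is outside mean ± 1 SD
        assert flag_outliers(accs) == ("d",)

    def test_constant_vector_has_no_outliers(self):
        assert flag_outliers({"a": 0.8, "b": 0.8, "c": 0.8}) == ()

    def test_symmetric_extremes_both_flagged(self):
        accs = {"lo": 0.70, "m1": 0.86, "m2": 0.86, "m3": 0.86, "hi": 0.99}
        vals = np.array(list(accs.values()))
        mean, sd = vals.mean(), vals.std(ddof=1)
        expected = tuple(k for k, v in accs.items() if v > mean + sd or v < mean - sd)
        assert flag_outliers(accs) == expected


class TestConfoundAttribution:
    def test_diagonal_matrix_all_zero_rates(self):
        counts = np.diag([5] * 16)
        cm = ConfusionMatrix(counts, tuple(f"g{i}" for i in range(15)) + ("smoking",))
        table = confound_attribution(cm, "smoking")
        assert all(
            v["predicted_as_smoking"] == 0 and v["smoking_predicted_as"] == 0
            for v in table.values()
        )

    def test_hand_built_toy_matrix(self):
        counts = np.array([[8, 1, 1], [0, 9, 1], [2, 0, 8]])
        cm = ConfusionMatrix(counts, ("eat", "drink", "smoking"))
        table = confound_attribution(cm, "smoking")
        assert table["eat"]["predicted_as_smoking"] == pytest.approx(1 / 10)
        assert table["drink"]["predicted_as_smoking"] == pytest.approx(1 / 10)
        assert table["eat"]["smoking_predicted_as"] == pytest.approx(2 / 10)
        assert table["drink"]["smoking_predicted_as"] == pytest.approx(0.0)

    def test_rates_lie_in_unit_interval(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 20, (16, 16))
        cm = ConfusionMatrix(counts, tuple(f"g{i}" for i in range(15)) + ("smoking",))
        for v in confound_attribution(cm, "smoking").values():
            assert 0.0 <= v["predicted_as_smoking"] <= 1.0
            assert 0.0 <= v["smoking_predicted_as"] <= 1.0
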