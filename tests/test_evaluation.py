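"""Balanced accuracy, recall, paired comparisons, learning curves."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import balanced_accuracy_score

from kafohar.evaluation import (
    ConfusionMatrix,
    absent_classes,
    balanced_accuracy,
    compare_models,
    confusion,
    learning_curve,
    recall_per_class,
    wilcoxon_signed_rank,
)
from kafohar.io import ACTIVITIES, ValidationError


def _cm(counts, classes=("sit", "stand")):
    return ConfusionMatrix(tuple(classes), np.asarray(counts))


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = np.repeat(ACTIVITIES, 4)
        cm = confusion(y, y)
        assert np.all(cm.counts == np.diag([4] * 5))

    def test_constant_predictor_fills_one_column(self):
        y = np.repeat(ACTIVITIES, 3)
        cm = confusion(y, ["walk"] * len(y))
        col = list(ACTIVITIES).index("walk")
        assert cm.counts[:, col].sum() == len(y)
        assert cm.counts.sum() == cm.counts[:, col].sum()

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(4)
        y_true = rng.choice(ACTIVITIES, size=200)
        y_pred = rng.choice(ACTIVITIES, size=200)
        cm = confusion(y_true, y_pred)
        for i, ci in enumerate(ACTIVITIES):
            for j, cj in enumerate(ACTIVITIES):
                assert cm.counts[i, j] == sum(
                    1 for t, p in zip(y_true, y_pred) if t == ci and p == cj
                )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError, match="jog"):
            confusion(["sit"], ["jog"])


class TestRecallAndBalancedAccuracy:
    def test_diagonal_matrix_has_unit_recalls(self):
        cm = _cm(np.diag([3, 5, 7, 2, 4]), ACTIVITIES)
        assert all(v == 1.0 for v in recall_per_class(cm).values())
        assert balanced_accuracy(cm) == 1.0

    def test_two_class_hand_example(self):
        # recalls 9/10 and 5/10 -> balanced accuracy (0.9 + 0.5) / 2
        assert balanced_accuracy(_cm([[9, 1], [5, 5]])) == pytest.approx(0.7)

    def test_replication_invariance_is_exact(self):
        counts = np.array([[9, 1], [5, 5]])
        replicated = counts.copy()
        replicated[0] *= 10  # duplicate every row of the first class 10x
        assert balanced_accuracy(_cm(counts)) == balanced_accuracy(_cm(replicated))

    def test_equals_plain_accuracy_when_balanced(self):
        rng = np.random.default_rng(9)
        y_true = np.repeat(ACTIVITIES, 20)
        y_pred = rng.choice(ACTIVITIES, size=y_true.size)
        cm = confusion(y_true, y_pred)
        assert balanced_accuracy(cm) == pytest.approx(np.mean(y_true == y_pred))

    def test_brute_force_oracle_and_sklearn_cross_check(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            y_true = rng.choice(ACTIVITIES, size=120)
            y_pred = rng.choice(ACTIVITIES, size=120)
            cm = confusion(y_true, y_pred)
            recalls = [
                np.mean(y_pred[y_true == c] == c) for c in ACTIVITIES if np.any(y_true == c)
            ]
            assert balanced_accuracy(cm) == pytest.approx(np.mean(recalls))
            assert balanced_accuracy(cm) == pytest.approx(
                balanced_accuracy_score(y_true, y_pred)
            )

    def test_absent_class_flagged_not_nan(self):
        counts = np.diag([3, 5, 7, 2, 4])
        counts[1] = 0  # no standing windows in the test set
        cm = _cm(counts, ACTIVITIES)
        assert absent_classes(cm) == ["stand"]
        assert "stand" not in recall_per_class(cm)
        assert balanced_accuracy(cm) == 1.0

    def test_all_absent_rejected(self):
        with pytest.raises(ValidationError):
            balanced_accuracy(_cm(np.zeros((5, 5)), ACTIVITIES))


class TestWilcoxon:
    def test_identical_scores_are_degenerate(self):
        res = wilcoxon_signed_rank([0.5] * 8, [0.5] * 8)
        assert res["p_value"] == 1.0 and res["n"] == 0

    def test_uniform_shift_reaches_smallest_exact_p(self):
        a = np.linspace(0.4, 0.9, 11)
        res = wilcoxon_signed_rank(a, a + 0.2)
        # all 11 differences positive: two-sided p = 2 / 2^11
        assert res["method"] == "exact"
        assert res["p_value"] == pytest.approx(2 / 2**11)

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_matches_enumerated_null(self, n):
        """Exact p equals enumeration of all 2^n sign assignments."""
        rng = np.random.default_rng(n)
        d = rng.normal(0.1, 1.0, size=n)
        while len(np.unique(np.abs(d))) < n or np.any(d == 0):
            d = rng.normal(0.1, 1.0, size=n)
        res = wilcoxon_signed_rank(np.zeros(n), d)
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_obs = ranks[d > 0].sum()
        w_all = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)
        ]
        total = 2**n
        p_two = min(
            1.0,
            2
            * min(
                sum(w >= w_obs for w in w_all) / total,
                sum(w <= w_obs for w in w_all) / total,
            ),
        )
        assert res["method"] == "exact"
        assert res["p_value"] == pytest.approx(p_two)


class TestCompareModels:
    def _scores(self):
        rng = np.random.default_rng(5)
        subjects = [f"P{i:02d}" for i in range(1, 12)]
        base = dict(zip(subjects, rng.uniform(0.4, 0.6, size=11)))
        # distinct positive per-subject gains so consecutive differences are
        # all positive and untied (exact signed-rank null applies)
        gain = dict(zip(subjects, rng.uniform(0.02, 0.06, size=11)))
        out = {}
        for k, scheme in enumerate(
            ["healthy", "impairment_specific", "device_specific", "patient_device_specific"]
        ):
            out[scheme] = {s: base[s] + k * gain[s] for s in subjects}
        return out

    def test_sequential_tests_follow_specificity_order(self):
        report = compare_models(self._scores())
        pairs = [(t["less_specific"], t["more_specific"]) for t in report["tests"]]
        assert pairs == [
            ("healthy", "impairment_specific"),
            ("impairment_specific", "device_specific"),
            ("device_specific", "patient_device_specific"),
        ]
        assert all(t["p_value"] == pytest.approx(2 / 2**11) for t in report["tests"])
        assert all(t["significant"] for t in report["tests"])

    def test_medians_and_iqr_reported(self):
        report = compare_models(self._scores())
        meds = [report["schemes"][s]["median"] for s in report["schemes"]]
        assert meds == sorted(meds)
        for row in report["schemes"].values():
            assert row["iqr"][0] <= row["median"] <= row["iqr"][1]
            assert row["shapiro_p"] is None or 0 <= row["shapiro_p"] <= 1

    def test_unpaired_subjects_rejected(self):
        scores = self._scores()
        del scores["healthy"]["P05"]
        with pytest.raises(ValidationError, match="P05"):
            compare_models(scores)


class TestLearningCurve:
    def test_max_n_is_pool_minus_test_patient(self, tiny_dataset):
        # 2 patients: the patient-trained families can use at most 1 trainer
        lc = learning_curve(
            tiny_dataset, "device_specific", n_iterations=2, n_bootstrap=20, seed=0
        )
        assert lc.n_subjects == (1,)
        with pytest.raises(ValidationError, match="exceeds"):
            learning_curve(
                tiny_dataset, "device_specific", n_iterations=2, n_bootstrap=20, seed=0, n_values=(2,)
            )

    def test_healthy_pool_does_not_exclude_test_patient(self, tiny_dataset):
        lc = learning_curve(tiny_dataset, "healthy", n_iterations=2, n_bootstrap=20, seed=0)
        assert max(lc.n_subjects) == 2  # both healthy subjects usable

    def test_single_iteration_gives_degenerate_ci(self, tiny_dataset):
        lc = learning_curve(
            tiny_dataset, "impairment_specific", n_iterations=1, n_bootstrap=30, seed=3
        )
        for lo, med, hi in zip(lc.ci_low, lc.median, lc.ci_high):
            assert lo == med == hi

    def test_seed_determinism(self, tiny_dataset):
        kw = dict(n_iterations=3, n_bootstrap=25, seed=42)
        a = learning_curve(tiny_dataset, "device_specific", **kw)
        b = learning_curve(tiny_dataset, "device_specific", **kw)
        assert a == b
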