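"""Evaluation: confusion matrices, balanced accuracy, paired comparisons,
and learning curves over training-subject count.

Balanced accuracy is the mean per-class recall,

    BA = (1/C) * sum_i TP_i / n_i,

with C the number of activity classes present in the test set, TP_i the
true positives for class i and n_i its test count. Averaging over *present*
classes keeps the metric defined for patients who could not perform the
stairs activities; absent classes are flagged in the result rather than
contributing NaN. The metric is invariant to replicating any class's rows,
which is why it is preferred over plain accuracy under the strong
walking-vs-stairs class imbalance of the protocol.

Scheme comparisons follow the study design: per-scheme medians and IQRs, a
Shapiro-Wilk normality note, and sequential two-sided Wilcoxon signed-rank
tests between each scheme and the next more specific one at alpha = 0.05
(no multiplicity correction — four separate tests by design). Zero
differences are discarded; the exact null distribution is used for n <= 12
without ties, the normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .io import ACTIVITIES, ValidationError
from .modeling import (
    DEFAULT_N_TREES,
    ClassifierSpec,
    SchemeSpec,
    WindowDataset,
    predict,
    scheme_folds,
    train,
)

SPECIFICITY_ORDER: tuple[str, ...] = (
    "healthy",
    "impairment_specific",
    "device_specific",
    "patient_specific",
    "patient_device_specific",
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C tally, rows = true class, columns = predicted class."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = len(self.classes)
        counts = np.asarray(self.counts)
        if counts.shape != (c, c) or np.any(counts < 0):
            raise ValidationError(f"counts must be non-negative {c}x{c}, got {counts.shape}")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_per_class(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def true_positives(self) -> np.ndarray:
        return np.diag(self.counts)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValidationError("cannot pool confusion matrices over different classes")
        return ConfusionMatrix(self.classes, self.counts + other.counts)


def confusion(y_true, y_pred, classes: tuple[str, ...] = ACTIVITIES) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("true and predicted label sequences differ in length")
    unknown = (set(y_true) | set(y_pred)) - set(classes)
    if unknown:
        raise ValidationError(f"labels outside class set: {sorted(unknown)}")
    counts = _sk_confusion(y_true, y_pred, labels=list(classes))
    return ConfusionMatrix(tuple(classes), counts)


def recall_per_class(cm: ConfusionMatrix) -> dict[str, float]:
    """Recall TP_i / n_i for every class present in the test set (n_i > 0)."""
    out: dict[str, float] = {}
    for cls, tp, n in zip(cm.classes, cm.true_positives, cm.n_per_class):
        if n > 0:
            out[cls] = float(tp) / float(n)
    return out


def absent_classes(cm: ConfusionMatrix) -> list[str]:
    return [cls for cls, n in zip(cm.classes, cm.n_per_class) if n == 0]


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean recall over the classes present in the test set."""
    recalls = recall_per_class(cm)
    if not recalls:
        raise ValidationError("no class has test samples; balanced accuracy undefined")
    return float(np.mean(list(recalls.values())))


@dataclass(frozen=True)
class EvalResult:
    confusion: ConfusionMatrix
    per_class_recall: dict[str, float]
    balanced_accuracy: float
    absent: list[str] = field(default_factory=list)
    scheme: str | None = None
    test_subject: str | None = None


def evaluate_predictions(
    y_true, y_pred, *, scheme: str | None = None, test_subject: str | None = None
) -> EvalResult:
    cm = confusion(y_true, y_pred)
    return EvalResult(
        confusion=cm,
        per_class_recall=recall_per_class(cm),
        balanced_accuracy=balanced_accuracy(cm),
        absent=absent_classes(cm),
        scheme=scheme,
        test_subject=test_subject,
    )


def evaluate_scheme(
    dataset: WindowDataset,
    scheme: str,
    test_subject: str,
    *,
    n_trees: int | None = None,
    rng_seed: int = 0,
) -> tuple[float, ConfusionMatrix]:
    """Per-patient balanced accuracy for one scheme (mean over session folds
    for the leave-one-session-out personal scheme) plus the pooled confusion."""
    n_trees = DEFAULT_N_TREES[scheme] if n_trees is None else n_trees
    folds = scheme_folds(scheme, dataset, test_subject)
    scores = []
    pooled: ConfusionMatrix | None = None
    for k, fold in enumerate(folds):
        model = train(
            dataset.X[fold.train_idx],
            dataset.y[fold.train_idx],
            ClassifierSpec(n_trees=n_trees, rng_seed=rng_seed + k),
            scheme_name=scheme,
        )
        y_pred = predict(model, dataset.X[fold.test_idx])
        cm = confusion(dataset.y[fold.test_idx], y_pred)
        scores.append(balanced_accuracy(cm))
        pooled = cm if pooled is None else pooled + cm
    return float(np.mean(scores)), pooled


# ---------------------------------------------------------------------------
# paired comparisons


def _exact_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p for the signed-rank statistic of nonzero ``d``.

    Enumerates all 2^n sign assignments of the midranked |differences|, so it
    stays exact under ties. Returns (W+, p)."""
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    n = d.size
    signs = np.arange(2**n)[:, None] >> np.arange(n) & 1  # all sign patterns
    w_all = signs @ ranks
    p_hi = np.count_nonzero(w_all >= w_obs - 1e-12) / 2**n
    p_lo = np.count_nonzero(w_all <= w_obs + 1e-12) / 2**n
    return w_obs, min(1.0, 2.0 * min(p_lo, p_hi))


def wilcoxon_signed_rank(a, b) -> dict:
    """Two-sided paired signed-rank test of b - a with documented zero handling.

    Zero differences are discarded; with no remaining differences the test is
    degenerate (statistic 0, p = 1). For n <= 12 the exact null is enumerated
    (midranks under ties); larger n uses the normal approximation.
    """
    d = np.asarray(b, float) - np.asarray(a, float)
    if d.size != np.asarray(a).size:
        raise ValidationError("paired samples differ in length")
    d = d[d != 0.0]
    if d.size == 0:
        return {"n": 0, "statistic": 0.0, "p_value": 1.0, "method": "degenerate"}
    if d.size <= 12:
        w_obs, p = _exact_signed_rank_p(d)
        return {"n": int(d.size), "statistic": w_obs, "p_value": float(p), "method": "exact"}
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="approx")
    return {
        "n": int(d.size),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": "approx",
    }


def compare_models(
    per_patient_scores: dict[str, dict[str, float]],
    alpha: float = 0.05,
    order: tuple[str, ...] = SPECIFICITY_ORDER,
) -> dict:
    """Sequential paired comparisons along the specificity order.

    ``per_patient_scores`` maps scheme -> {subject: balanced accuracy}. All
    schemes must share the same subject ids (pairing).
    """
    present = [s for s in order if s in per_patient_scores]
    if len(present) < 2:
        raise ValidationError("need at least two schemes to compare")
    subject_sets = {s: set(per_patient_scores[s]) for s in present}
    common = set.intersection(*subject_sets.values())
    missing = {
        s: sorted(subject_sets[s] ^ common) for s in present if subject_sets[s] != common
    }
    if missing:
        raise ValidationError(f"unpaired subjects per scheme: {missing}")
    subjects = sorted(common)
    summary = {}
    for s in present:
        vals = np.array([per_patient_scores[s][subj] for subj in subjects])
        sw = stats.shapiro(vals) if len(vals) >= 3 and np.ptp(vals) > 0 else None
        q75, q25 = np.percentile(vals, [75, 25])
        summary[s] = {
            "median": float(np.median(vals)),
            "iqr": [float(q25), float(q75)],
            "shapiro_p": float(sw.pvalue) if sw else None,
        }
    tests = []
    for less, more in zip(present, present[1:]):
        a = [per_patient_scores[less][subj] for subj in subjects]
        b = [per_patient_scores[more][subj] for subj in subjects]
        t = wilcoxon_signed_rank(a, b)
        t.update(
            {
                "less_specific": less,
                "more_specific": more,
                "significant": bool(t["p_value"] < alpha),
            }
        )
        tests.append(t)
    return {"subjects": subjects, "alpha": alpha, "schemes": summary, "tests": tests}


# ---------------------------------------------------------------------------
# learning curves


@dataclass(frozen=True)
class LearningCurve:
    """Median balanced accuracy (with bootstrap CI of the median) vs the
    number of training subjects."""

    scheme_family: str
    n_subjects: tuple[int, ...]
    median: tuple[float, ...]
    ci_low: tuple[float, ...]
    ci_high: tuple[float, ...]
    bootstrap_mean_of_medians: tuple[float, ...]
    n_iterations: int
    n_bootstrap: int

    def __post_init__(self) -> None:
        for lo, med, hi in zip(self.ci_low, self.median, self.ci_high):
            if not (lo <= med + 1e-12 and med <= hi + 1e-12):
                raise ValidationError("learning-curve CI must bracket the median")


def learning_curve(
    dataset: WindowDataset,
    scheme_family: str,
    *,
    n_iterations: int = 1000,
    n_bootstrap: int = 1000,
    seed: int = 0,
    n_values: tuple[int, ...] | None = None,
    n_trees: int | None = None,
) -> LearningCurve:
    """Balanced accuracy as a function of the number of training subjects.

    For each n, ``n_iterations`` random draws each pick one test patient and
    n training subjects (healthy subjects for the ``healthy`` family; the
    *other* patients' control- or novel-device data for the two patient-
    trained families, so the maximum n is one less than the patient count).
    The point estimate is the median over iterations; the CI is the
    percentile bootstrap of the median.
    """
    if scheme_family not in ("healthy", "impairment_specific", "device_specific"):
        raise ValidationError(f"no learning curve for scheme {scheme_family!r}")
    m = dataset.meta
    patients = dataset.patients()
    if scheme_family == "healthy":
        pool = sorted(set(m.loc[m.group == "healthy", "subject_id"]))
        train_device = "none"
        excludes_test = False
    else:
        pool = sorted(patients)
        train_device = "control" if scheme_family == "impairment_specific" else "novel"
        excludes_test = True
    max_n = len(pool) - (1 if excludes_test else 0)
    if max_n < 1 or len(patients) < 1:
        raise ValidationError("not enough subjects for a learning curve")
    if n_values is None:
        n_values = tuple(range(1, max_n + 1))
    if max(n_values) > max_n:
        raise ValidationError(f"n={max(n_values)} exceeds the {max_n} available training subjects")
    n_trees = DEFAULT_N_TREES[scheme_family] if n_trees is None else n_trees
    rng = np.random.default_rng(np.random.SeedSequence((seed, 404)))
    subj_col = m.subject_id.to_numpy()
    device_col = m.device.to_numpy()
    medians, lows, highs, boot_means = [], [], [], []
    for n in n_values:
        scores = np.empty(n_iterations)
        for it in range(n_iterations):
            test_patient = patients[rng.integers(len(patients))]
            candidates = [s for s in pool if not excludes_test or s != test_patient]
            chosen = rng.choice(candidates, size=n, replace=False)
            train_mask = np.isin(subj_col, chosen) & (device_col == train_device)
            test_mask = (subj_col == test_patient) & (device_col == "novel")
            model = train(
                dataset.X[train_mask],
                dataset.y[train_mask],
                ClassifierSpec(n_trees=n_trees, rng_seed=int(rng.integers(2**31 - 1))),
            )
            cm = confusion(dataset.y[test_mask], predict(model, dataset.X[test_mask]))
            scores[it] = balanced_accuracy(cm)
        boot = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            boot[b] = np.median(rng.choice(scores, size=scores.size, replace=True))
        med = float(np.median(scores))
        lo, hi = np.percentile(boot, [2.5, 97.5])
        medians.append(med)
        lows.append(float(min(lo, med)))
        highs.append(float(max(hi, med)))
        boot_means.append(float(boot.mean()))
    return LearningCurve(
        scheme_family=scheme_family,
        n_subjects=tuple(int(n) for n in n_values),
        median=tuple(medians),
        ci_low=tuple(lows),
        ci_high=tuple(highs),
        bootstrap_mean_of_medians=tuple(boot_means),
        n_iterations=n_iterations,
        n_bootstrap=n_bootstrap,
    )
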