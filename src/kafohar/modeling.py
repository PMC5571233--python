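"""Random-forest activity classifiers and the five train/test schemes.

The five schemes, in increasing specificity to the tested patient's novel
orthosis (the test set is always that patient's novel-device windows):

* ``healthy`` — trained on all healthy subjects' (no-device) windows.
* ``impairment_specific`` — trained on the *other* patients' control-device
  windows.
* ``device_specific`` — trained on the other patients' novel-device windows.
* ``patient_specific`` — trained on the test patient's own control-device
  windows (personal model, wrong device).
* ``patient_device_specific`` — leave-one-session-out within the test
  patient's own novel-device data; per-patient score is the mean over
  session folds.

Tree counts default to 10 for the healthy scheme and 50 for all others (the
values tuned for balanced accuracy in the emulated study); other forest
hyperparameters stay at library-independent defaults (sqrt(p) features per
split, unlimited depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io import ACTIVITIES, ValidationError
from .features import N_FEATURES, REGISTRY_VERSION

SCHEMES: tuple[str, ...] = (
    "healthy",
    "impairment_specific",
    "device_specific",
    "patient_specific",
    "patient_device_specific",
)
GLOBAL_SCHEMES = ("healthy", "impairment_specific", "device_specific")
DEFAULT_N_TREES = {
    "healthy": 10,
    "impairment_specific": 50,
    "device_specific": 50,
    "patient_specific": 50,
    "patient_device_specific": 50,
}


@dataclass(frozen=True)
class ClassifierSpec:
    n_trees: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    classes: tuple[str, ...]
    registry_version: str = REGISTRY_VERSION
    scheme_name: str | None = None


@dataclass(frozen=True)
class SchemeSpec:
    """One materialized train/test split over a featurized window dataset."""

    name: str
    test_subject: str
    train_idx: np.ndarray  # boolean mask over dataset rows
    test_idx: np.ndarray
    held_out_session: str | None = None

    def __post_init__(self) -> None:
        if bool(np.any(self.train_idx & self.test_idx)):
            raise ValidationError(f"{self.name}: train and test rows overlap")


@dataclass
class WindowDataset:
    """Featurized windows: X (n, 131), labels y, and provenance meta."""

    X: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.y), N_FEATURES):
            raise ValidationError(
                f"X must be (n, {N_FEATURES}); got {self.X.shape} for {len(self.y)} labels"
            )

    @classmethod
    def from_cohort(cls, cohort, window_s: float = 6.0, overlap: float = 0.75) -> "WindowDataset":
        from .features import feature_matrix
        from .windowing import window_dataset

        X, y, meta = feature_matrix(window_dataset(cohort, window_s=window_s, overlap=overlap))
        return cls(X, y, meta)

    def patients(self) -> list[str]:
        m = self.meta
        return list(dict.fromkeys(m.loc[m.group == "patient", "subject_id"]))

    def sessions(self, subject: str, device: str) -> list[str]:
        m = self.meta
        sel = (m.subject_id == subject) & (m.device == device)
        return sorted(set(m.loc[sel, "session_id"]))


def train(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    scheme_name: str | None = None,
) -> TrainedModel:
    """Fit a random forest; deterministic given ``spec.rng_seed``."""
    X = np.asarray(X)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValidationError(f"expected (n, {N_FEATURES}) features, got {X.shape}")
    if len(y) != X.shape[0]:
        raise ValidationError("feature rows and labels differ in length")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValidationError(
            f"training set has a single class {classes}; balanced accuracy undefined"
        )
    unknown = set(classes) - set(ACTIVITIES)
    if unknown:
        raise ValidationError(f"unknown activity labels {sorted(unknown)}")
    forest = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features="sqrt",
        random_state=spec.rng_seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return TrainedModel(forest=forest, classes=tuple(classes), scheme_name=scheme_name)


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Predict one activity per feature row; validates width and registry."""
    X = np.asarray(X)
    if X.size == 0:
        return np.array([], dtype=object)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValidationError(f"expected {N_FEATURES} features per row, got {X.shape[1]}")
    if model.registry_version != REGISTRY_VERSION:
        raise ValidationError(
            f"feature registry mismatch: model {model.registry_version}, "
            f"current {REGISTRY_VERSION}"
        )
    return model.forest.predict(X)


def build_scheme(
    name: str,
    dataset: WindowDataset,
    test_subject: str,
    held_out_session: str | None = None,
) -> SchemeSpec:
    """Materialize one scheme's train/test masks for one test patient.

    For ``patient_device_specific`` a ``held_out_session`` id is required;
    call once per session and average (see :func:`scheme_folds`).
    """
    if name not in SCHEMES:
        raise ValidationError(f"unknown scheme {name!r}")
    m = dataset.meta
    is_subject = (m.subject_id == test_subject).to_numpy()
    is_patient = (m.group == "patient").to_numpy()
    novel = (m.device == "novel").to_numpy()
    control = (m.device == "control").to_numpy()
    if not np.any(is_subject & is_patient & novel):
        raise ValidationError(f"{test_subject!r} is not a patient with novel-device windows")
    test_idx = is_subject & novel
    if name == "healthy":
        train_idx = (m.group == "healthy").to_numpy()
    elif name == "impairment_specific":
        train_idx = is_patient & control & ~is_subject
    elif name == "device_specific":
        train_idx = is_patient & novel & ~is_subject
    elif name == "patient_specific":
        train_idx = is_subject & control
    else:  # patient_device_specific
        if held_out_session is None:
            raise ValidationError("patient_device_specific requires held_out_session")
        in_session = (m.session_id == held_out_session).to_numpy()
        train_idx = is_subject & novel & ~in_session
        test_idx = is_subject & novel & in_session
    if name in GLOBAL_SCHEMES:
        assert not np.any(train_idx & is_subject), "test subject leaked into global training"
    if not train_idx.any():
        raise ValidationError(f"{name}: empty training selection for {test_subject}")
    if not test_idx.any():
        raise ValidationError(f"{name}: empty test selection for {test_subject}")
    return SchemeSpec(name, test_subject, train_idx, test_idx, held_out_session)


def scheme_folds(name: str, dataset: WindowDataset, test_subject: str) -> list[SchemeSpec]:
    """All folds for a scheme: one for most, one per session for the personal
    device-specific leave-one-session-out scheme."""
    if name == "patient_device_specific":
        sessions = dataset.sessions(test_subject, "novel")
        if len(sessions) < 2:
            raise ValidationError(
                f"{test_subject} needs >= 2 novel-device sessions for leave-one-session-out"
            )
        return [build_scheme(name, dataset, test_subject, held_out_session=s) for s in sessions]
    return [build_scheme(name, dataset, test_subject)]


def tune_n_trees(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    grid: tuple[int, ...] = (10, 25, 50, 100),
    rng_seed: int = 0,
) -> int:
    """Pick the tree count maximizing leave-one-group-out balanced accuracy.

    Re-exposes the study's tuning step over an explicit grid; ``groups``
    is typically the subject id per row.
    """
    from .evaluation import balanced_accuracy, confusion

    best, best_score = grid[0], -1.0
    unique_groups = list(dict.fromkeys(groups))
    for n_trees in grid:
        scores = []
        for g in unique_groups:
            mask = groups == g
            if len(set(y[~mask])) < 2 or not mask.any():
                continue
            model = train(X[~mask], y[~mask], ClassifierSpec(n_trees, rng_seed))
            cm = confusion(y[mask], predict(model, X[mask]), classes=ACTIVITIES)
            scores.append(balanced_accuracy(cm))
        score = float(np.mean(scores)) if scores else -1.0
        if score > best_score:
            best, best_score = n_trees, score
    return best
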