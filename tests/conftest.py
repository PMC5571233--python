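import numpy as np
import pandas as pd
import pytest

from kafohar.features import N_FEATURES
from kafohar.io import ACTIVITIES
from kafohar.modeling import WindowDataset
from kafohar.synth import CohortSpec, sample_cohort

TINY_DURATIONS = {
    "sit": 30.0,
    "stand": 30.0,
    "walk": 36.0,
    "stairs_up": 9.0,
    "stairs_down": 9.0,
}


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small but fully structured cohort: 2 healthy + 2 patients, 2 sessions."""
    spec = CohortSpec(
        n_healthy=2,
        n_patients=2,
        sessions_per_condition=2,
        durations_s=TINY_DURATIONS,
        seed=7,
    )
    return sample_cohort(spec)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cohort):
    return WindowDataset.from_cohort(tiny_cohort)


@pytest.fixture(scope="session")
def cohort22_dataset():
    """Featurized full-size cohort (11 healthy + 11 patients, 3 sessions) with
    zero subject/device effects: every subject shares the same generative
    parameters, so activities are recoverable up to sensor noise."""
    spec = CohortSpec(seed=11, delta_subject=0.0, delta_device=0.0)
    return WindowDataset.from_cohort(sample_cohort(spec))


@pytest.fixture
def fake_dataset():
    """Factory for a provenance-only dataset (random features) used to test
    scheme construction without synthesizing signals."""

    def make(
        n_healthy=2,
        n_patients=3,
        sessions=3,
        windows_per_session=5,
        seed=0,
    ) -> WindowDataset:
        rng = np.random.default_rng(seed)
        rows = []
        for h in range(n_healthy):
            for s in range(sessions):
                rows += [(f"H{h + 1:02d}", "healthy", "none", f"S{s + 1}")] * windows_per_session
        for p in range(n_patients):
            for device in ("control", "novel"):
                for s in range(sessions):
                    rows += [
                        (f"P{p + 1:02d}", "patient", device, f"S{s + 1}")
                    ] * windows_per_session
        meta = pd.DataFrame(rows, columns=["subject_id", "group", "device", "session_id"])
        meta["start_s"] = np.tile(
            np.arange(windows_per_session, dtype=float), len(rows) // windows_per_session
        )
        X = rng.normal(size=(len(rows), N_FEATURES))
        y = np.array([ACTIVITIES[i % len(ACTIVITIES)] for i in range(len(rows))])
        return WindowDataset(X, y, meta)

    return make
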