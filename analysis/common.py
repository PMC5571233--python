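"""Shared configuration for the numbered analysis scripts.

One master seed drives every stage; each script regenerates the cohort
deterministically rather than reading bulk intermediates, so any script can
be run on its own. Bulk artifacts (raw recordings, feature tables) go to
scratch/; the small result tables the scripts discuss go to results/.
"""

from pathlib import Path

from kafohar.modeling import WindowDataset
from kafohar.synth import CohortSpec, sample_cohort

STUDY_SEED = 42

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def study_spec(**overrides) -> CohortSpec:
    """The default study conditions: 11 healthy + 11 patients, 3 sessions."""
    return CohortSpec(seed=STUDY_SEED, **overrides)


def study_dataset(**overrides) -> WindowDataset:
    return WindowDataset.from_cohort(sample_cohort(study_spec(**overrides)))
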