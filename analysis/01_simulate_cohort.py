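"""Simulate the synthetic cohort and summarize its structure.

Generates the default cohort — 11 healthy subjects (3 sessions, no device)
and 11 patients (3 sessions with each of the control and novel orthoses),
each session a scripted sit/stand/walk/stairs sequence — writes the raw
recording CSVs plus manifest to scratch/cohort/, and a per-recording summary
to results/cohort_summary.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from common import RESULTS, SCRATCH, study_spec
from kafohar.io import write_cohort
from kafohar.synth import sample_cohort


def main() -> None:
    spec = study_spec()
    cohort = sample_cohort(spec)
    manifest = write_cohort(cohort, SCRATCH / "cohort")
    summary = cohort.index()
    summary["duration_s"] = [r.duration_s for r in cohort]
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False)

    n_healthy_rec = (summary.group == "healthy").sum()
    n_patient_rec = (summary.group == "patient").sum()
    print(f"cohort written to {manifest.parent}")
    print(f"  healthy recordings: {n_healthy_rec} (expected 11 subjects x 3 sessions = 33)")
    print(f"  patient recordings: {n_patient_rec} (expected 11 x 3 x 2 devices = 66)")
    print(f"  session length: {summary.duration_s.iloc[0]:.1f} s "
          f"(sit 60 + stand 60 + walk 120 + stairs 2 x 20)")
    print(pd.crosstab(summary.group, summary.device))


if __name__ == "__main__":
    main()
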