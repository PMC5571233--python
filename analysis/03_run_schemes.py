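"""Run the five training schemes for every patient and compare them.

For each of the 11 patients, trains the five classifiers (healthy,
impairment-specific, device-specific, patient-specific, patient+device-
specific; 10 trees for the healthy model, 50 otherwise) and evaluates
balanced accuracy on the patient's novel-device windows. Writes per-patient
scores (results/scheme_scores.csv), pooled confusion matrices
(results/confusion_<scheme>.csv), and the sequential Wilcoxon comparison
report (results/comparison.md).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np
import pandas as pd

from common import RESULTS, STUDY_SEED, study_dataset
from kafohar.evaluation import compare_models
from kafohar.experiments import ordering_holds, run_schemes


def main() -> None:
    dataset = study_dataset()
    scores, pooled = run_schemes(dataset, seed=STUDY_SEED + 23)

    RESULTS.mkdir(exist_ok=True)
    df = pd.DataFrame(scores).rename_axis("patient")
    df.to_csv(RESULTS / "scheme_scores.csv", float_format="%.4f")
    for scheme, cm in pooled.items():
        pd.DataFrame(cm.counts, index=list(cm.classes), columns=list(cm.classes)).to_csv(
            RESULTS / f"confusion_{scheme}.csv", index_label="true\\pred"
        )

    report = compare_models(scores)
    lines = ["| scheme | median BA | IQR | p (vs previous) |", "|---|---|---|---|"]
    tests = {t["more_specific"]: t for t in report["tests"]}
    for s, row in report["schemes"].items():
        p = f"{tests[s]['p_value']:.4g}" if s in tests else "-"
        lines.append(
            f"| {s} | {row['median']:.3f} | [{row['iqr'][0]:.3f}, {row['iqr'][1]:.3f}] | {p} |"
        )
    (RESULTS / "comparison.md").write_text("\n".join(lines) + "\n")

    medians = {s: float(np.median(list(v.values()))) for s, v in scores.items()}
    print("median balanced accuracy per scheme:")
    for s, m in medians.items():
        print(f"  {s:26s} {m:.3f}")
    print(
        "specificity ordering healthy <= impairment <= device <= patient+device:",
        ordering_holds(medians),
    )
    for t in report["tests"]:
        print(
            f"  {t['less_specific']} -> {t['more_specific']}: "
            f"p = {t['p_value']:.4g} ({t['method']})"
        )


if __name__ == "__main__":
    main()
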