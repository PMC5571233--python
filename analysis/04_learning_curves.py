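"""Learning curves: balanced accuracy vs number of training subjects.

For each global scheme family (healthy, impairment-specific, device-
specific), repeatedly draws a random test patient and a random subset of n
training subjects, and traces the median balanced accuracy with a bootstrap
confidence interval of the median. Patient-trained curves stop at n = 10:
one of the 11 patients is always held out for testing. Tables go to
results/learning_curve_<family>.csv.

Desk-scale draw counts are used here (12 iterations, 200 bootstrap
replicates per point); pass --profile paper for 1000/1000.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from common import RESULTS, STUDY_SEED, study_dataset
from kafohar.evaluation import learning_curve


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--profile", choices=["desk", "paper"], default="desk")
    args = ap.parse_args()
    iters, boots = (12, 200) if args.profile == "desk" else (1000, 1000)

    dataset = study_dataset()
    RESULTS.mkdir(exist_ok=True)
    for family in ("healthy", "impairment_specific", "device_specific"):
        lc = learning_curve(
            dataset, family, n_iterations=iters, n_bootstrap=boots, seed=STUDY_SEED + 37
        )
        df = pd.DataFrame(
            {
                "n_subjects": lc.n_subjects,
                "median": lc.median,
                "ci_low": lc.ci_low,
                "ci_high": lc.ci_high,
                "bootstrap_mean_of_medians": lc.bootstrap_mean_of_medians,
            }
        )
        df.to_csv(RESULTS / f"learning_curve_{family}.csv", index=False, float_format="%.4f")
        print(f"{family}: n = 1..{max(lc.n_subjects)}, "
              f"median BA {lc.median[0]:.3f} -> {lc.median[-1]:.3f}")


if __name__ == "__main__":
    main()
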