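"""End-to-end study replica on a synthetic cohort.

``run_study`` chains simulate -> window -> featurize -> all five schemes for
every patient -> paired comparisons -> learning curves, from a single config,
and writes a reproducible report bundle (config and seeds embedded; repeated
runs with the same config are byte-identical).

Profiles scale the stochastic stages: ``paper`` uses 1000 learning-curve
iterations and 1000 bootstrap replicates, ``test`` 50/200, ``smoke`` 6/100.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import (
    SPECIFICITY_ORDER,
    ConfusionMatrix,
    compare_models,
    evaluate_scheme,
    learning_curve,
)
from .io import ValidationError
from .modeling import DEFAULT_N_TREES, WindowDataset
from .synth import CohortSpec, sample_cohort

PROFILES = {
    "paper": {"n_iterations": 1000, "n_bootstrap": 1000},
    "test": {"n_iterations": 50, "n_bootstrap": 200},
    "smoke": {"n_iterations": 6, "n_bootstrap": 100},
}

#: substream offsets under the master seed
_SEED_COHORT = 11
_SEED_FOREST = 23
_SEED_CURVE = 37


@dataclass
class ExperimentConfig:
    master_seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides (sans seed)
    window_s: float = 6.0
    overlap: float = 0.75
    n_trees: dict = field(default_factory=lambda: dict(DEFAULT_N_TREES))
    alpha: float = 0.05
    profile: str = "test"
    learning_curve_families: tuple = ("healthy", "impairment_specific", "device_specific")

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValidationError(f"unknown profile {self.profile!r}; choose {list(PROFILES)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        return cfg

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(seed=self.master_seed + _SEED_COHORT, **self.cohort)


def run_schemes(
    dataset: WindowDataset,
    *,
    n_trees: dict[str, int] | None = None,
    seed: int = 0,
    schemes: tuple[str, ...] = SPECIFICITY_ORDER,
) -> tuple[dict[str, dict[str, float]], dict[str, ConfusionMatrix]]:
    """Per-patient balanced accuracies and pooled confusion matrix per scheme."""
    n_trees = dict(DEFAULT_N_TREES) if n_trees is None else n_trees
    scores: dict[str, dict[str, float]] = {s: {} for s in schemes}
    pooled: dict[str, ConfusionMatrix] = {}
    for scheme in schemes:
        for i, patient in enumerate(dataset.patients()):
            ba, cm = evaluate_scheme(
                dataset,
                scheme,
                patient,
                n_trees=n_trees[scheme],
                rng_seed=seed + 100 * i,
            )
            scores[scheme][patient] = ba
            pooled[scheme] = cm if scheme not in pooled else pooled[scheme] + cm
    return scores, pooled


def run_study(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full replica; returns the report dict and optionally writes it.

    Report contents: per-patient balanced accuracies for the five schemes,
    per-scheme medians/IQRs with the sequential Wilcoxon comparisons, pooled
    confusion matrices, and one learning curve per global scheme family.
    """
    profile = PROFILES[config.profile]
    spec = config.cohort_spec()
    cohort = sample_cohort(spec)
    dataset = WindowDataset.from_cohort(cohort, window_s=config.window_s, overlap=config.overlap)
    scores, pooled = run_schemes(
        dataset, n_trees=config.n_trees, seed=config.master_seed + _SEED_FOREST
    )
    comparison = compare_models(scores, alpha=config.alpha)
    curves = {}
    for fam in config.learning_curve_families:
        lc = learning_curve(
            dataset,
            fam,
            n_iterations=profile["n_iterations"],
            n_bootstrap=profile["n_bootstrap"],
            seed=config.master_seed + _SEED_CURVE,
            n_trees=config.n_trees[fam],
        )
        curves[fam] = {
            "n_subjects": list(lc.n_subjects),
            "median": list(lc.median),
            "ci_low": list(lc.ci_low),
            "ci_high": list(lc.ci_high),
            "bootstrap_mean_of_medians": list(lc.bootstrap_mean_of_medians),
        }
    report = {
        "config": {
            "master_seed": config.master_seed,
            "cohort": asdict(spec) | {"durations_s": dict(spec.durations_s)},
            "window_s": config.window_s,
            "overlap": config.overlap,
            "n_trees": dict(config.n_trees),
            "alpha": config.alpha,
            "profile": config.profile,
        },
        "n_windows": int(len(dataset.y)),
        "per_patient_balanced_accuracy": {
            s: {p: round(v, 10) for p, v in sorted(scores[s].items())} for s in scores
        },
        "comparison": comparison,
        "learning_curves": curves,
    }
    if out_dir is not None:
        _write_bundle(report, pooled, out_dir)
    return report


def _write_bundle(report: dict, pooled: dict[str, ConfusionMatrix], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    for scheme, cm in pooled.items():
        df = pd.DataFrame(cm.counts, index=list(cm.classes), columns=list(cm.classes))
        df.to_csv(out / f"confusion_{scheme}.csv", index_label="true\\pred")
    for fam, lc in report["learning_curves"].items():
        pd.DataFrame(lc).to_csv(out / f"learning_curve_{fam}.csv", index=False)
    lines = [
        "| scheme | median BA | IQR | Wilcoxon p (vs previous) |",
        "|---|---|---|---|",
    ]
    tests = {t["more_specific"]: t for t in report["comparison"]["tests"]}
    for s, row in report["comparison"]["schemes"].items():
        p = f"{tests[s]['p_value']:.4g}" if s in tests else "-"
        lines.append(
            f"| {s} | {row['median']:.3f} | [{row['iqr'][0]:.3f}, {row['iqr'][1]:.3f}] | {p} |"
        )
    (out / "comparison.md").write_text("\n".join(lines) + "\n")


def ordering_holds(medians: dict[str, float], tol: float = 0.0) -> bool:
    """Whether medians respect healthy <= impairment <= device <= patient+device."""
    chain = ("healthy", "impairment_specific", "device_specific", "patient_device_specific")
    vals = [medians[s] for s in chain]
    return all(b >= a - tol for a, b in zip(vals, vals[1:]))
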