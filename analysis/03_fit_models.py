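#!/usr/bin/env python
"""Fit the statistical layer on the derived metrics.

Per frequency band: a random-intercept mixed model of small-worldness on
disease, eyes state and age (cluster-robust z tests, alpha = 0.05); robust OLS
of SW on delayed recall + age per group x condition (alpha = 0.025); and
robust OLS of eyes-state reactivity on delayed recall + age per group
(alpha = 0.025). Writes the three tidy result CSVs plus the demographics
table.
"""

import argparse
from pathlib import Path

import pandas as pd

from megsw import PipelineConfig, run_analyze


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/study/data"))
    ap.add_argument("--derived", type=Path, default=Path("results/study/derived"))
    ap.add_argument("--out", type=Path, default=Path("results/study/stats"))
    ap.add_argument("--seed", type=int, default=2024)
    args = ap.parse_args()

    cfg = PipelineConfig(master_seed=args.seed)
    out = run_analyze(
        cfg,
        metrics_csv=args.derived / "metrics.csv",
        subjects_csv=args.data / "subjects.csv",
        reactivity_csv=args.derived / "reactivity.csv",
        out_dir=args.out,
    )
    mixed = pd.read_csv(out / "mixed_models.csv")
    print(f"mixed-model rows: {len(mixed)} -> {out / 'mixed_models.csv'}")
    if len(mixed):
        print("\nmixed-model coefficients (sw ~ disease + condition + age):")
        cols = ["band", "term", "coefficient", "robust_se", "statistic", "p_value", "significant"]
        print(mixed[cols].round(4).to_string(index=False))
    for f in ("recall_regressions.csv", "reactivity_regressions.csv", "demographics.csv"):
        df = pd.read_csv(out / f)
        print(f"\n{f}: {len(df)} rows")


if __name__ == "__main__":
    main()
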