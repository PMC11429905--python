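#!/usr/bin/env python
"""PLS-DA and the four-model classifier suite on both representations.

Reads results/features/, writes results/classify/, and prints the PLS-DA
R2/Q2/accuracy/AUC for control-vs-malignant and control-vs-benign plus the
cross-validated metric panel of RF / LR / SVM / SGD. Uses the 10-repetition
desk profile; pass --reps 100 for the full protocol.
"""

import argparse
from pathlib import Path

import pandas as pd

from utfmp.models import (
    CvSpec,
    SplitSpec,
    default_model_specs,
    fit_plsda,
    run_suite,
    stratified_split,
    suite_summary,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--features-dir", type=Path, default=Path("results/features"))
    ap.add_argument("--outdir", type=Path, default=Path("results/classify"))
    ap.add_argument("--seed", type=int, default=2024)
    ap.add_argument("--reps", type=int, default=10)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    zones = pd.read_csv(args.features_dir / "features_zones.csv", index_col="sample_id")

    print("PLS-DA (zone features):")
    plsda_rows = []
    for positive in ("malignant", "benign"):
        sub = zones[zones["group"].isin(["control", positive])]
        train, test = stratified_split(sub, SplitSpec(seed=args.seed))
        res = fit_plsda(train, test, n_components=2, positive_group=positive, seed=args.seed)
        plsda_rows.append({"comparison": f"control_vs_{positive}", "r2": res.r2,
                           "q2": res.q2, "accuracy": res.accuracy, "auc": res.auc})
        print(f"  control vs {positive}: R2={res.r2:.3f} Q2={res.q2:.3f} "
              f"accuracy={res.accuracy:.2f} AUC={res.auc:.2f}")
    pd.DataFrame(plsda_rows).to_csv(args.outdir / "plsda.csv", index=False)

    summaries = []
    for representation in ("zones", "utfmp"):
        table = pd.read_csv(
            args.features_dir / f"features_{representation}.csv", index_col="sample_id"
        )
        reports = run_suite(
            table, default_model_specs(),
            CvSpec(n_folds=10, n_repetitions=args.reps, seed=args.seed),
            SplitSpec(seed=args.seed), representation=representation,
        )
        summaries.append(suite_summary(reports))
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(args.outdir / "classifier_metrics.csv", index=False)

    wide = summary.pivot_table(index=["representation", "model"], columns="metric", values="cv_mean")
    print(f"\nclassifier suite, mean CV metrics over {args.reps} repetitions:")
    print(wide[["sensitivity", "specificity", "ppv", "npv", "plr", "nlr", "accuracy", "auc"]]
          .round(2).to_string())


if __name__ == "__main__":
    main()
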