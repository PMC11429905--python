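#!/usr/bin/env python
"""Group-difference tests for every zone and ratio marker, plus ROC/AUC
summaries of the two spectral-marker ratios against the control group.

Reads results/features/features_zones.csv, writes results/stats/, and
prints the adjusted pairwise p-values and the marker AUCs with their
Hanley-McNeil confidence intervals.
"""

import argparse
from pathlib import Path

import pandas as pd

from utfmp.stats import marker_roc_table, significance_stars, test_group_differences


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", type=Path, default=Path("results/features/features_zones.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results/stats"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    table = pd.read_csv(args.features, index_col="sample_id")
    zone_cols = ["Z1a", "Z1b", "Z2", "Z3", "Z4a", "Z4b", "Z5", "Z6", "Z7",
                 "Z4a_over_Z5", "Z6_over_Z7"]
    rows = []
    for variable in zone_cols:
        res = test_group_differences(table, variable)
        row = {"variable": variable, "test": res.global_test,
               "p_global": res.global_p, "stars": significance_stars(res.global_p)}
        for comp in res.pairwise:
            row[f"p_{comp.pair[0]}_vs_{comp.pair[1]}"] = comp.p_adjusted
        rows.append(row)
    tests = pd.DataFrame(rows)
    tests.to_csv(args.outdir / "zone_tests.csv", index=False)
    print("group-difference tests (adjusted pairwise p-values):")
    print(tests.round(4).to_string(index=False))

    roc = pd.concat(
        [marker_roc_table(table, g) for g in ("benign", "malignant")],
        ignore_index=True,
    )
    roc.to_csv(args.outdir / "marker_roc.csv", index=False)
    print("\nratio-marker ROC (AUC, SE, 95% CI, p vs 0.5):")
    print(roc.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
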