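#!/usr/bin/env python
"""Integrate the RNA and protein candidate lists.

Partitions the RNA candidates against the protein layer (not detected /
overlapping with matching or opposite direction / detected but not a
protein candidate) and computes the fold-change concordance (Pearson R of
log2 FC) over genes significant in both layers that pass both expression
gates. Assembles the final run summary.
"""

import argparse
import json
from pathlib import Path

import migexpress as mx
from migexpress import io


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    rna = io.read_candidates(args.outdir / "rna_candidates.tsv")
    prot = io.read_candidates(args.outdir / "protein_candidates.tsv")
    detected = prot["feature"]  # universe of MS-detected genes
    rep = mx.overlap_candidates(rna, prot, detected)
    n, r = mx.fc_concordance(rna, prot)

    io.write_run_summary(
        {"overlap": rep.counts(), "concordance": {"n": n, "r": round(r, 4)},
         "genes": rep.genes},
        args.outdir / "integrate_summary.json",
    )
    merged = {}
    for path in sorted(args.outdir.glob("*_summary.json")):
        with open(path) as fh:
            merged[path.stem] = json.load(fh)
    io.write_run_summary(merged, args.outdir / "run_summary.json")

    n_rna = int(rna["candidate"].sum())
    print(f"overlap partition of {n_rna} RNA candidates: {rep.counts()}")
    print(f"fold-change concordance: R = {r:.3f} over n = {n} genes "
          "significant in both layers")
    if rep.overlap_discordant == 0:
        print("no overlaps in opposing directions, as expected when protein "
              "effects share the RNA effect sign")
    print(f"run summary written to {args.outdir / 'run_summary.json'}")


if __name__ == "__main__":
    main()
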