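"""Cross-layer integration of RNA and protein candidate lists.

Two views: (1) an overlap partition of the RNA candidate list against the
protein candidates, keeping direction agreement explicit (discordant
overlaps are reported even when zero); (2) the fold-change concordance —
Pearson correlation of log2 fold changes for the genes that are
significant in both layers and pass both layers' expression gates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OverlapReport:
    """Partition of the RNA candidate list against protein candidates.

    The first four count fields partition the RNA candidates exactly:
    not detected at the protein level; overlapping with agreeing direction
    (up / down); overlapping with opposite direction; detected at the
    protein level but not a protein candidate. ``protein_only`` counts
    protein candidates absent from the RNA list.
    """

    rna_not_detected_in_protein: int
    overlap_up: int
    overlap_down: int
    overlap_discordant: int
    rna_only_detected: int
    protein_only: int
    genes: dict

    def counts(self) -> dict:
        d = asdict(self)
        d.pop("genes")
        return d


def _norm_ids(ids) -> pd.Index:
    idx = pd.Index([str(g).upper() for g in ids])
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValueError(f"duplicated gene id after normalization: {dup!r}")
    return idx


def overlap_candidates(
    rna: pd.DataFrame, prot: pd.DataFrame, prot_detected
) -> OverlapReport:
    """Partition RNA candidates against protein candidates and detection.

    ``rna`` and ``prot`` are candidate tables (only rows with
    ``candidate`` True are considered candidates); ``prot_detected`` is the
    set of gene ids with a measurable protein signal. Gene matching is
    exact string match after uppercasing.
    """
    rna_cand = rna[rna["candidate"].astype(bool)]
    prot_cand = prot[prot["candidate"].astype(bool)]
    rna_ids = _norm_ids(rna_cand["feature"])
    prot_ids = _norm_ids(prot_cand["feature"])
    detected = set(str(g).upper() for g in prot_detected)

    rna_dir = dict(zip(rna_ids, rna_cand["direction"]))
    prot_dir = dict(zip(prot_ids, prot_cand["direction"]))

    not_detected = [g for g in rna_ids if g not in detected]
    overlap = [g for g in rna_ids if g in set(prot_ids)]
    up = [g for g in overlap if rna_dir[g] == prot_dir[g] == "up"]
    down = [g for g in overlap if rna_dir[g] == prot_dir[g] == "down"]
    discordant = [g for g in overlap if rna_dir[g] != prot_dir[g]]
    only_detected = [
        g for g in rna_ids
        if g in detected and g not in set(prot_ids)
    ]
    protein_only = [g for g in prot_ids if g not in set(rna_ids)]

    return OverlapReport(
        rna_not_detected_in_protein=len(not_detected),
        overlap_up=len(up),
        overlap_down=len(down),
        overlap_discordant=len(discordant),
        rna_only_detected=len(only_detected),
        protein_only=len(protein_only),
        genes={
            "rna_not_detected_in_protein": not_detected,
            "overlap_up": up,
            "overlap_down": down,
            "overlap_discordant": discordant,
            "rna_only_detected": only_detected,
            "protein_only": protein_only,
        },
    )


def fc_concordance(
    rna: pd.DataFrame, prot: pd.DataFrame, alpha: float = 0.05
) -> tuple[int, float]:
    """Fold-change concordance between layers.

    Takes the full per-feature tables of both layers (not just candidates),
    keeps genes with P < alpha in both layers that pass both layers'
    expression/detection gates (the ``expressed`` flag), and returns the
    number of qualifying genes and the Pearson R of their log2 mean fold
    changes. Fewer than 3 qualifying genes yields NaN with a warning.
    """
    r = rna.set_index(_norm_ids(rna["feature"]))
    p = prot.set_index(_norm_ids(prot["feature"]))
    shared = r.index.intersection(p.index)
    r, p = r.loc[shared], p.loc[shared]
    keep = (
        (r["p_value"].astype(float) < alpha) & (p["p_value"].astype(float) < alpha)
        & r["expressed"].astype(bool) & p["expressed"].astype(bool)
    )
    n = int(keep.sum())
    if n < 3:
        warnings.warn(f"only {n} genes qualify for concordance; R set to NaN")
        return n, float("nan")
    x = np.log2(r.loc[keep, "mean_fc"].astype(float))
    y = np.log2(p.loc[keep, "mean_fc"].astype(float))
    return n, float(stats.pearsonr(x, y).statistic)
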