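"""Differential circRNA analysis from back-splice junction counts.

Back-splice reads quantify circular RNAs; counts are normalized to reads
per million of each line's sequencing library. The analysis runs at two
levels: individual back-splice junctions, and genes (junction counts summed
per gene before normalization). Candidate selection mirrors the mRNA
funnel — detection in >= 50% of lines, average fold change across the
three coatings >= 3 (or <= 1/3) — but the significance value is the
average of the three per-coating Welch p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import COATINGS, FilterSet
from .diffexp import GroupAssignment, _direction, mean_fold_change, welch_test
from .matrix import OmicsMatrix

log = logging.getLogger("migexpress")

#: per-million pseudocount used for log transforms and fold-change guards
CPM_PSEUDOCOUNT = 0.5


def parse_junction_gene(junction_id: str) -> str:
    """Gene symbol from a ``GENE|chrom:donorExon-acceptorExon`` junction id."""
    gene, sep, _ = junction_id.partition("|")
    if not sep or not gene:
        raise ValueError(f"malformed junction id: {junction_id!r}")
    return gene


@dataclass
class BackspliceTable:
    """Raw back-splice read counts (junctions x lines) with library sizes."""

    counts: pd.DataFrame
    library_sizes: pd.Series
    genes: pd.Series | None = None  # junction id -> gene; parsed if None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate junction ids")
        counts = self.counts.astype(float)
        if (counts < 0).any().any() or not np.allclose(counts, counts.round()):
            raise ValueError("back-splice counts must be nonnegative integers")
        self.counts = counts
        missing = set(self.counts.columns) - set(self.library_sizes.index)
        if missing:
            raise ValueError(f"missing library size for lines: {sorted(missing)}")
        self.library_sizes = self.library_sizes.loc[self.counts.columns].astype(float)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        if self.genes is None:
            self.genes = pd.Series(
                [parse_junction_gene(j) for j in self.counts.index],
                index=self.counts.index,
            )


def aggregate_gene_level(table: BackspliceTable) -> BackspliceTable:
    """Sum raw junction counts per gene (aggregation always precedes
    normalization, since counts are additive only before scaling)."""
    summed = table.counts.groupby(table.genes).sum()
    return BackspliceTable(
        counts=summed,
        library_sizes=table.library_sizes,
        genes=pd.Series(summed.index, index=summed.index),
    )


def normalize_libsize(table: BackspliceTable, level: str = "backsplice") -> OmicsMatrix:
    """Back-splice reads per million library reads, with a detection mask
    marking lines where the raw count is nonzero."""
    values = table.counts.div(table.library_sizes, axis=1) * 1e6
    layer = "circ_gene" if level == "gene" else "circ_bs"
    return OmicsMatrix(
        values=values, layer=layer, scale="linear",
        detected=table.counts > 0,
    )


def circ_candidates(
    matrix: OmicsMatrix,
    groups: GroupAssignment,
    filters: FilterSet,
    combine: str = "mean_p",
    pseudocount: float = CPM_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, dict]:
    """circRNA candidate funnel on a normalized (per-million) matrix.

    Detection gate on the fraction of lines with a nonzero raw count; per
    coating, FC on unlogged per-million values (pseudocount-guarded) and a
    Welch test on log2(value + pseudocount); selection uses the mean FC and
    either the mean per-coating p (default) or Fisher's combined p
    (``combine='fisher'``).
    """
    if combine not in ("mean_p", "fisher"):
        raise ValueError("combine must be 'mean_p' or 'fisher'")
    if matrix.detected is None:
        raise ValueError("circ candidate selection requires a detection mask")
    logmat = OmicsMatrix(
        values=np.log2(matrix.values + pseudocount),
        layer=matrix.layer, scale="log2", detected=matrix.detected,
    )
    fc, pvals = {}, {}
    for coating in COATINGS:
        fast, slow = groups.per_coating.get(coating, ([], []))
        if fast and slow:
            num = matrix.values[list(fast)].mean(axis=1) + pseudocount
            den = matrix.values[list(slow)].mean(axis=1) + pseudocount
            fc[f"fc_{coating}"] = num / den
            pvals[coating] = welch_test(logmat, fast, slow)
        else:
            fc[f"fc_{coating}"] = pd.Series(np.nan, index=matrix.features)
            pvals[coating] = pd.Series(np.nan, index=matrix.features)
    fc = pd.DataFrame(fc)
    pmat = pd.DataFrame(pvals)
    mean_fc = mean_fold_change(fc)
    if combine == "mean_p":
        p = pmat.mean(axis=1, skipna=True)
    else:
        stat = -2.0 * np.log(pmat).sum(axis=1, skipna=False)
        p = pd.Series(
            stats.chi2.sf(stat, 2 * pmat.notna().sum(axis=1)),
            index=matrix.features,
        )

    detected_frac = matrix.detection_mask().mean(axis=1)
    expressed = detected_frac >= (filters.min_detect_frac or 0.5)
    regulated = (mean_fc >= filters.min_fc) | (mean_fc <= 1.0 / filters.min_fc)
    significant = p < filters.alpha

    q = pd.Series(np.nan, index=matrix.features)
    tested = p.notna()
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "feature": matrix.features,
            **{c: fc[c].to_numpy() for c in fc.columns},
            "mean_fc": mean_fc.to_numpy(),
            "p_value": p.to_numpy(),
            "q_value": q.to_numpy(),
            "direction": _direction(mean_fc).to_numpy(),
            "expressed": expressed.to_numpy(),
            "regulated": regulated.fillna(False).to_numpy(),
            "significant": significant.fillna(False).to_numpy(),
        }
    )
    table["candidate"] = table["expressed"] & table["regulated"] & table["significant"]
    table["layer"] = matrix.layer
    funnel = {
        "n_total": int(len(table)),
        "n_expressed": int(table["expressed"].sum()),
        "n_regulated": int((table["expressed"] & table["regulated"]).sum()),
        "n_significant": int(table["candidate"].sum()),
    }
    log.info(
        "circ_candidates[%s]: %d -> %d detected -> %d regulated -> %d significant",
        matrix.layer, funnel["n_total"], funnel["n_expressed"],
        funnel["n_regulated"], funnel["n_significant"],
    )
    return table.reset_index(drop=True), funnel
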