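"""End-to-end screen analysis: classification through integration."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .circrna import aggregate_gene_level, circ_candidates, normalize_libsize
from .config import RunConfig
from .diffexp import GroupAssignment, groups_from_classes, select_candidates
from .integrate import OverlapReport, fc_concordance, overlap_candidates
from .matrix import OmicsMatrix
from .migration import classify_screen
from .simulate import SimulatedScreen
from .tmt import drop_reference_columns, normalize_tmt


@dataclass
class ScreenAnalysis:
    classes: pd.DataFrame
    groups: GroupAssignment
    rna_candidates: pd.DataFrame
    rna_funnel: dict
    protein_candidates: pd.DataFrame
    protein_funnel: dict
    circ_gene_candidates: pd.DataFrame
    circ_gene_funnel: dict
    circ_bs_candidates: pd.DataFrame
    circ_bs_funnel: dict
    overlap: OverlapReport
    concordance_n: int
    concordance_r: float

    def summary(self) -> dict:
        return {
            "class_counts": self.classes["consensus"].value_counts().to_dict(),
            "rna_funnel": self.rna_funnel,
            "protein_funnel": self.protein_funnel,
            "circ_gene_funnel": self.circ_gene_funnel,
            "circ_bs_funnel": self.circ_bs_funnel,
            "overlap": self.overlap.counts(),
            "concordance": {"n": self.concordance_n, "r": self.concordance_r},
        }


def normalize_protein_layer(screen: SimulatedScreen) -> OmicsMatrix:
    """TMT normalization (within-plex quantile alignment + cross-plex
    reference correction), restricted to cell-line columns."""
    normalized, _, _ = normalize_tmt(screen.protein, screen.plex_design)
    return drop_reference_columns(normalized, screen.plex_design)


def analyze_screen(screen: SimulatedScreen, config: RunConfig | None = None) -> ScreenAnalysis:
    """Run the full candidate-selection pipeline on one screen."""
    config = config or RunConfig()
    classes = classify_screen(screen.migration, config.thresholds)
    groups = groups_from_classes(classes)

    rna_cand, rna_funnel = select_candidates(
        screen.rna, groups, config.rna_filters,
        pseudocount=config.pseudocount, layer="rna",
    )
    protein_norm = normalize_protein_layer(screen)
    prot_cand, prot_funnel = select_candidates(
        protein_norm, groups, config.protein_filters, layer="protein",
    )

    circ_bs = normalize_libsize(screen.circ, level="backsplice")
    bs_cand, bs_funnel = circ_candidates(circ_bs, groups, config.circ_filters)
    circ_gene = normalize_libsize(aggregate_gene_level(screen.circ), level="gene")
    gene_cand, gene_funnel = circ_candidates(circ_gene, groups, config.circ_filters)

    prot_detected = protein_norm.features[
        protein_norm.values.notna().any(axis=1)
    ]
    overlap = overlap_candidates(rna_cand, prot_cand, prot_detected)
    n, r = fc_concordance(rna_cand, prot_cand, alpha=config.rna_filters.alpha)

    return ScreenAnalysis(
        classes=classes, groups=groups,
        rna_candidates=rna_cand, rna_funnel=rna_funnel,
        protein_candidates=prot_cand, protein_funnel=prot_funnel,
        circ_gene_candidates=gene_cand, circ_gene_funnel=gene_funnel,
        circ_bs_candidates=bs_cand, circ_bs_funnel=bs_funnel,
        overlap=overlap, concordance_n=n, concordance_r=r,
    )


def recovery_metrics(candidates: pd.DataFrame, planted: pd.DataFrame) -> dict:
    """Sensitivity and empirical FDR of a candidate list against the
    planted ground-truth features."""
    called = set(candidates.loc[candidates["candidate"], "feature"])
    truth = set(planted["feature"])
    tp = len(called & truth)
    return {
        "n_called": len(called),
        "n_planted": len(truth),
        "recovered": tp,
        "sensitivity": tp / len(truth) if truth else float("nan"),
        "fdr": (len(called) - tp) / len(called) if called else 0.0,
    }
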