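"""Migration quantification and fast/medium/slow classification.

A cell line's migration on a coating is the replicate mean of its
% migration at the 48-h endpoint. Per-coating classes use fixed strict
thresholds (fast above 60/75/60 % on uncoated/collagen/fibronectin, slow
below 25 %); the consensus class is the one reached on at least two of the
three coating surfaces.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .config import COATINGS, ClassificationThresholds

log = logging.getLogger("migexpress")

CLASSES = ("fast", "medium", "slow")


def oris_percent(area_t0: float, area_t: float) -> float:
    """% migration from exclusion-zone areas: the fraction of the initially
    cell-free zone (0-h control area) covered at time t, clipped to [0, 100].
    """
    if area_t0 <= 0:
        raise ValueError(f"0-h area must be positive, got {area_t0}")
    if area_t < 0:
        raise ValueError(f"area at time t must be nonnegative, got {area_t}")
    return float(np.clip(100.0 * (area_t0 - area_t) / area_t0, 0.0, 100.0))


def scratch_migrated_area(gap_0h, gap_t) -> float:
    """Scratch-assay migrated area: mean gap width at 0 h minus mean gap
    width at time t, each measured at exactly three positions. A widening
    gap (negative difference) is reported as 0 with a warning.
    """
    gap_0h = np.asarray(gap_0h, dtype=float)
    gap_t = np.asarray(gap_t, dtype=float)
    if gap_0h.shape != (3,) or gap_t.shape != (3,):
        raise ValueError("exactly 3 gap measurements required per timepoint")
    if (gap_0h <= 0).any() or (gap_t <= 0).any():
        raise ValueError("gap widths must be positive")
    migrated = float(gap_0h.mean() - gap_t.mean())
    if migrated < 0:
        warnings.warn("gap widened over time; reporting migrated area as 0")
        return 0.0
    return migrated


def proliferation_doublings(count_0: float, count_t: float) -> float:
    """Population doublings between two viable-cell counts: log2(Nt / N0)."""
    if count_0 <= 0 or count_t <= 0:
        raise ValueError("cell counts must be positive")
    return float(np.log2(count_t / count_0))


def replicate_sem(values) -> float:
    """Standard error of the mean across replicate measurements."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("SEM requires at least 2 replicates")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def classify_per_coating(
    mean_percent: float, coating: str, thresholds: ClassificationThresholds
) -> str:
    """Classify one (line, coating) mean % migration. Strict comparisons:
    boundary values fall to medium."""
    if not 0 <= mean_percent <= 100:
        raise ValueError(f"percent migration out of [0, 100]: {mean_percent}")
    if mean_percent > thresholds.fast_threshold(coating):
        return "fast"
    if mean_percent < thresholds.slow_all:
        return "slow"
    return "medium"


def classify_consensus(per_coating) -> str:
    """Consensus class across coatings: the class reached on >= 2 surfaces.

    A single measured coating carries its own class. When no class reaches
    two votes (all available classes distinct), the line falls to medium,
    the residual category.
    """
    votes = [c for c in per_coating if c is not None and c == c and c != "NA"]
    if not votes:
        raise ValueError("consensus requires at least one classified coating")
    if len(votes) == 1:
        return votes[0]
    counts = pd.Series(votes).value_counts()
    if counts.iloc[0] >= 2:
        return counts.index[0]
    return "medium"


def coating_means(table: pd.DataFrame, timepoint_h: int = 48) -> pd.DataFrame:
    """Per-line replicate means of % migration at one timepoint, one column
    per coating (NaN where a line did not attach on a surface)."""
    at_t = table[table["timepoint_h"] == timepoint_h]
    if at_t.empty:
        raise ValueError(f"no measurements at timepoint {timepoint_h} h")
    means = at_t.pivot_table(
        index="cell_line", columns="coating", values="percent_migration",
        aggfunc="mean",
    )
    return means.reindex(columns=list(COATINGS))


def coating_sems(table: pd.DataFrame, timepoint_h: int = 48) -> pd.DataFrame:
    """Replicate SEM per (line, coating); NaN with fewer than 2 replicates."""
    at_t = table[table["timepoint_h"] == timepoint_h]
    sems = at_t.pivot_table(
        index="cell_line", columns="coating", values="percent_migration",
        aggfunc=lambda v: replicate_sem(v) if len(v) >= 2 else np.nan,
    )
    return sems.reindex(columns=list(COATINGS))


def classify_screen(
    table: pd.DataFrame,
    thresholds: ClassificationThresholds | None = None,
    timepoint_h: int = 48,
) -> pd.DataFrame:
    """Classify every line in a migration table.

    Returns one row per cell line with per-coating means and SEMs,
    per-coating classes ('NA' where unmeasured), the consensus class, and a
    flag for lines classified from a single measurable coating.
    """
    thresholds = thresholds or ClassificationThresholds()
    means = coating_means(table, timepoint_h)
    sems = coating_sems(table, timepoint_h)
    out = pd.DataFrame(index=means.index)
    for coating in COATINGS:
        out[f"mean_{coating}"] = means[coating]
        out[f"sem_{coating}"] = sems[coating]
        out[f"class_{coating}"] = [
            "NA" if np.isnan(m) else classify_per_coating(m, coating, thresholds)
            for m in means[coating]
        ]
    class_cols = [f"class_{c}" for c in COATINGS]
    out["consensus"] = [
        classify_consensus([row[c] for c in class_cols if row[c] != "NA"])
        for _, row in out.iterrows()
    ]
    out["single_coating"] = (out[class_cols] != "NA").sum(axis=1) == 1
    counts = out["consensus"].value_counts()
    log.info(
        "classify_screen: %d lines -> %s",
        len(out), {c: int(counts.get(c, 0)) for c in CLASSES},
    )
    return out


def coating_correlations(table: pd.DataFrame, timepoint_h: int = 48) -> pd.Series:
    """Pairwise Pearson correlation of per-line mean % migration between
    coating surfaces (pairwise-complete lines). Pairs with fewer than 3
    complete lines yield NaN with a warning."""
    means = coating_means(table, timepoint_h)
    out = {}
    pairs = [(a, b) for i, a in enumerate(COATINGS) for b in COATINGS[i + 1:]]
    for a, b in pairs:
        both = means[[a, b]].dropna()
        if len(both) < 3:
            warnings.warn(f"fewer than 3 lines with both {a} and {b}; R set to NaN")
            out[f"{a}_vs_{b}"] = np.nan
        else:
            out[f"{a}_vs_{b}"] = stats.pearsonr(both[a], both[b]).statistic
    return pd.Series(out)


def migration_proliferation_correlation(
    table: pd.DataFrame, doublings: pd.Series, timepoint_h: int = 48
) -> float:
    """Pearson R between average migration capacity (mean over coatings)
    and proliferation doublings, over lines present in both."""
    capacity = coating_means(table, timepoint_h).mean(axis=1)
    both = pd.concat([capacity, doublings], axis=1, join="inner").dropna()
    if len(both) < 3:
        raise ValueError("need at least 3 lines with both measurements")
    return float(stats.pearsonr(both.iloc[:, 0], both.iloc[:, 1]).statistic)
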