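"""Fold-change / Welch-test candidate selection between fast and slow lines.

Fold changes are ratios of group means on the linear scale, computed for
each coating surface separately (using that coating's fast and slow
classes) and averaged arithmetically. Significance is a two-sided Welch
t-test on log2 values between the overall (consensus-class) fast and slow
groups. The candidate funnel applies, in order: an expression floor or
detection gate, a fold-change magnitude cutoff, and raw P < alpha — no
multiple-testing correction is used for selection, though BH q-values are
reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import COATINGS, FilterSet
from .matrix import OmicsMatrix

log = logging.getLogger("migexpress")


@dataclass
class GroupAssignment:
    """Fast/slow line ids per coating and overall (consensus classes).
    Medium lines are excluded from all comparisons."""

    per_coating: dict = field(default_factory=dict)  # coating -> (fast, slow)
    overall_fast: list = field(default_factory=list)
    overall_slow: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for coating, (fast, slow) in self.per_coating.items():
            if set(fast) & set(slow):
                raise ValueError(f"fast/slow overlap on coating {coating!r}")
        if set(self.overall_fast) & set(self.overall_slow):
            raise ValueError("fast/slow overlap in overall grouping")


def groups_from_classes(classes: pd.DataFrame) -> GroupAssignment:
    """Build a group assignment from a ``classify_screen`` table."""
    per_coating = {}
    for coating in COATINGS:
        col = classes[f"class_{coating}"]
        per_coating[coating] = (
            list(classes.index[col == "fast"]),
            list(classes.index[col == "slow"]),
        )
    return GroupAssignment(
        per_coating=per_coating,
        overall_fast=list(classes.index[classes["consensus"] == "fast"]),
        overall_slow=list(classes.index[classes["consensus"] == "slow"]),
    )


def _linear_values(matrix: OmicsMatrix) -> pd.DataFrame:
    return matrix.values if matrix.scale == "linear" else 2.0 ** matrix.values


def _log2_values(matrix: OmicsMatrix, pseudocount: float) -> pd.DataFrame:
    if matrix.scale == "log2":
        return matrix.values
    return np.log2(matrix.values + pseudocount)


def group_fold_change(
    matrix: OmicsMatrix, fast, slow, pseudocount: float = 0.0
) -> pd.Series:
    """Per-feature FC = (mean over fast + pc) / (mean over slow + pc),
    on the linear scale, skipping missing values."""
    if len(fast) == 0 or len(slow) == 0:
        raise ValueError("both groups must be non-empty")
    values = _linear_values(matrix)
    num = values[list(fast)].mean(axis=1, skipna=True) + pseudocount
    den = values[list(slow)].mean(axis=1, skipna=True) + pseudocount
    return num / den


def mean_fold_change(fc_by_coating: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of the available (finite) per-coating fold changes."""
    fc = fc_by_coating.replace([np.inf, -np.inf], np.nan)
    return fc.mean(axis=1, skipna=True)


def welch_test(matrix: OmicsMatrix, fast, slow) -> pd.Series:
    """Two-sided Welch t-test p-value per feature on log2 values.

    Features with fewer than 2 non-missing values in either group get NaN.
    Zero variance in both groups gives p = 1 when the means agree (no
    evidence of difference) and p = 0 when they differ.
    """
    if matrix.scale != "log2":
        raise ValueError("welch_test expects a log2-scale matrix")
    a = matrix.values[list(fast)].to_numpy()
    b = matrix.values[list(slow)].to_numpy()
    na = np.sum(~np.isnan(a), axis=1).astype(float)
    nb = np.sum(~np.isnan(b), axis=1).astype(float)
    import warnings as _warnings
    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # features failing the n>=2 rule produce empty-slice warnings here
        # and are set to NaN below
        _warnings.simplefilter("ignore", RuntimeWarning)
        ma, mb = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
        sa, sb = va / na, vb / nb
        se2 = sa + sb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p[degenerate & (ma == mb)] = 1.0
    p[degenerate & (ma != mb)] = 0.0
    p[(na < 2) | (nb < 2)] = np.nan
    return pd.Series(p, index=matrix.features)


def _direction(mean_fc: pd.Series) -> pd.Series:
    return pd.Series(
        np.where(mean_fc > 1.0, "up", "down"), index=mean_fc.index
    )


def per_coating_fold_changes(
    matrix: OmicsMatrix, groups: GroupAssignment, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Fold change per coating surface using that coating's own fast/slow
    classes; coatings without both groups populated give NaN."""
    fc = {}
    for coating in COATINGS:
        fast, slow = groups.per_coating.get(coating, ([], []))
        if fast and slow:
            fc[f"fc_{coating}"] = group_fold_change(
                matrix, fast, slow, pseudocount
            )
        else:
            fc[f"fc_{coating}"] = pd.Series(np.nan, index=matrix.features)
    return pd.DataFrame(fc)


def select_candidates(
    matrix: OmicsMatrix,
    groups: GroupAssignment,
    filters: FilterSet,
    pseudocount: float = 0.0,
    layer: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply the candidate funnel and return (candidate table, funnel counts).

    Funnel order: (1) expression floor (mean over all lines >= min_expr) or
    detection gate (fraction of lines with signal >= min_detect_frac);
    (2) regulation, mean FC >= min_fc or <= 1/min_fc; (3) significance,
    Welch P < alpha on the overall fast-vs-slow grouping. Flags are
    conjunctive: a candidate passes all three.
    """
    if not groups.overall_fast or not groups.overall_slow:
        raise ValueError("overall fast and slow groups must be non-empty")
    layer = layer or matrix.layer
    fc = per_coating_fold_changes(matrix, groups, pseudocount)
    mean_fc = mean_fold_change(fc)
    logmat = matrix if matrix.scale == "log2" else OmicsMatrix(
        values=_log2_values(matrix, pseudocount), layer=matrix.layer,
        scale="log2",
    )
    p = welch_test(logmat, groups.overall_fast, groups.overall_slow)

    if filters.min_expr is not None:
        expressed = _linear_values(matrix).mean(axis=1, skipna=True) >= filters.min_expr
    elif filters.min_detect_frac is not None:
        frac = matrix.detection_mask().mean(axis=1)
        expressed = frac >= filters.min_detect_frac
    else:
        expressed = pd.Series(True, index=matrix.features)
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
    table["layer"] = layer
    funnel = {
        "n_total": int(len(table)),
        "n_expressed": int(table["expressed"].sum()),
        "n_regulated": int((table["expressed"] & table["regulated"]).sum()),
        "n_significant": int(table["candidate"].sum()),
    }
    log.info(
        "select_candidates[%s]: %d -> %d expressed -> %d regulated -> "
        "%d significant",
        layer, funnel["n_total"], funnel["n_expressed"],
        funnel["n_regulated"], funnel["n_significant"],
    )
    return table.reset_index(drop=True), funnel


def volcano_table(candidates: pd.DataFrame) -> pd.DataFrame:
    """log2 mean FC and -log10 p per feature, for volcano plots."""
    with np.errstate(divide="ignore"):
        return pd.DataFrame(
            {
                "feature": candidates["feature"],
                "log2_mean_fc": np.log2(candidates["mean_fc"]),
                "neg_log10_p": -np.log10(candidates["p_value"]),
                "candidate": candidates["candidate"],
                "direction": candidates["direction"],
            }
        )


def timecourse_compare(
    confluence_a: pd.DataFrame,
    confluence_b: pd.DataFrame,
    f_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-timepoint comparison of two wound-confluence timecourses.

    Inputs are replicate x timepoint tables on the same time grid with at
    least 3 replicates per arm. At each timepoint a two-sided variance-ratio
    F-test chooses between the pooled-variance t-test (variances compatible)
    and Welch's t-test; the chosen test's two-sided p is returned together
    with the route taken.
    """
    if list(confluence_a.columns) != list(confluence_b.columns):
        raise ValueError("timecourses must share an identical time grid")
    if len(confluence_a) < 3 or len(confluence_b) < 3:
        raise ValueError("need at least 3 replicates per arm")
    rows = []
    for t in confluence_a.columns:
        a = confluence_a[t].to_numpy(dtype=float)
        b = confluence_b[t].to_numpy(dtype=float)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va == 0 and vb == 0:
            f_p = 1.0
        else:
            big, nb_, small, ns_ = (
                (va, len(a), vb, len(b)) if va >= vb else (vb, len(b), va, len(a))
            )
            ratio = np.inf if small == 0 else big / small
            f_p = 2.0 * min(
                stats.f.sf(ratio, nb_ - 1, ns_ - 1),
                stats.f.cdf(ratio, nb_ - 1, ns_ - 1),
            )
            f_p = min(f_p, 1.0)
        equal_var = f_p >= f_alpha
        t_p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
        rows.append(
            {"timepoint": t, "f_p": f_p,
             "test": "pooled" if equal_var else "welch",
             "p_value": float(t_p)}
        )
    return pd.DataFrame(rows)
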