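"""Two-stage proteomics normalization for multi-plex TMT screens.

Stage 1 aligns each sample's intensity distribution to a reference sample
via a linear model fitted on 11 quantiles (25% to 75% in steps of 5%).
Stage 2 removes between-plex batch effects using the pooled reference
sample carried in 2 of the 10 channels of every plex: per protein and plex,
a correction factor is the ratio of that plex's reference mean to the grand
reference mean over all plexes, and the whole plex is divided by it.

All computation happens on log2 intensities; the reference correction is a
subtraction of log factors, equivalent to division on the linear scale, and
the grand mean is arithmetic in log space (geometric on the linear scale).
Missing values are excluded, never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .matrix import OmicsMatrix, PlexDesign

log = logging.getLogger("migexpress")

QUANTILE_LEVELS = np.round(np.arange(0.25, 0.7501, 0.05), 2)  # 11 levels


@dataclass
class QuantileAlignment:
    """Per-sample affine fit of the anchor sample's quantiles on the
    sample's own quantiles; ``table`` has columns sample, group, slope,
    intercept; ``quantiles`` stores the pre-alignment quantiles."""

    table: pd.DataFrame
    quantiles: pd.DataFrame
    levels: np.ndarray


def sample_quantiles(values: pd.Series) -> np.ndarray:
    """The 11 alignment quantiles of one sample's non-missing log
    intensities (linear interpolation between order statistics)."""
    obs = values.dropna().to_numpy()
    if obs.size < len(QUANTILE_LEVELS):
        raise ValueError(
            f"sample {values.name!r} has {obs.size} non-missing values; "
            f"need at least {len(QUANTILE_LEVELS)} for quantile alignment"
        )
    return np.quantile(obs, QUANTILE_LEVELS)


def quantile_align(
    matrix: OmicsMatrix, groups: dict | None = None
) -> tuple[OmicsMatrix, QuantileAlignment]:
    """Align each sample's intensity distribution to the first sample.

    For sample s with quantile vector q_s, fit q_first ~ a_s + b_s * q_s by
    least squares and transform all of s's values by x -> a_s + b_s * x.
    The anchor (first) sample is unchanged. With ``groups`` (name ->
    list of sample ids, e.g. plex -> channels), alignment runs separately
    within each group, anchored at the group's first sample, so that
    between-group differences survive for the reference correction stage.
    """
    mat = matrix.to_log2() if matrix.scale == "linear" else matrix
    values = mat.values
    if values.shape[1] < 2:
        raise ValueError("quantile alignment requires at least 2 samples")
    if groups is None:
        groups = {"all": list(values.columns)}
    aligned = values.copy()
    rows, qrows = [], {}
    for group, samples in groups.items():
        anchor = samples[0]
        q_anchor = sample_quantiles(values[anchor])
        for sample in samples:
            q_s = sample_quantiles(values[sample])
            if np.ptp(q_s) == 0:
                raise ValueError(
                    f"degenerate sample {sample!r}: zero quantile spread"
                )
            slope, intercept = np.polyfit(q_s, q_anchor, 1)
            if slope <= 0:
                raise ValueError(
                    f"non-positive alignment slope for sample {sample!r}"
                )
            aligned[sample] = intercept + slope * values[sample]
            rows.append(
                {"sample": sample, "group": group,
                 "slope": slope, "intercept": intercept}
            )
            qrows[sample] = q_s
    report = QuantileAlignment(
        table=pd.DataFrame(rows),
        quantiles=pd.DataFrame(qrows, index=QUANTILE_LEVELS),
        levels=QUANTILE_LEVELS.copy(),
    )
    out = replace(mat, values=aligned, scale="log2")
    return out, report


def reference_correct(
    matrix: OmicsMatrix, design: PlexDesign
) -> tuple[OmicsMatrix, pd.DataFrame, pd.Series]:
    """Cross-plex correction using the pooled reference channels.

    On the log2 scale: for protein p and plex k, the log factor is
    mean(reference values of p in plex k) minus the grand mean of the
    per-plex reference means of p; all of plex k's values of p (reference
    channels included) are shifted down by it. Proteins without a reference
    measurement in some plex are left unchanged in that plex; proteins
    absent from every reference are flagged and not corrected at all.

    Returns (corrected matrix, log2 factors [proteins x plexes],
    boolean flags of uncorrectable proteins).
    """
    mat = matrix.to_log2() if matrix.scale == "linear" else matrix
    values = mat.values
    missing_samples = set(design.table["sample"]) - set(values.columns)
    if missing_samples:
        raise ValueError(
            f"plex design samples absent from matrix: {sorted(missing_samples)}"
        )
    unassigned = set(values.columns) - set(design.table["sample"])
    if unassigned:
        raise ValueError(
            f"matrix samples without a plex assignment: {sorted(unassigned)}"
        )
    plexes = design.plexes
    ref_means = pd.DataFrame(
        {k: values[design.reference_samples(k)].mean(axis=1) for k in plexes}
    )
    grand = ref_means.mean(axis=1)  # arithmetic in log space
    factors = ref_means.sub(grand, axis=0)
    never_referenced = ref_means.isna().all(axis=1)
    corrected = values.copy()
    for k in plexes:
        shift = factors[k].fillna(0.0)  # missing-in-this-plex: unchanged
        corrected[design.plex_samples(k)] = values[design.plex_samples(k)].sub(
            shift, axis=0
        )
    n_flagged = int(never_referenced.sum())
    if n_flagged:
        log.warning(
            "reference_correct: %d proteins absent from all reference "
            "channels were left uncorrected", n_flagged,
        )
    out = replace(mat, values=corrected, scale="log2")
    return out, factors, never_referenced


def detection_filter(matrix: OmicsMatrix, min_frac: float) -> OmicsMatrix:
    """Keep features with a measurable signal in at least
    ceil(min_frac * n_lines) lines."""
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    needed = math.ceil(min_frac * matrix.n_lines)
    detected = matrix.detection_mask().sum(axis=1)
    keep = matrix.features[detected >= needed]
    out = matrix.subset_features(keep)
    log.info(
        "detection_filter: %d features in, %d kept (>= %d of %d lines)",
        matrix.n_features, out.n_features, needed, matrix.n_lines,
    )
    return out


def normalize_tmt(
    matrix: OmicsMatrix,
    design: PlexDesign,
    align: str = "per_plex",
) -> tuple[OmicsMatrix, QuantileAlignment, pd.DataFrame]:
    """Full normalization: within-plex quantile alignment, then cross-plex
    reference correction. ``align='joint'`` aligns all samples to the first
    sample across plexes instead (which also absorbs plex-level batch
    shifts, leaving near-unit correction factors).

    Returns (normalized log2 matrix incl. reference columns, alignment
    report, log2 correction factors).
    """
    if align == "per_plex":
        groups = {k: design.plex_samples(k) for k in design.plexes}
    elif align == "joint":
        groups = None
    else:
        raise ValueError("align must be 'per_plex' or 'joint'")
    aligned, report = quantile_align(matrix, groups=groups)
    corrected, factors, _ = reference_correct(aligned, design)
    return corrected, report, factors


def drop_reference_columns(matrix: OmicsMatrix, design: PlexDesign) -> OmicsMatrix:
    """Restrict a proteomics matrix to cell-line columns, renaming samples
    to their cell-line ids."""
    t = design.table[~design.table["is_reference"]]
    sub = matrix.values[list(t["sample"])].copy()
    sub.columns = list(t["cell_line"])
    return OmicsMatrix(values=sub, layer=matrix.layer, scale=matrix.scale)
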