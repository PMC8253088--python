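"""Reading and writing the pipeline's tabular formats.

Conventions: omics matrices are TSV (first column feature id, header row of
cell-line ids; empty fields are missing, permitted only for protein layers).
Migration tables are CSV with columns cell_line, coating, replicate,
percent_migration, timepoint_h. Candidate tables round-trip losslessly
through TSV.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from .config import COATINGS
from .matrix import MISSING_ALLOWED, OmicsMatrix, PlexDesign

log = logging.getLogger("migexpress")

CANDIDATE_COLUMNS = [
    "feature",
    "fc_uncoated",
    "fc_collagen",
    "fc_fibronectin",
    "mean_fc",
    "p_value",
    "q_value",
    "direction",
    "expressed",
    "regulated",
    "significant",
    "candidate",
    "layer",
]


def read_matrix(path, layer: str, scale: str = "linear") -> OmicsMatrix:
    """Parse a delimited feature x cell-line table into a validated matrix.

    Raises ``ValueError`` on duplicate ids, negative linear values, or a
    non-numeric cell (named by row and column).
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            row = raw.index[bad][0]
            raise ValueError(
                f"non-numeric value {raw.loc[row, col]!r} at row {row!r}, "
                f"column {col!r} in {path}"
            )
        values[col] = parsed
    if values.isna().any().any() and layer not in MISSING_ALLOWED:
        i, j = np.argwhere(values.isna().to_numpy())[0]
        cell = (values.index[i], values.columns[j])
        raise ValueError(f"empty value at {cell} not allowed for layer {layer!r}")
    values.index.name = None  # the container carries no axis names
    mat = OmicsMatrix(values=values, layer=layer, scale=scale)
    log.info(
        "read_matrix: parsed %d features x %d cell lines (%s) from %s",
        mat.n_features, mat.n_lines, layer, path,
    )
    return mat


def write_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature", na_rep="")


def read_migration_table(path) -> pd.DataFrame:
    """Read a per-replicate migration assay CSV and validate its contents."""
    table = pd.read_csv(path)
    required = {"cell_line", "coating", "replicate", "percent_migration", "timepoint_h"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"migration table missing columns: {sorted(missing)}")
    unknown = set(table["coating"]) - set(COATINGS)
    if unknown:
        raise ValueError(f"unknown coatings in migration table: {sorted(unknown)}")
    pct = table["percent_migration"].astype(float)
    if pct.isna().any():
        raise ValueError("percent_migration contains missing values")
    n_clipped = int(((pct < 0) | (pct > 100)).sum())
    if n_clipped:
        log.warning("clipping %d percent_migration values into [0, 100]", n_clipped)
    table["percent_migration"] = pct.clip(0.0, 100.0)
    return table


def write_migration_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_plex_design(path, **kwargs) -> PlexDesign:
    table = pd.read_csv(path, sep="\t")
    table["is_reference"] = table["is_reference"].astype(bool)
    table["cell_line"] = table["cell_line"].fillna("")
    return PlexDesign(table=table, **kwargs)


def write_plex_design(design: PlexDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def write_candidates(table: pd.DataFrame, path) -> None:
    """Write a candidate table as TSV; round-trips through read_candidates."""
    missing = set(CANDIDATE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    table[CANDIDATE_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_candidates(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("expressed", "regulated", "significant", "candidate"):
        table[col] = table[col].astype(bool)
    if len(table) == 0:
        # header-only file: restore dtypes lost to an empty frame
        table = table.astype(
            {c: float for c in ("fc_uncoated", "fc_collagen", "fc_fibronectin",
                                "mean_fc", "p_value", "q_value")}
        )
    return table


def write_run_summary(summary: dict, path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_default)
        fh.write("\n")
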