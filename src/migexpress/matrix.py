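"""Validated in-memory containers for omics matrices and plex designs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LAYERS = ("rna", "protein", "circ_gene", "circ_bs")
SCALES = ("linear", "log2")

#: Layers in which missing values (NaN) are permitted. Protein intensities
#: below the MS detection limit are genuinely unobserved; RNA FPKM and
#: circRNA counts are always quantified (possibly as 0).
MISSING_ALLOWED = ("protein",)


@dataclass
class OmicsMatrix:
    """A features x cell-lines abundance matrix with a layer and scale tag.

    ``values`` is a float DataFrame indexed by feature id with cell-line
    columns; NaN marks a missing measurement (protein layers only).
    ``detected`` is an optional boolean mask of the same shape used by
    count-based layers, where a stored 0 is a real observation but counts
    as "not detected" for the detection filter.
    """

    values: pd.DataFrame
    layer: str
    scale: str = "linear"
    detected: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer tag: {self.layer!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale tag: {self.scale!r}")
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate cell-line id: {dup!r}")
        if self.values.isna().any().any() and self.layer not in MISSING_ALLOWED:
            raise ValueError(f"missing values not allowed in layer {self.layer!r}")
        if self.scale == "linear" and (self.values < 0).any().any():
            bad = self.values.stack()
            bad = bad[bad < 0].index[0]
            raise ValueError(f"negative linear-scale value at {bad}")
        if self.detected is not None:
            if not self.detected.index.equals(self.values.index) or not (
                self.detected.columns.equals(self.values.columns)
            ):
                raise ValueError("detected mask must share the matrix axes")
            self.detected = self.detected.astype(bool)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def lines(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_lines(self) -> int:
        return self.values.shape[1]

    def detection_mask(self) -> pd.DataFrame:
        """Boolean mask of measurable signals (non-missing and, where a
        detection mask exists, detected)."""
        mask = self.values.notna()
        if self.detected is not None:
            mask &= self.detected
        return mask

    def subset_features(self, ids) -> "OmicsMatrix":
        detected = self.detected.loc[ids] if self.detected is not None else None
        return replace(self, values=self.values.loc[ids], detected=detected)

    def to_log2(self, pseudocount: float = 0.0) -> "OmicsMatrix":
        if self.scale == "log2":
            return self
        return replace(
            self,
            values=np.log2(self.values + pseudocount),
            scale="log2",
            detected=self.detected,
        )


@dataclass
class PlexDesign:
    """TMT plex/channel layout for a proteomics run.

    ``table`` has one row per labelled sample with columns ``sample``
    (matrix column id), ``plex``, ``channel``, ``is_reference`` and
    ``cell_line`` (empty for reference channels). Each plex carries
    ``plex_size`` channels of which ``n_reference`` hold the pooled
    reference sample.
    """

    table: pd.DataFrame
    plex_size: int = 10
    n_reference: int = 2
    reference_note: str = "pooled reference sample shared by all plexes"

    def __post_init__(self) -> None:
        required = {"sample", "plex", "channel", "is_reference", "cell_line"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"plex design missing columns: {sorted(missing)}")
        if self.table["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in plex design")
        for plex, grp in self.table.groupby("plex"):
            n_ref = int(grp["is_reference"].sum())
            if n_ref != self.n_reference:
                raise ValueError(
                    f"plex {plex!r} has {n_ref} reference channels, "
                    f"expected {self.n_reference}"
                )
            if len(grp) > self.plex_size:
                raise ValueError(f"plex {plex!r} exceeds {self.plex_size} channels")

    @property
    def plexes(self) -> list:
        return sorted(self.table["plex"].unique())

    def reference_samples(self, plex) -> list[str]:
        t = self.table
        return list(t.loc[(t["plex"] == plex) & t["is_reference"], "sample"])

    def plex_samples(self, plex, include_reference: bool = True) -> list[str]:
        t = self.table[self.table["plex"] == plex]
        if not include_reference:
            t = t[~t["is_reference"]]
        return list(t["sample"])

    def plex_of(self) -> pd.Series:
        """sample id -> plex id."""
        return self.table.set_index("sample")["plex"]

    def line_to_sample(self) -> pd.Series:
        t = self.table[~self.table["is_reference"]]
        return t.set_index("cell_line")["sample"]
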