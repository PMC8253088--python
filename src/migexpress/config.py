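"""Run configuration: classification thresholds and candidate-filter cutoffs.

Defaults reproduce the screen's published cutoffs: fast thresholds of
60/75/60 % migration (uncoated / collagen / fibronectin), slow below 25 %;
RNA candidates need mean FPKM >= 1, mean fold change >= 3 and Welch
P < 0.05; protein candidates need detection in >= 50 % of lines, fold
change >= 2 and P < 0.05; circRNA candidates mirror RNA but use a
detection filter instead of an expression floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

CONFIG_SCHEMA_VERSION = 1

COATINGS = ("uncoated", "collagen", "fibronectin")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Percent-migration cutoffs defining fast and slow classes per coating.

    Comparisons are strict: a line is fast on a coating when its mean
    % migration is strictly above that coating's fast threshold, slow when
    strictly below ``slow_all``, and medium otherwise.
    """

    fast_uncoated: float = 60.0
    fast_collagen: float = 75.0
    fast_fibronectin: float = 60.0
    slow_all: float = 25.0

    def __post_init__(self) -> None:
        for name in ("fast_uncoated", "fast_collagen", "fast_fibronectin"):
            if self.slow_all >= getattr(self, name):
                raise ValueError(
                    f"slow_all ({self.slow_all}) must be below {name} "
                    f"({getattr(self, name)})"
                )

    def fast_threshold(self, coating: str) -> float:
        try:
            return {
                "uncoated": self.fast_uncoated,
                "collagen": self.fast_collagen,
                "fibronectin": self.fast_fibronectin,
            }[coating]
        except KeyError:
            raise ValueError(f"unknown coating: {coating!r}") from None


@dataclass(frozen=True)
class FilterSet:
    """One layer's candidate-funnel cutoffs.

    ``min_expr`` is an expression floor on the per-feature mean (FPKM for
    RNA); ``min_detect_frac`` is the minimum fraction of lines with a
    measurable signal (protein / circRNA); a layer uses one or the other.
    """

    min_fc: float
    alpha: float
    min_expr: float | None = None
    min_detect_frac: float | None = None

    def __post_init__(self) -> None:
        if self.min_fc <= 0:
            raise ValueError("min_fc must be strictly positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_expr is not None and self.min_expr <= 0:
            raise ValueError("min_expr must be strictly positive")
        if self.min_detect_frac is not None and not 0 < self.min_detect_frac <= 1:
            raise ValueError("min_detect_frac must be in (0, 1]")


@dataclass(frozen=True)
class RunConfig:
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    rna_filters: FilterSet = field(
        default_factory=lambda: FilterSet(min_fc=3.0, alpha=0.05, min_expr=1.0)
    )
    protein_filters: FilterSet = field(
        default_factory=lambda: FilterSet(min_fc=2.0, alpha=0.05, min_detect_frac=0.5)
    )
    circ_filters: FilterSet = field(
        default_factory=lambda: FilterSet(min_fc=3.0, alpha=0.05, min_detect_frac=0.5)
    )
    pseudocount: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be strictly positive")

    def to_yaml(self, path) -> None:
        doc = {"schema_version": CONFIG_SCHEMA_VERSION, **asdict(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        version = doc.pop("schema_version", None)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema_version: {version!r}")
        thresholds = ClassificationThresholds(**doc.pop("thresholds", {}))
        filters = {
            key: FilterSet(**doc.pop(key))
            for key in ("rna_filters", "protein_filters", "circ_filters")
            if key in doc
        }
        return cls(thresholds=thresholds, **filters, **doc)
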