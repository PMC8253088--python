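"""Synthetic migration screen with known ground truth.

Generates the full data structure of a 54-cell-line migration screen:
per-replicate % migration on three coating surfaces drawn so each line
lands in a designated fast/medium/slow class under the classification
thresholds; a lognormal RNA abundance matrix with planted signed log2
fold-change effects on a migration-associated gene subset; TMT-style
protein intensities sharing (attenuated) effects with the RNA layer, with
per-plex multiplicative batch effects, pooled-reference channels and
intensity-dependent missingness; Poisson back-splice counts proportional to
library size; and an independent proliferation table.

Planted effect magnitudes are drawn from a normal distribution truncated
below at the screen's fold-change cutoff, so that "migration-associated"
means regulated at at least the magnitude the candidate funnel targets.
All randomness flows through one seeded generator, making every output
bit-reproducible from the spec's seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .circrna import BackspliceTable
from .config import COATINGS, ClassificationThresholds
from .matrix import OmicsMatrix, PlexDesign

log = logging.getLogger("migexpress")

#: latent speed score entering expression effects: fast lines carry the
#: full planted effect relative to slow lines, medium lines half of it
SPEED_SCORE = {"fast": 1.0, "medium": 0.5, "slow": 0.0}


@dataclass(frozen=True)
class SimulationSpec:
    n_lines: int = 54
    n_fast: int = 18
    n_medium: int = 10
    n_slow: int = 26
    n_genes: int = 2000
    n_proteins: int = 1500
    n_circ: int = 300
    frac_migration_assoc: float = 0.05
    effect_log2fc_mean: float = 2.0
    effect_log2fc_sd: float = 0.5
    min_effect_log2fc: float = float(np.log2(3.0))
    replicate_noise_sd: float = 3.0
    n_replicates: int = 3
    expr_noise_sd: float = 0.5
    protein_attenuation: float = 0.8
    attenuation_noise_sd: float = 1.3
    plex_size: int = 10
    n_ref_channels_per_plex: int = 2
    plex_batch_log_sd: float = 0.3
    ref_channel_noise_sd: float = 0.1
    missing_midpoint_log2: float = 18.0
    missing_slope: float = 1.0
    library_size_range: tuple = (2.0e7, 6.0e7)
    thresholds: ClassificationThresholds = field(
        default_factory=ClassificationThresholds
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fast + self.n_medium + self.n_slow != self.n_lines:
            raise ValueError("class targets must sum to n_lines")
        if not 0 <= self.frac_migration_assoc < 1:
            raise ValueError("frac_migration_assoc must be in [0, 1)")
        for name in ("replicate_noise_sd", "expr_noise_sd", "plex_batch_log_sd",
                     "ref_channel_noise_sd", "attenuation_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per (line, coating)")
        if self.n_proteins > self.n_genes:
            raise ValueError("n_proteins cannot exceed n_genes")


@dataclass
class GroundTruth:
    """What was planted: per-line latent speed and class, and the signed
    true log2 fold change of every migration-associated feature per layer."""

    lines: pd.DataFrame            # line, true_class, latent_u, speed_score
    planted_rna: pd.DataFrame      # feature, true_log2fc
    planted_protein: pd.DataFrame
    planted_circ: pd.DataFrame
    plex_batch_log2: pd.Series     # plex -> injected log2 batch factor


@dataclass
class SimulatedScreen:
    migration: pd.DataFrame
    rna: OmicsMatrix
    protein: OmicsMatrix          # includes reference-channel columns
    plex_design: PlexDesign
    circ: BackspliceTable
    proliferation: pd.Series
    truth: GroundTruth


def _class_windows(spec: SimulationSpec) -> dict:
    """Per-coating sampling windows of latent mean % migration that keep a
    line strictly inside its designated class, with a margin against
    replicate noise. Raises if noise makes a window empty."""
    thr = spec.thresholds
    margin = max(2.0, 2.0 * spec.replicate_noise_sd)
    windows = {}
    for coating in COATINGS:
        fast_thr = thr.fast_threshold(coating)
        w = {
            "fast": (fast_thr + margin, 98.0),
            "medium": (thr.slow_all + margin, fast_thr - margin),
            "slow": (2.0, thr.slow_all - margin),
        }
        for cls, (lo, hi) in w.items():
            if lo >= hi:
                raise ValueError(
                    f"infeasible class target: {cls!r} window on {coating} is "
                    f"empty with replicate_noise_sd={spec.replicate_noise_sd}"
                )
        windows[coating] = w
    return windows


def _truncated_effects(n: int, spec: SimulationSpec, rng) -> np.ndarray:
    """Signed planted log2 fold changes: magnitude ~ N(mean, sd) truncated
    below at min_effect_log2fc, sign uniform."""
    a = (spec.min_effect_log2fc - spec.effect_log2fc_mean) / spec.effect_log2fc_sd
    mag = stats.truncnorm.rvs(
        a, np.inf, loc=spec.effect_log2fc_mean, scale=spec.effect_log2fc_sd,
        size=n, random_state=rng,
    )
    sign = rng.choice([-1.0, 1.0], size=n)
    return sign * mag


def _simulate_migration(spec: SimulationSpec, lines: pd.DataFrame, rng):
    windows = _class_windows(spec)
    rows = []
    latent = {}
    for _, line in lines.iterrows():
        for coating in COATINGS:
            lo, hi = windows[coating][line["true_class"]]
            mean48 = lo + line["latent_u"] * (hi - lo)
            latent[(line["line"], coating)] = mean48
            for tp, scale in ((24, 0.6), (48, 1.0)):
                noise = rng.normal(0.0, spec.replicate_noise_sd, spec.n_replicates)
                for rep, eps in enumerate(noise, start=1):
                    rows.append(
                        {
                            "cell_line": line["line"],
                            "coating": coating,
                            "replicate": rep,
                            "percent_migration": float(
                                np.clip(scale * mean48 + eps, 0.0, 100.0)
                            ),
                            "timepoint_h": tp,
                        }
                    )
    return pd.DataFrame(rows), latent


def _plex_design(spec: SimulationSpec, line_ids: list, rng) -> PlexDesign:
    per_plex = spec.plex_size - spec.n_ref_channels_per_plex
    n_plex = int(np.ceil(len(line_ids) / per_plex))
    rows = []
    order = list(rng.permutation(line_ids))
    for k in range(n_plex):
        plex = f"plex{k + 1}"
        members = order[k * per_plex:(k + 1) * per_plex]
        channel = 1
        for r in range(spec.n_ref_channels_per_plex):
            rows.append(
                {"sample": f"{plex}_ref{r + 1}", "plex": plex,
                 "channel": f"ch{channel:02d}", "is_reference": True,
                 "cell_line": ""}
            )
            channel += 1
        for line in members:
            rows.append(
                {"sample": line, "plex": plex, "channel": f"ch{channel:02d}",
                 "is_reference": False, "cell_line": line}
            )
            channel += 1
    return PlexDesign(
        table=pd.DataFrame(rows),
        plex_size=spec.plex_size,
        n_reference=spec.n_ref_channels_per_plex,
        reference_note="pooled sample of all screen lines (synthetic)",
    )


def inject_batch_effect(
    matrix: OmicsMatrix, design: PlexDesign, log_sd: float, rng=None
) -> tuple[OmicsMatrix, pd.Series]:
    """Multiply each plex's intensities by its own lognormal factor
    (reference channels included). Returns the perturbed matrix and the
    injected log2 factors per plex."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    unassigned = set(matrix.lines) - set(design.table["sample"])
    if unassigned:
        raise ValueError(f"samples without plex assignment: {sorted(unassigned)}")
    factors = pd.Series(
        rng.normal(0.0, log_sd, len(design.plexes)), index=design.plexes
    )
    values = matrix.values.copy()
    for plex, f in factors.items():
        samples = [s for s in design.plex_samples(plex) if s in values.columns]
        if matrix.scale == "log2":
            values[samples] = values[samples] + f
        else:
            values[samples] = values[samples] * 2.0**f
    return replace(matrix, values=values), factors


def simulate_screen(spec: SimulationSpec) -> SimulatedScreen:
    """Generate one complete synthetic screen; bit-reproducible from seed."""
    rng = np.random.default_rng(spec.seed)

    classes = (
        ["fast"] * spec.n_fast + ["medium"] * spec.n_medium + ["slow"] * spec.n_slow
    )
    line_ids = [f"CL{i + 1:02d}" for i in range(spec.n_lines)]
    lines = pd.DataFrame(
        {
            "line": line_ids,
            "true_class": classes,
            "latent_u": rng.uniform(0.0, 1.0, spec.n_lines),
        }
    )
    lines["speed_score"] = lines["true_class"].map(SPEED_SCORE)

    migration, _ = _simulate_migration(spec, lines, rng)
    score = lines.set_index("line")["speed_score"].loc[line_ids].to_numpy()

    # --- RNA layer: lognormal FPKM with planted effects -------------------
    gene_ids = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    baseline = rng.normal(3.0, 2.0, spec.n_genes)  # log2 FPKM
    n_planted = int(round(spec.frac_migration_assoc * spec.n_genes))
    rna_effect = np.zeros(spec.n_genes)
    eligible = np.flatnonzero(baseline >= 2.0)  # planted genes are expressed
    if n_planted > eligible.size:
        raise ValueError("not enough well-expressed genes to plant effects in")
    planted_idx = rng.choice(eligible, size=n_planted, replace=False)
    rna_effect[planted_idx] = _truncated_effects(n_planted, spec, rng)

    log2_fpkm = (
        baseline[:, None]
        + rna_effect[:, None] * score[None, :]
        + rng.normal(0.0, spec.expr_noise_sd, (spec.n_genes, spec.n_lines))
    )
    rna = OmicsMatrix(
        values=pd.DataFrame(2.0**log2_fpkm, index=gene_ids, columns=line_ids),
        layer="rna",
    )

    # --- protein layer: shared, attenuated effects + TMT structure --------
    prot_pos = rng.choice(spec.n_genes, size=spec.n_proteins, replace=False)
    prot_pos.sort()
    prot_ids = [gene_ids[i] for i in prot_pos]
    prot_effect = np.zeros(spec.n_proteins)
    shared = np.isin(prot_pos, planted_idx)
    e = rna_effect[prot_pos[shared]]
    mag = np.abs(
        spec.protein_attenuation * np.abs(e)
        + rng.normal(0.0, spec.attenuation_noise_sd, e.size)
    )
    prot_effect[shared] = np.sign(e) * mag  # same sign as RNA by construction

    prot_baseline = rng.normal(20.0, 2.0, spec.n_proteins)  # log2 intensity
    clean = (
        prot_baseline[:, None]
        + prot_effect[:, None] * score[None, :]
        + rng.normal(0.0, spec.expr_noise_sd, (spec.n_proteins, spec.n_lines))
    )
    design = _plex_design(spec, line_ids, rng)
    pooled = clean.mean(axis=1)  # the pooled reference carries the screen mean
    columns = {line: clean[:, j] for j, line in enumerate(line_ids)}
    for plex in design.plexes:
        for ref in design.reference_samples(plex):
            columns[ref] = pooled + rng.normal(
                0.0, spec.ref_channel_noise_sd, spec.n_proteins
            )
    sample_order = list(design.table["sample"])
    prot_log2 = pd.DataFrame(columns, index=prot_ids)[sample_order]
    protein = OmicsMatrix(values=prot_log2, layer="protein", scale="log2")
    protein, batch_factors = inject_batch_effect(
        protein, design, spec.plex_batch_log_sd, rng
    )

    # intensity-dependent missingness (MS detection limit)
    x = protein.values.to_numpy()
    p_missing = 1.0 / (
        1.0 + np.exp(spec.missing_slope * (x - spec.missing_midpoint_log2))
    )
    mask = rng.uniform(size=x.shape) < p_missing
    values = protein.values.mask(pd.DataFrame(
        mask, index=protein.features, columns=protein.lines
    ))
    protein = replace(protein, values=values)

    # --- circRNA layer: Poisson back-splice counts ------------------------
    n_circ_genes = max(1, int(spec.n_circ * 0.7))
    circ_gene_of = rng.integers(0, n_circ_genes, spec.n_circ)
    junction_ids = []
    seen = {}
    for j, g in enumerate(circ_gene_of):
        seen[g] = seen.get(g, 0) + 1
        donor = 2 * seen[g]
        junction_ids.append(f"CIRCG{g + 1:03d}|chr1:e{donor}-e{donor + 3}")
    log2_rate = rng.normal(-2.0, 2.0, spec.n_circ)  # per-million rate
    n_circ_planted = int(round(spec.frac_migration_assoc * spec.n_circ))
    circ_effect = np.zeros(spec.n_circ)
    circ_eligible = np.flatnonzero(log2_rate >= -1.0)
    if n_circ_planted > circ_eligible.size:
        raise ValueError("not enough detectable junctions to plant effects in")
    circ_idx = rng.choice(circ_eligible, size=n_circ_planted, replace=False)
    circ_effect[circ_idx] = _truncated_effects(n_circ_planted, spec, rng)

    lib = rng.uniform(*spec.library_size_range, spec.n_lines)
    rate = (
        2.0 ** (log2_rate[:, None] + circ_effect[:, None] * score[None, :])
        * lib[None, :] / 1e6
    )
    counts = rng.poisson(rate)
    circ = BackspliceTable(
        counts=pd.DataFrame(counts, index=junction_ids, columns=line_ids),
        library_sizes=pd.Series(lib, index=line_ids),
    )

    proliferation = pd.Series(
        np.clip(rng.normal(3.0, 1.0, spec.n_lines), 0.5, None),
        index=line_ids, name="doublings_72h",
    )

    truth = GroundTruth(
        lines=lines,
        planted_rna=pd.DataFrame(
            {"feature": [gene_ids[i] for i in planted_idx],
             "true_log2fc": rna_effect[planted_idx]}
        ),
        planted_protein=pd.DataFrame(
            {"feature": [prot_ids[i] for i in np.flatnonzero(shared)],
             "true_log2fc": prot_effect[shared]}
        ),
        planted_circ=pd.DataFrame(
            {"feature": [junction_ids[i] for i in circ_idx],
             "true_log2fc": circ_effect[circ_idx]}
        ),
        plex_batch_log2=batch_factors,
    )
    log.info(
        "simulate_screen: %d lines, %d genes (%d planted), %d proteins, "
        "%d junctions (%d planted)",
        spec.n_lines, spec.n_genes, n_planted, spec.n_proteins,
        spec.n_circ, n_circ_planted,
    )
    return SimulatedScreen(
        migration=migration, rna=rna, protein=protein, plex_design=design,
        circ=circ, proliferation=proliferation, truth=truth,
    )
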