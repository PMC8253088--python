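"""Parameter-recovery and calibration studies on synthetic screens.

These functions re-run the pipeline on freshly simulated screens with known
ground truth and summarize how well it recovers what was planted: the
sensitivity/FDR of the RNA candidate funnel, the false-positive calibration
of the Welch test under a null screen, the removal of injected TMT batch
effects, and the accuracy of migration classification without noise.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .diffexp import groups_from_classes, select_candidates, welch_test
from .matrix import OmicsMatrix
from .migration import classify_screen
from .pipeline import recovery_metrics
from .simulate import SimulationSpec, simulate_screen
from .tmt import normalize_tmt
from .config import RunConfig


def _seeds(base_seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, n)]


def rna_recovery_study(
    base_seed: int = 0, n_seeds: int = 20, config: RunConfig | None = None
) -> dict:
    """Median sensitivity and empirical FDR of the RNA funnel over freshly
    simulated default screens (classification included in the loop)."""
    config = config or RunConfig()
    sens, fdr = [], []
    for seed in _seeds(base_seed, n_seeds):
        screen = simulate_screen(dataclasses.replace(SimulationSpec(), seed=seed))
        classes = classify_screen(screen.migration, config.thresholds)
        groups = groups_from_classes(classes)
        table, _ = select_candidates(
            screen.rna, groups, config.rna_filters,
            pseudocount=config.pseudocount, layer="rna",
        )
        rec = recovery_metrics(table, screen.truth.planted_rna)
        sens.append(rec["sensitivity"])
        fdr.append(rec["fdr"])
    return {
        "n_seeds": n_seeds,
        "median_sensitivity": float(np.median(sens)),
        "median_fdr": float(np.median(fdr)),
        "sensitivity": sens,
        "fdr": fdr,
    }


def null_calibration_study(
    base_seed: int = 0, n_seeds: int = 50, alpha: float = 0.05
) -> dict:
    """Mean fraction of features with Welch p < alpha on screens with no
    planted effects (should match alpha)."""
    fractions = []
    for seed in _seeds(base_seed, n_seeds):
        spec = dataclasses.replace(
            SimulationSpec(), seed=seed, frac_migration_assoc=0.0
        )
        screen = simulate_screen(spec)
        groups = groups_from_classes(classify_screen(screen.migration))
        p = welch_test(
            screen.rna.to_log2(0.01), groups.overall_fast, groups.overall_slow
        )
        fractions.append(float((p < alpha).mean()))
    return {
        "n_seeds": n_seeds,
        "alpha": alpha,
        "mean_fraction": float(np.mean(fractions)),
        "fractions": fractions,
    }


def tmt_batch_removal_study(base_seed: int = 0, n_seeds: int = 20) -> dict:
    """Run the normalization on default screens with injected per-plex
    batch factors and measure (a) the reduction in plex-level mean variance
    and (b) the correlation of recovered vs injected (mean-centered) log2
    factors; both summarized as medians over seeds."""
    reductions, rs = [], []
    for seed in _seeds(base_seed, n_seeds):
        screen = simulate_screen(dataclasses.replace(SimulationSpec(), seed=seed))
        design = screen.plex_design
        normalized, _, factors = normalize_tmt(screen.protein, design)

        def plex_mean_var(mat: OmicsMatrix) -> float:
            means = [
                float(mat.values[design.plex_samples(p, include_reference=False)]
                      .stack().mean())
                for p in design.plexes
            ]
            return float(np.var(means))

        var_before = plex_mean_var(screen.protein)
        var_after = plex_mean_var(normalized)
        reductions.append(1.0 - var_after / var_before)
        injected = screen.truth.plex_batch_log2
        centered = injected - injected.mean()
        recovered = factors.median(axis=0)
        rs.append(float(np.corrcoef(recovered[centered.index], centered)[0, 1]))
    return {
        "n_seeds": n_seeds,
        "median_variance_reduction": float(np.median(reductions)),
        "median_factor_recovery_r": float(np.median(rs)),
        "variance_reduction": reductions,
        "factor_recovery_r": rs,
    }


def welch_permutation_agreement(
    seed: int = 0, n_features: int = 10, n_perm: int = 10_000
) -> dict:
    """Maximum absolute difference between the Welch p-value and a
    permutation p-value of the Welch statistic on 9-vs-9 normal fixtures
    with moderate shifts."""
    rng = np.random.default_rng(seed)
    data = rng.normal(0.0, 1.0, (n_features, 18))
    data[: n_features // 2, :9] += rng.uniform(0.3, 1.2, (n_features // 2, 1))
    lines = [f"L{i}" for i in range(18)]
    fast, slow = lines[:9], lines[9:]
    import pandas as pd

    mat = OmicsMatrix(
        values=pd.DataFrame(data, index=[f"F{i}" for i in range(n_features)],
                            columns=lines),
        layer="rna", scale="log2",
    )
    p_welch = welch_test(mat, fast, slow).to_numpy()

    def welch_t(a, b):
        va = a.var(ddof=1, axis=-1) / a.shape[-1]
        vb = b.var(ddof=1, axis=-1) / b.shape[-1]
        return (a.mean(-1) - b.mean(-1)) / np.sqrt(va + vb)

    t_obs = welch_t(data[:, :9], data[:, 9:])
    exceed = np.zeros(n_features)
    for _ in range(n_perm):
        perm = rng.permutation(18)
        t_p = welch_t(data[:, perm[:9]], data[:, perm[9:]])
        exceed += np.abs(t_p) >= np.abs(t_obs)
    p_perm = exceed / n_perm
    return {
        "n_perm": n_perm,
        "max_abs_diff": float(np.max(np.abs(p_welch - p_perm))),
    }


def consensus_accuracy_noise_free(seed: int = 0) -> dict:
    """Fraction of lines whose consensus class equals the designated class
    on a replicate-noise-free screen (should be 1.0)."""
    spec = dataclasses.replace(
        SimulationSpec(), seed=seed, replicate_noise_sd=0.0,
        n_genes=50, n_proteins=20, n_circ=20,
    )
    screen = simulate_screen(spec)
    classes = classify_screen(screen.migration, spec.thresholds)
    truth = screen.truth.lines.set_index("line")["true_class"]
    accuracy = float((classes["consensus"] == truth.loc[classes.index]).mean())
    return {"n_lines": len(classes), "accuracy": accuracy}
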