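"""TMT quantile alignment, reference-channel correction, detection filter."""

import numpy as np
import pandas as pd
import pytest

import migexpress as mx
from migexpress.tmt import QUANTILE_LEVELS, drop_reference_columns, sample_quantiles

from conftest import make_matrix


def _log_matrix(columns: dict) -> mx.OmicsMatrix:
    return mx.OmicsMatrix(values=pd.DataFrame(columns), layer="protein",
                          scale="log2")


def test_eleven_quantile_levels():
    assert len(QUANTILE_LEVELS) == 11
    assert QUANTILE_LEVELS[0] == 0.25 and QUANTILE_LEVELS[-1] == 0.75
    assert np.allclose(np.diff(QUANTILE_LEVELS), 0.05)


def test_quantile_align_identical_sample_is_identity():
    rng = np.random.default_rng(0)
    base = rng.normal(20, 2, 200)
    mat = _log_matrix({"s1": base, "s2": base.copy()})
    aligned, report = mx.quantile_align(mat)
    row = report.table.set_index("sample").loc["s2"]
    assert row["slope"] == pytest.approx(1.0, abs=1e-9)
    assert row["intercept"] == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(aligned.values["s2"], base, atol=1e-9)


def test_quantile_align_recovers_affine_shift():
    """A sample equal to the first shifted by +c aligns back exactly."""
    rng = np.random.default_rng(1)
    base = rng.normal(20, 2, 500)
    c = 1.7
    mat = _log_matrix({"s1": base, "s2": base + c})
    aligned, report = mx.quantile_align(mat)
    row = report.table.set_index("sample").loc["s2"]
    assert row["slope"] == pytest.approx(1.0, abs=1e-6)
    assert row["intercept"] == pytest.approx(-c, abs=1e-6)
    np.testing.assert_allclose(aligned.values["s2"], base, atol=1e-6)


def test_quantile_align_matches_quantiles_for_lognormal_family():
    """Samples that are affine transforms of a common base distribution end
    up with identical alignment quantiles (within 1e-6)."""
    rng = np.random.default_rng(2)
    z = rng.normal(0, 1, 400)
    mat = _log_matrix({
        "s1": 20 + 2.0 * z,
        "s2": 17 + 1.2 * z,
        "s3": 23 + 3.1 * z,
    })
    aligned, _ = mx.quantile_align(mat)
    q1 = sample_quantiles(aligned.values["s1"])
    for s in ("s2", "s3"):
        np.testing.assert_allclose(sample_quantiles(aligned.values[s]), q1,
                                   atol=1e-6)


def test_quantile_align_is_idempotent():
    rng = np.random.default_rng(3)
    mat = _log_matrix({f"s{i}": rng.normal(18 + i, 1 + 0.3 * i, 300)
                       for i in range(4)})
    once, _ = mx.quantile_align(mat)
    twice, report = mx.quantile_align(once)
    np.testing.assert_allclose(twice.values, once.values, atol=1e-9)
    assert np.allclose(report.table["slope"], 1.0, atol=1e-9)
    assert np.allclose(report.table["intercept"], 0.0, atol=1e-9)


def test_quantile_align_rejects_degenerate_sample():
    mat = _log_matrix({"s1": np.linspace(10, 20, 50),
                       "flat": np.full(50, 15.0)})
    with pytest.raises(ValueError, match="flat"):
        mx.quantile_align(mat)


def test_quantile_align_requires_enough_values():
    mat = _log_matrix({"s1": np.arange(5.0), "s2": np.arange(5.0) + 1})
    with pytest.raises(ValueError, match="at least 11"):
        mx.quantile_align(mat)


def _two_plex_design():
    rows = []
    for plex, lines in (("plex1", ["A", "B"]), ("plex2", ["C", "D"])):
        rows.append({"sample": f"{plex}_r1", "plex": plex, "channel": "ch01",
                     "is_reference": True, "cell_line": ""})
        rows.append({"sample": f"{plex}_r2", "plex": plex, "channel": "ch02",
                     "is_reference": True, "cell_line": ""})
        for i, line in enumerate(lines):
            rows.append({"sample": line, "plex": plex,
                         "channel": f"ch{i + 3:02d}", "is_reference": False,
                         "cell_line": line})
    return mx.PlexDesign(table=pd.DataFrame(rows))


def test_reference_correct_single_plex_is_identity():
    rng = np.random.default_rng(4)
    design = _two_plex_design()
    sub = design.table[design.table["plex"] == "plex1"]
    single = mx.PlexDesign(table=sub)
    mat = _log_matrix({s: rng.normal(20, 2, 50) for s in sub["sample"]})
    corrected, factors, flags = mx.reference_correct(mat, single)
    np.testing.assert_allclose(corrected.values, mat.values, atol=1e-12)
    assert np.allclose(factors, 0.0)
    assert not flags.any()


def test_reference_correct_equalizes_reference_means():
    rng = np.random.default_rng(5)
    design = _two_plex_design()
    base = rng.normal(20, 2, (100, 8))
    mat = _log_matrix(dict(zip(
        ["plex1_r1", "plex1_r2", "A", "B", "plex2_r1", "plex2_r2", "C", "D"],
        base.T,
    )))
    shifted, injected = mx.inject_batch_effect(mat, design, 0.5,
                                               np.random.default_rng(6))
    corrected, factors, _ = mx.reference_correct(shifted, design)
    m1 = corrected.values[["plex1_r1", "plex1_r2"]].mean(axis=1)
    m2 = corrected.values[["plex2_r1", "plex2_r2"]].mean(axis=1)
    np.testing.assert_allclose(m1, m2, atol=1e-9)


def test_reference_correct_preserves_within_plex_ratios():
    """Correction subtracts a per-plex constant per protein, so channel
    differences within a plex are untouched."""
    rng = np.random.default_rng(7)
    design = _two_plex_design()
    mat = _log_matrix({s: rng.normal(20, 2, 60)
                       for s in design.table["sample"]})
    corrected, _, _ = mx.reference_correct(mat, design)
    before = mat.values["A"] - mat.values["B"]
    after = corrected.values["A"] - corrected.values["B"]
    np.testing.assert_allclose(after, before, atol=1e-12)


def test_reference_correct_flags_unreferenced_proteins():
    design = _two_plex_design()
    rng = np.random.default_rng(8)
    values = pd.DataFrame(
        rng.normal(20, 1, (3, 8)),
        index=["P1", "P2", "P3"],
        columns=["plex1_r1", "plex1_r2", "A", "B",
                 "plex2_r1", "plex2_r2", "C", "D"],
    )
    values.loc["P2", ["plex1_r1", "plex1_r2", "plex2_r1", "plex2_r2"]] = np.nan
    values.loc["P3", ["plex2_r1", "plex2_r2"]] = np.nan
    mat = mx.OmicsMatrix(values=values, layer="protein", scale="log2")
    corrected, factors, flags = mx.reference_correct(mat, design)
    assert bool(flags["P2"]) and not bool(flags["P1"])
    # P2 untouched everywhere; P3 untouched in plex2 only
    np.testing.assert_allclose(corrected.values.loc["P2"], values.loc["P2"])
    np.testing.assert_allclose(corrected.values.loc["P3", ["C", "D"]],
                               values.loc["P3", ["C", "D"]])
    assert factors.loc["P3", "plex1"] == pytest.approx(0.0)  # single ref plex


def test_recovered_factors_match_injected(default_screen):
    """Reference-derived correction factors recover the injected per-plex
    batch factors (relative to their mean) at R > 0.99."""
    design = default_screen.plex_design
    normalized, _, factors = mx.normalize_tmt(default_screen.protein, design)
    injected = default_screen.truth.plex_batch_log2
    centered = injected - injected.mean()
    recovered = factors.median(axis=0)
    r = np.corrcoef(recovered[centered.index], centered)[0, 1]
    assert r > 0.99


def test_detection_filter_ceiling_rule():
    det = np.ones((3, 54), dtype=bool)
    det[1, 26:] = False  # present in 26/54 lines -> dropped (26 < 27)
    det[2, 27:] = False  # present in 27/54 lines -> kept
    values = np.where(det, 5.0, np.nan)
    mat = make_matrix(values, layer="protein")
    kept = mx.detection_filter(mat, 0.5)
    assert list(kept.features) == ["F0", "F2"]
    complete_only = mx.detection_filter(mat, 1.0)
    assert list(complete_only.features) == ["F0"]


def test_detection_filter_uses_detection_mask_for_counts():
    values = np.ones((2, 4))
    detected = [[True, True, True, True], [True, False, False, False]]
    mat = make_matrix(values, layer="circ_bs", detected=detected)
    kept = mx.detection_filter(mat, 0.5)
    assert list(kept.features) == ["F0"]


def test_normalization_pipeline_removes_plex_batch_variance(default_screen):
    """Within-plex alignment + reference correction shrinks the variance of
    plex-level mean intensities by >= 90%."""
    design = default_screen.plex_design
    raw = default_screen.protein
    normalized, _, _ = mx.normalize_tmt(raw, design)

    def plex_mean_var(mat):
        means = [
            mat.values[design.plex_samples(p, include_reference=False)]
            .stack().mean()
            for p in design.plexes
        ]
        return np.var(means)

    assert plex_mean_var(normalized) < 0.1 * plex_mean_var(raw)


def test_drop_reference_columns(default_screen):
    trimmed = drop_reference_columns(default_screen.protein,
                                     default_screen.plex_design)
    assert trimmed.n_lines == 54
    assert set(trimmed.lines) == set(default_screen.rna.lines)
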