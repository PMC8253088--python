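"""Fold changes, Welch tests, candidate funnel, timecourse comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import migexpress as mx
from migexpress.config import FilterSet
from migexpress.diffexp import per_coating_fold_changes, volcano_table

from conftest import make_matrix


def _groups(fast, slow):
    return mx.GroupAssignment(
        per_coating={c: (list(fast), list(slow))
                     for c in ("uncoated", "collagen", "fibronectin")},
        overall_fast=list(fast), overall_slow=list(slow),
    )


def test_group_fold_change_ratio_of_means():
    mat = make_matrix([[8, 8, 2, 2], [5, 5, 5, 5], [0, 0, 0, 0]])
    fc = mx.group_fold_change(mat, ["L0", "L1"], ["L2", "L3"], pseudocount=0.0)
    assert fc["F0"] == pytest.approx(4.0)
    assert fc["F1"] == pytest.approx(1.0)
    fc_pc = mx.group_fold_change(mat, ["L0", "L1"], ["L2", "L3"], pseudocount=0.1)
    assert fc_pc["F2"] == pytest.approx(1.0)  # 0/0 guarded by pseudocount


def test_group_fold_change_swap_is_reciprocal():
    rng = np.random.default_rng(0)
    mat = make_matrix(rng.lognormal(2, 1, (20, 8)))
    fast, slow = [f"L{i}" for i in range(4)], [f"L{i}" for i in range(4, 8)]
    fwd = mx.group_fold_change(mat, fast, slow)
    rev = mx.group_fold_change(mat, slow, fast)
    np.testing.assert_allclose(fwd * rev, 1.0, rtol=1e-12)


def test_group_fold_change_scale_invariant():
    rng = np.random.default_rng(1)
    values = rng.lognormal(2, 1, (15, 6))
    fast, slow = ["L0", "L1", "L2"], ["L3", "L4", "L5"]
    fc1 = mx.group_fold_change(make_matrix(values), fast, slow)
    fc2 = mx.group_fold_change(make_matrix(values * 37.5), fast, slow)
    np.testing.assert_allclose(fc1, fc2, rtol=1e-12)


def test_group_fold_change_rejects_empty_group():
    mat = make_matrix([[1.0, 2.0]])
    with pytest.raises(ValueError):
        mx.group_fold_change(mat, [], ["L0"])


def test_mean_fold_change_available_value_mean():
    fc = pd.DataFrame({"fc_uncoated": [2.0, 3.0, 1.0],
                       "fc_collagen": [4.0, np.nan, 1.0],
                       "fc_fibronectin": [6.0, 5.0, 1.0]})
    mean = mx.mean_fold_change(fc)
    np.testing.assert_allclose(mean, [4.0, 4.0, 1.0])


def test_welch_test_identical_groups_p_one():
    mat = make_matrix([[5, 6, 7, 5, 6, 7]], scale="log2")
    p = mx.welch_test(mat, ["L0", "L1", "L2"], ["L3", "L4", "L5"])
    assert p["F0"] == pytest.approx(1.0)


def test_welch_test_matches_closed_form():
    fast, slow = [5.9, 6.1, 6.0], [1.9, 2.1, 2.0]
    mat = make_matrix([fast + slow], scale="log2")
    p = mx.welch_test(mat, ["L0", "L1", "L2"], ["L3", "L4", "L5"])
    expected = stats.ttest_ind(fast, slow, equal_var=False).pvalue
    assert p["F0"] == pytest.approx(expected, rel=1e-10)
    assert p["F0"] < 0.001


def test_welch_test_degenerate_conventions():
    # zero variance in both groups, equal means -> p = 1
    mat = make_matrix([[3, 3, 3, 3, 3, 3], [3, 3, 3, 4, 4, 4]], scale="log2")
    p = mx.welch_test(mat, ["L0", "L1", "L2"], ["L3", "L4", "L5"])
    assert p["F0"] == 1.0
    assert p["F1"] == 0.0  # zero variance, different means
    # fewer than 2 non-missing per group -> NaN
    mat2 = make_matrix([[3, np.nan, np.nan, 4, 4, 5]], layer="protein",
                       scale="log2")
    p2 = mx.welch_test(mat2, ["L0", "L1", "L2"], ["L3", "L4", "L5"])
    assert np.isnan(p2["F0"])


def test_welch_test_shift_invariant():
    rng = np.random.default_rng(2)
    values = rng.normal(5, 1, (30, 10))
    fast, slow = [f"L{i}" for i in range(5)], [f"L{i}" for i in range(5, 10)]
    p1 = mx.welch_test(make_matrix(values, scale="log2"), fast, slow)
    p2 = mx.welch_test(make_matrix(values + 11.0, scale="log2"), fast, slow)
    np.testing.assert_allclose(p1, p2, atol=1e-12)


def test_welch_test_agrees_with_permutation_oracle():
    """Welch p within +/-0.02 of a 10,000-draw permutation test, 9 vs 9."""
    rng = np.random.default_rng(3)
    n_feat = 10
    data = rng.normal(0, 1, (n_feat, 18))
    data[:5, :9] += rng.uniform(0.3, 1.2, (5, 1))  # moderate shifts
    fast, slow = [f"L{i}" for i in range(9)], [f"L{i}" for i in range(9, 18)]
    p_welch = mx.welch_test(make_matrix(data, scale="log2"), fast, slow)

    def welch_t(a, b):
        va, vb = a.var(ddof=1, axis=-1), b.var(ddof=1, axis=-1)
        return (a.mean(-1) - b.mean(-1)) / np.sqrt(va / 9 + vb / 9)

    t_obs = welch_t(data[:, :9], data[:, 9:])
    n_perm = 10_000
    exceed = np.zeros(n_feat)
    for _ in range(n_perm):
        perm = rng.permutation(18)
        t_p = welch_t(data[:, perm[:9]], data[:, perm[9:]])
        exceed += np.abs(t_p) >= np.abs(t_obs)
    p_perm = exceed / n_perm
    assert np.max(np.abs(p_welch.to_numpy() - p_perm)) < 0.02


def test_select_candidates_recovers_planted_fixture():
    """Brute-force oracle: with 2 planted features (log2FC 3, sd 0.1, 5v5)
    exactly the planted features pass all three filters."""
    rng = np.random.default_rng(4)
    n, fast_n = 10, 5
    log2 = rng.normal(4, 0.1, (n, 10))
    log2[0, :fast_n] += 3.0
    log2[1, :fast_n] -= 3.0
    mat = make_matrix(2.0**log2)
    fast = [f"L{i}" for i in range(fast_n)]
    slow = [f"L{i}" for i in range(fast_n, 10)]
    filters = FilterSet(min_fc=3.0, alpha=0.05, min_expr=1.0)
    table, funnel = mx.select_candidates(mat, _groups(fast, slow), filters)

    # independent brute-force evaluation of the three filters
    linear = 2.0**log2
    expected = []
    for i in range(n):
        mean_fc = linear[i, :fast_n].mean() / linear[i, fast_n:].mean()
        expr = linear[i].mean() >= 1.0
        reg = mean_fc >= 3.0 or mean_fc <= 1 / 3.0
        p = stats.ttest_ind(log2[i, :fast_n], log2[i, fast_n:],
                            equal_var=False).pvalue
        if expr and reg and p < 0.05:
            expected.append(f"F{i}")
    assert expected == ["F0", "F1"]
    assert list(table.loc[table["candidate"], "feature"]) == expected
    assert table.loc[0, "direction"] == "up"
    assert table.loc[1, "direction"] == "down"
    assert funnel["n_significant"] == 2


def test_select_candidates_funnel_nonincreasing(default_analysis):
    for funnel in (default_analysis.rna_funnel, default_analysis.protein_funnel):
        assert (funnel["n_total"] >= funnel["n_expressed"]
                >= funnel["n_regulated"] >= funnel["n_significant"])


def test_select_candidates_vacuous_filters_keep_all_expressed():
    rng = np.random.default_rng(5)
    mat = make_matrix(rng.lognormal(2, 1, (25, 10)))
    fast = [f"L{i}" for i in range(5)]
    slow = [f"L{i}" for i in range(5, 10)]
    filters = FilterSet(min_fc=1.0, alpha=0.999999, min_expr=1e-9)
    table, funnel = mx.select_candidates(mat, _groups(fast, slow), filters)
    assert funnel["n_significant"] == funnel["n_expressed"] == 25


def test_select_candidates_requires_groups():
    mat = make_matrix([[1.0, 2.0]])
    empty = mx.GroupAssignment(per_coating={}, overall_fast=[], overall_slow=[])
    with pytest.raises(ValueError):
        mx.select_candidates(mat, empty, FilterSet(min_fc=3, alpha=0.05))


def test_per_coating_fold_changes_use_per_coating_groups():
    mat = make_matrix([[10, 10, 1, 1]])
    groups = mx.GroupAssignment(
        per_coating={
            "uncoated": (["L0", "L1"], ["L2", "L3"]),
            "collagen": (["L2", "L3"], ["L0", "L1"]),  # deliberately flipped
            "fibronectin": ([], []),
        },
        overall_fast=["L0", "L1"], overall_slow=["L2", "L3"],
    )
    fc = per_coating_fold_changes(mat, groups)
    assert fc.loc["F0", "fc_uncoated"] == pytest.approx(10.0)
    assert fc.loc["F0", "fc_collagen"] == pytest.approx(0.1)
    assert np.isnan(fc.loc["F0", "fc_fibronectin"])


def test_volcano_table_transforms(default_analysis):
    vol = volcano_table(default_analysis.rna_candidates)
    cand = default_analysis.rna_candidates
    np.testing.assert_allclose(vol["log2_mean_fc"], np.log2(cand["mean_fc"]))


def test_null_welch_rate_close_to_alpha():
    """On a null screen the p < 0.05 fraction is near 0.05 (single seed;
    the multi-seed calibration lives in the acceptance suite)."""
    screen = mx.simulate_screen(
        mx.SimulationSpec(seed=11, frac_migration_assoc=0.0)
    )
    classes = mx.classify_screen(screen.migration)
    groups = mx.groups_from_classes(classes)
    p = mx.welch_test(screen.rna.to_log2(0.01), groups.overall_fast,
                      groups.overall_slow)
    assert abs((p < 0.05).mean() - 0.05) < 0.02


def test_timecourse_compare_identical_arms_nonsignificant():
    rng = np.random.default_rng(6)
    base = rng.normal(50, 2, (4, 5))
    cols = [0, 6, 12, 18, 24]
    a = pd.DataFrame(base, columns=cols)
    b = pd.DataFrame(base + rng.normal(0, 0.01, base.shape), columns=cols)
    res = mx.timecourse_compare(a, b)
    assert (res["p_value"] > 0.5).all()


def test_timecourse_compare_detects_separation_and_routes_by_f_test():
    rng = np.random.default_rng(7)
    cols = [0, 6, 12]
    a = pd.DataFrame(rng.normal(50, 1, (6, 3)), columns=cols)
    b = pd.DataFrame(rng.normal(50, 1, (6, 3)), columns=cols)
    b[6] += 10.0  # 10-sd separation from 6 h on
    b[12] += 10.0
    b[12] = 50 + (b[12] - b[12].mean()) * 4 + 10  # variance ratio 16 at 12 h
    res = mx.timecourse_compare(a, b).set_index("timepoint")
    assert res.loc[0, "p_value"] > 0.05
    assert res.loc[6, "p_value"] < 0.001
    assert res.loc[12, "test"] == "welch"  # F-test routed to Welch branch
    assert res.loc[6, "test"] == "pooled"


def test_timecourse_compare_rejects_mismatched_grid():
    a = pd.DataFrame(np.zeros((3, 2)), columns=[0, 6])
    b = pd.DataFrame(np.zeros((3, 2)), columns=[0, 12])
    with pytest.raises(ValueError):
        mx.timecourse_compare(a, b)
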