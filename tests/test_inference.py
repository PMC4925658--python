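"""Matched-pair permutation machinery, significance maps, reports."""

import numpy as np
import pandas as pd
import pytest

from occmap import (
    CohortConfig,
    EffectSpec,
    PermutationPlan,
    auc_permutation_test,
    make_region_report,
    match_pairs,
    permute_unit_labels,
    preimage_significance,
    sign_trends,
    simulate_cohort,
)
from occmap.inference import AUCPermutationResult, InferenceError, region_report_text


def test_permute_preserves_sizes_and_swaps(matched_null):
    _, subjects, part = matched_null
    rng = np.random.default_rng(0)
    permuted = permute_unit_labels(part, subjects, rng)
    assert (permuted["group"] == "case").sum() == (subjects["group"] == "case").sum()
    assert set(permuted.index) == set(subjects.index)
    # per unit the label multiset is preserved
    for unit in part.units:
        ids = list(unit.subjects)
        assert sorted(permuted.loc[ids, "group"]) == sorted(subjects.loc[ids, "group"])


def test_all_swap_and_no_swap_outcomes(matched_null):
    _, subjects, part = matched_null

    class AlwaysSwap:
        def random(self):
            return 0.0

        def integers(self, n):
            return 0

    class NeverSwap:
        def random(self):
            return 0.99

    inverted = permute_unit_labels(part, subjects, AlwaysSwap())
    for unit in part.units:
        if len(unit.cases) == 1 and len(unit.controls) == 1:
            assert inverted.loc[unit.cases[0], "group"] == "control"
            assert inverted.loc[unit.controls[0], "group"] == "case"
    identity = permute_unit_labels(part, subjects, NeverSwap())
    pd.testing.assert_frame_equal(identity, subjects)


def test_swap_rate_is_binomial_half(matched_null):
    _, subjects, part = matched_null
    unit = part.units[0]
    case_id = unit.cases[0]
    n, swaps = 10_000, 0
    plan = PermutationPlan(n_permutations=1, seed=99)
    for b in range(n):
        rng = plan.rng_for(b)
        permuted = permute_unit_labels(part, subjects, rng)
        swaps += permuted.loc[case_id, "group"] == "control"
    assert abs(swaps / n - 0.5) < 0.015


def test_triplet_swap_symmetric():
    cfg = CohortConfig(n_cases=3, n_controls=2, seed=5)
    _, subjects = simulate_cohort(cfg, EffectSpec.null())
    part = match_pairs(subjects)
    triplet = next(u for u in part.units if len(u.cases) == 2)
    counts = {c: 0 for c in triplet.cases}
    for b in range(4000):
        rng = np.random.default_rng(b)
        permuted = permute_unit_labels(part, subjects, rng)
        for c in triplet.cases:
            if permuted.loc[c, "group"] == "control":
                counts[c] += 1
    # each case swapped in ~ half of the ~50% swap events
    for c in triplet.cases:
        assert abs(counts[c] / 4000 - 0.25) < 0.03


def test_p_value_extremes_by_injection(matched_null):
    features, subjects, part = matched_null
    plan = PermutationPlan(n_permutations=30, seed=1)
    res = auc_permutation_test(features, subjects, part, plan, target_class="case")
    # monotonicity: pushing the observed AUC to the extremes drives p to 0 / 1
    hi = AUCPermutationResult(1.01, float((res.null_aucs > 1.01).mean()), 0, res.null_aucs, 30)
    lo_count = float((res.null_aucs > -0.01).mean())
    assert hi.p_value == 0.0
    assert lo_count == 1.0
    exceed = (res.null_aucs > res.observed_auc).sum()
    assert res.p_value == exceed / 30
    assert res.p_value_add_one == (exceed + 1) / 31
    assert 0.0 <= res.p_value <= 1.0


def test_permutation_determinism(matched_null):
    features, subjects, part = matched_null
    plan = PermutationPlan(n_permutations=10, seed=3)
    a = auc_permutation_test(features, subjects, part, plan, target_class="case")
    b = auc_permutation_test(features, subjects, part, plan, target_class="case")
    np.testing.assert_array_equal(a.null_aucs, b.null_aucs)
    assert a.p_value == b.p_value


def test_sign_trends_match_generator():
    planted = [("lh", "cuneus", "Volume"), ("rh", "insula", "Area")]
    cfg = CohortConfig(n_cases=200, n_controls=200, seed=23)
    eff = EffectSpec(affected_features=planted, effect_sizes=[2.0, -2.0],
                     case_within_cov_scale=1.0, control_heterogeneity=0.0)
    features, subjects = simulate_cohort(cfg, eff)
    trend = sign_trends(features, subjects)
    assert trend["lh_cuneus_Volume"] == "up"
    assert trend["rh_insula_Area"] == "down"
    # exactly equal group means -> none
    toy = pd.DataFrame({"f": [1.0, 2.0, 1.0, 2.0]}, index=["a", "b", "c", "d"])
    meta = pd.DataFrame({"group": ["case", "case", "control", "control"]},
                        index=toy.index)
    assert sign_trends(toy, meta)["f"] == "none"
    with pytest.raises(InferenceError):
        sign_trends(toy, pd.DataFrame({"group": ["case"] * 4}, index=toy.index))


def test_preimage_significance_structure(matched_null):
    features, subjects, part = matched_null
    plan = PermutationPlan(n_permutations=25, seed=2)
    sig = preimage_significance(features, subjects, part, plan)
    table = sig.table
    assert len(table) == 314
    assert table["p"].between(0, 1).all()
    assert (table["significant"] == (table["p"] < 0.05)).all()
    assert set(table["sign_trend"]) <= {"up", "down", "none"}
    assert table["p_bh"].between(0, 1).all()
    assert (table["p_bh"] >= table["p"] - 1e-12).all()
    # determinism
    sig2 = preimage_significance(features, subjects, part, plan)
    pd.testing.assert_frame_equal(sig.table, sig2.table)


def test_exchangeability_of_pooled_features(matched_null):
    """Permuting unit labels leaves the pooled feature distribution unchanged
    (it only relabels rows)."""
    features, subjects, part = matched_null
    pooled = np.sort(features.to_numpy(), axis=0)
    for seed in range(20):
        permuted = permute_unit_labels(part, subjects, np.random.default_rng(seed))
        reordered = features.loc[permuted.index]
        np.testing.assert_array_equal(np.sort(reordered.to_numpy(), axis=0), pooled)


def test_region_report_layout(matched_null):
    features, subjects, part = matched_null
    plan = PermutationPlan(n_permutations=25, seed=2)
    sig = preimage_significance(features, subjects, part, plan)
    report = make_region_report(sig)
    n_sig = int(sig.table["significant"].sum())
    n_arrows = int((report.isin(["^", "v"])).sum().sum()) if not report.empty else 0
    assert n_arrows == n_sig
    assert region_report_text(report)
    # empty map -> header-only table
    sig.table["p"] = 1.0
    empty = make_region_report(sig)
    assert empty.empty
    assert "No features significant" in region_report_text(empty)


def test_plan_validation():
    with pytest.raises(InferenceError):
        PermutationPlan(n_permutations=0)
    with pytest.raises(InferenceError):
        PermutationPlan(alpha=1.5)
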