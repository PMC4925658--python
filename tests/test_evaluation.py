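"""Matching, LPO-CV, nested optimization and ROC/AUC."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from occmap import (
    CohortConfig,
    EffectSpec,
    OptGrid,
    lpo_splits,
    match_pairs,
    nested_optimize,
    roc_auc,
    run_occ_cv,
    run_two_class_cv,
    simulate_cohort,
    subgroup_auc,
)
from occmap.evaluation import EvaluationError, UndefinedMetricError, _inner_cv_auc, _partition_index_sets


def brute_force_auc(scores, labels):
    """Exact pairwise Mann-Whitney count with rational arithmetic (ties = 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    total = Fraction(0)
    for p in pos:
        for n in neg:
            total += Fraction(1) if p > n else (Fraction(1, 2) if p == n else Fraction(0))
    return total / (len(pos) * len(neg))


def test_auc_examples_and_brute_force_oracle():
    # worked example: cases {3, 2}, controls {1, 2} -> (1+1+1+1/2)/4
    auc, _ = roc_auc([3, 2, 1, 2], [1, 1, -1, -1])
    assert auc == pytest.approx(0.875)
    assert roc_auc([5, 4, 1, 0], [1, 1, -1, -1])[0] == 1.0
    assert roc_auc([1, 1, 1, 1], [1, 1, -1, -1])[0] == 0.5
    rng = np.random.default_rng(77)
    for _ in range(100):
        n = int(rng.integers(4, 30))
        scores = rng.integers(0, 8, size=n).astype(float)  # many ties
        labels = np.where(rng.random(n) < 0.5, 1, -1)
        if (labels == 1).all() or (labels == -1).all():
            labels[0], labels[-1] = 1, -1
        auc, _ = roc_auc(scores, labels)
        assert Fraction(auc).limit_denominator(10**9) == brute_force_auc(scores, labels)


def test_auc_requires_both_classes():
    with pytest.raises(UndefinedMetricError):
        roc_auc([1.0, 2.0], [1, 1])


def test_match_pairs_counts():
    cfg = CohortConfig(n_cases=41, n_controls=40, sex_ratio=0.51, seed=4)
    _, subjects = simulate_cohort(cfg, EffectSpec.null())
    part = match_pairs(subjects, "pooled")
    assert part.M == 40
    sizes = sorted(len(u.cases) + len(u.controls) for u in part.units)
    assert sizes.count(2) == 39 and sizes.count(3) == 1
    assert sorted(part.subjects) == sorted(subjects.index)


def test_match_pairs_strata_and_designed_pairing():
    cfg = CohortConfig(n_cases=20, n_controls=20, sex_ratio=0.0, seed=8)
    _, subjects = simulate_cohort(cfg, EffectSpec.null())
    part = match_pairs(subjects, "female")
    assert part.M == 20
    assert all(len(u.cases) == 1 and len(u.controls) == 1 for u in part.units)
    # jitter-matched covariates let matching recover the designed pairing
    recovered = sum(
        u.cases[0].replace("case", "") == u.controls[0].replace("control", "")
        for u in part.units
    )
    assert recovered >= 16
    with pytest.raises(EvaluationError):
        match_pairs(subjects, "male")


def test_lpo_splits_partition_property():
    cfg = CohortConfig(n_cases=7, n_controls=6, seed=2)
    _, subjects = simulate_cohort(cfg, EffectSpec.null())
    part = match_pairs(subjects)
    folds = list(lpo_splits(part))
    assert len(folds) == part.M
    tested = [s for _, test in folds for s in test.subjects]
    assert sorted(tested) == sorted(subjects.index)
    for train, test in folds:
        assert len(train) == part.M - 1
        assert not set(test.subjects) & {s for u in train for s in u.subjects}


def test_optgrid_defaults_match_protocol():
    grid = OptGrid()
    assert len(grid.gamma_coarse) == 19
    assert grid.gamma_coarse[0] == 2.0**-15 and grid.gamma_coarse[-1] == 2.0**3
    assert len(grid.nu_coarse) == 10
    assert grid.nu_coarse[0] == pytest.approx(0.01) and grid.nu_coarse[-1] == pytest.approx(0.5)
    assert len(grid.nu_fine) == 20
    assert grid.nu_fine[0] == pytest.approx(0.01) and grid.nu_fine[-1] == pytest.approx(0.3)
    assert grid.nu_init == 0.1


def test_nested_optimize_beats_grid_points(planted_cohort):
    """On a separable cohort the chosen (γ, ν) attains the best inner AUC on
    an exhaustive reduced grid."""
    features, subjects, _ = planted_cohort
    part = match_pairs(subjects)
    sub_units = part.units[:8]
    from occmap.evaluation import MatchedPartition

    sub = MatchedPartition(units=sub_units, stratum="pooled")
    X = features.to_numpy()
    order = features.index
    y = subjects.loc[order, "y"].to_numpy()
    is_target = subjects.loc[order, "group"].to_numpy() == "case"
    units_idx = _partition_index_sets(features, sub)
    grid = OptGrid(
        gamma_coarse=np.array([2.0**-9, 2.0**-5, 2.0**-1]),
        nu_coarse=np.array([0.1, 0.3, 0.5]),
        nu_fine=np.array([0.05, 0.15]),
        gamma_refine_halfwidth=0.0,
    )
    g_opt, nu_opt = nested_optimize(X, is_target, y, units_idx, grid)
    auc_opt = _inner_cv_auc(X, is_target, y, units_idx, g_opt, nu_opt)
    for g in grid.gamma_coarse:
        assert auc_opt >= _inner_cv_auc(X, is_target, y, units_idx, g, 0.1) - 1e-12
    for nv in list(grid.nu_coarse) + list(grid.nu_fine):
        assert auc_opt >= _inner_cv_auc(X, is_target, y, units_idx, g_opt, nv) - 1e-12


def test_run_occ_cv_null_is_chance(matched_null):
    features, subjects, part = matched_null
    cv = run_occ_cv(features, subjects, part, target_class="control")
    auc, _ = roc_auc(cv.scores, cv.labels)
    assert 0.25 < auc < 0.75
    assert len(cv.scores) == len(subjects)
    assert all(p["gamma"] == pytest.approx(1 / 314) and p["nu"] == 0.1 for p in cv.fold_params)


def test_out_of_fold_integrity(matched_null):
    """No test subject's data (standardization included) touches its fold's
    training: mutating the held-out case leaves its unit-mate's score fixed,
    and mutating a control (never trained on when target=case) leaves every
    other subject's score fixed."""
    features, subjects, part = matched_null
    cv = run_occ_cv(features, subjects, part, target_class="case")
    unit = part.units[0]
    # 1. mutate the held-out case: its fold's model must be unchanged, so the
    #    co-tested control of the same unit keeps its score exactly
    mutated = features.copy()
    mutated.loc[list(unit.cases)] = mutated.loc[list(unit.cases)] * 3.0 + 17.0
    cv2 = run_occ_cv(mutated, subjects, part, target_class="case")
    for ctrl in unit.controls:
        assert cv2.scores[ctrl] == cv.scores[ctrl]
    assert not np.allclose(cv2.scores[list(unit.cases)], cv.scores[list(unit.cases)])
    # 2. mutate a control: controls never enter case-targeted training
    mutated = features.copy()
    victim = unit.controls[0]
    mutated.loc[victim] = mutated.loc[victim] * 5.0 - 3.0
    cv3 = run_occ_cv(mutated, subjects, part, target_class="case")
    others = [s for s in cv.scores.index if s != victim]
    pd.testing.assert_series_equal(cv.scores[others], cv3.scores[others])


def test_subgroup_auc_consistency(matched_null):
    features, subjects, part = matched_null
    cv = run_occ_cv(features, subjects, part, target_class="case")
    overall, _ = roc_auc(cv.scores, cv.labels)
    assert subgroup_auc(cv, subjects, lambda r: True) == pytest.approx(overall)
    lo = subgroup_auc(cv, subjects, lambda r: r["nviq"] < 70)
    hi = subgroup_auc(cv, subjects, lambda r: r["nviq"] >= 70)
    assert 0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0
    with pytest.raises(UndefinedMetricError):
        subgroup_auc(cv, subjects, lambda r: False)


def test_subgroup_auc_tracks_stratified_effect(matched_null):
    """An effect present only in high-NVIQ subjects shows up in the
    NVIQ >= 70 subgroup AUC, not in the low-NVIQ one."""
    features, subjects, part = matched_null
    boosted = features.copy()
    mask = (subjects["group"] == "control") & (subjects["nviq"] >= 70)
    cols = boosted.columns[:40]
    boosted.loc[mask, cols] += 6.0 * boosted[cols].std(ddof=0)
    cv = run_occ_cv(boosted, subjects, part, target_class="case")
    hi = subgroup_auc(cv, subjects, lambda r: r["nviq"] >= 70)
    lo = subgroup_auc(cv, subjects, lambda r: r["nviq"] < 70)
    assert hi > lo


def test_cv_determinism(matched_null):
    features, subjects, part = matched_null
    a = run_occ_cv(features, subjects, part, target_class="case")
    b = run_occ_cv(features, subjects, part, target_class="case")
    pd.testing.assert_series_equal(a.scores, b.scores)


def test_two_class_reference_on_linearly_separable_cohort(matched_null):
    """On a mean-shifted (linearly separable) cohort the binary SVM, which
    uses both classes, does at least as well as the one-class SVM; on the
    null cohort it sits at chance."""
    planted = [("lh", r, "Volume") for r in
               ("cuneus", "fusiform", "insula", "lingual", "precuneus")]
    cfg = CohortConfig(n_cases=25, n_controls=25, seed=31)
    eff = EffectSpec(affected_features=planted, effect_sizes=[2.0] * 5,
                     case_within_cov_scale=1.0, control_heterogeneity=0.0)
    features, subjects = simulate_cohort(cfg, eff)
    part = match_pairs(subjects)
    occ = run_occ_cv(features, subjects, part, target_class="case")
    two = run_two_class_cv(features, subjects, part, kernel="linear", C=0.01)
    auc_occ, _ = roc_auc(occ.scores, occ.labels)
    auc_two, _ = roc_auc(two.scores, two.labels)
    assert auc_two >= auc_occ - 0.05
    assert auc_two > 0.8
    nf, ns, np_ = matched_null
    null_two = run_two_class_cv(nf, ns, np_, kernel="linear")
    assert 0.2 < roc_auc(null_two.scores, null_two.labels)[0] < 0.8


def test_two_class_linear_recovers_planted_direction():
    """The fitted linear weight's sign and rank reflect a single planted shift."""
    planted = [("lh", "cuneus", "Volume")]
    cfg = CohortConfig(n_cases=30, n_controls=30, seed=17)
    eff = EffectSpec(affected_features=planted, effect_sizes=[4.0],
                     case_within_cov_scale=1.0, control_heterogeneity=0.0)
    features, subjects = simulate_cohort(cfg, eff)
    from occmap.svm import Standardizer
    from sklearn.svm import SVC

    std = Standardizer.fit(features.to_numpy())
    clf = SVC(kernel="linear", C=1.0).fit(std.transform(features.to_numpy()),
                                          subjects["y"].to_numpy())
    w = clf.coef_[0]
    k = list(features.columns).index("lh_cuneus_Volume")
    assert w[k] > 0 and abs(w[k]) == np.abs(w).max()
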