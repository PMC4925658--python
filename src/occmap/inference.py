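"""Matched-pair permutation inference for AUC and preimage maps.

The permutation null for a matched case-control design exchanges labels
*within* matched units: independently per unit, with probability ½ the case
and control swap group labels (for a triplet, the control swaps with one of
the two cases chosen uniformly), giving 2^M equiprobable relabelings that
preserve group sizes and the matching structure.  Each relabeling defines an
"artificial" target class; repeating the full analysis on it builds the null
distribution of the statistic of interest.

Two statistics are handled:

* **AUC** — the one-class LPO-CV is retrained per permutation (with the same
  configuration as the observed run, including nested parameter optimization
  when requested) and the out-of-fold AUC recorded.  The raw one-sided
  p-value is the fraction of null AUCs strictly exceeding the observed one;
  the add-one corrected p-value (count + 1) / (B + 1) is reported alongside.

* **Preimage map** — a one-class SVM with fixed ν = 0.1 and heuristic γ is
  trained on the full (artificial) target set and its RBF preimage computed;
  per feature the p-value is the fraction of permutations whose |z| exceeds
  the observed |z|.  Features with p < α are flagged significant; no
  multiple-testing correction is applied to the primary flag, but a
  Benjamini-Hochberg column is emitted alongside.

For the map, features are standardized ONCE against the pooled sample (all
subjects, a permutation-invariant quantity), so that preimage components are
comparable across permuted refits; the models are then fitted without
refitting a standardizer.  Each permutation's random stream derives from
(seed, permutation index), so results are independent of any parallel or
chunked execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dkt import FeatureIndex
from .evaluation import CVResult, MatchedPartition, roc_auc, run_occ_cv
from .preimage import PreimageError, compute_preimage
from .svm import KernelSpec, Standardizer, fit_one_class, heuristic_gamma


class InferenceError(ValueError):
    pass


@dataclass
class PermutationPlan:
    n_permutations: int = 10_000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise InferenceError("n_permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise InferenceError("alpha must lie in (0, 1)")

    def rng_for(self, index: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, index)))


def permute_unit_labels(
    partition: MatchedPartition, subjects: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Return a copy of the subject table with within-unit labels exchanged.

    Per unit, with probability ½ the case(s) and control(s) exchange group
    labels; in a triplet the control is exchanged with one of the two cases
    chosen uniformly.  Group sizes are preserved.
    """
    permuted = subjects.copy()
    for unit in partition.units:
        if rng.random() >= 0.5:
            continue
        cases, controls = list(unit.cases), list(unit.controls)
        if len(cases) == 1 and len(controls) == 1:
            swap_case, swap_control = cases[0], controls[0]
        elif len(cases) > len(controls):
            swap_case = cases[int(rng.integers(len(cases)))]
            swap_control = controls[0]
        else:
            swap_case = cases[0]
            swap_control = controls[int(rng.integers(len(controls)))]
        permuted.at[swap_case, "group"] = "control"
        permuted.at[swap_case, "y"] = -1
        permuted.at[swap_control, "group"] = "case"
        permuted.at[swap_control, "y"] = 1
    return permuted


@dataclass
class AUCPermutationResult:
    observed_auc: float
    p_value: float
    p_value_add_one: float
    null_aucs: np.ndarray
    n_permutations: int


def auc_permutation_test(
    features: pd.DataFrame,
    subjects: pd.DataFrame,
    partition: MatchedPartition,
    plan: PermutationPlan,
    observed: CVResult | None = None,
    progress: "callable | None" = None,
    **cv_kwargs,
) -> AUCPermutationResult:
    """Null distribution of the LPO-CV AUC under within-unit label exchange.

    ``cv_kwargs`` (target_class, optimize, nu, gamma, grid) configure
    :func:`occmap.evaluation.run_occ_cv` identically for the observed and
    every permuted run.
    """
    if observed is None:
        observed = run_occ_cv(features, subjects, partition, **cv_kwargs)
    obs_auc, _ = roc_auc(observed.scores, observed.labels)
    null_aucs = np.empty(plan.n_permutations)
    for b in range(plan.n_permutations):
        rng = plan.rng_for(b)
        permuted = permute_unit_labels(partition, subjects, rng)
        perm_partition = _relabel_partition(partition, permuted)
        cv = run_occ_cv(features, permuted, perm_partition, **cv_kwargs)
        null_aucs[b], _ = roc_auc(cv.scores, cv.labels)
        if progress is not None:
            progress(b, null_aucs[b])
    exceed = int((null_aucs > obs_auc).sum())
    return AUCPermutationResult(
        observed_auc=obs_auc,
        p_value=exceed / plan.n_permutations,
        p_value_add_one=(exceed + 1) / (plan.n_permutations + 1),
        null_aucs=null_aucs,
        n_permutations=plan.n_permutations,
    )


def _relabel_partition(partition: MatchedPartition, permuted: pd.DataFrame) -> MatchedPartition:
    """Rebuild units so that cases/controls reflect the permuted labels."""
    from .evaluation import MatchedUnit

    units = []
    for unit in partition.units:
        ids = unit.subjects
        cases = tuple(s for s in ids if permuted.loc[s, "group"] == "case")
        controls = tuple(s for s in ids if permuted.loc[s, "group"] == "control")
        units.append(MatchedUnit(cases=cases, controls=controls))
    return MatchedPartition(units=units, stratum=partition.stratum)


def sign_trends(features: pd.DataFrame, subjects: pd.DataFrame) -> pd.Series:
    """Per-feature trend of the case-control mean difference: up / down / none."""
    is_case = subjects.loc[features.index, "group"] == "case"
    if is_case.all() or (~is_case).all():
        raise InferenceError("both groups are required for sign trends")
    pooled_sd = features.std(ddof=0).replace(0.0, 1.0)
    diff = (features[is_case.to_numpy()].mean() - features[~is_case.to_numpy()].mean()) / pooled_sd
    trend = pd.Series("none", index=features.columns, name="sign_trend")
    trend[diff > 1e-12] = "up"
    trend[diff < -1e-12] = "down"
    return trend


@dataclass
class SignificanceMap:
    """Per-feature preimage component, permutation p-value and sign trend."""

    table: pd.DataFrame          # z_obs, exceedance, n_effective, p, p_add_one, p_bh, significant, sign_trend
    alpha: float
    nu: float
    gamma: float
    n_permutations: int
    feature_index: FeatureIndex | None = None
    observed_model_json: str | None = None
    n_failed_permutations: int = 0


def _fit_map_model(Z: np.ndarray, is_target: np.ndarray, nu: float, gamma: float):
    if not is_target.any():
        raise InferenceError("target class empty")
    return fit_one_class(Z[is_target], nu, KernelSpec("rbf", gamma), standardize=False)


def preimage_significance(
    features: pd.DataFrame,
    subjects: pd.DataFrame,
    partition: MatchedPartition,
    plan: PermutationPlan,
    target_class: str = "case",
    nu: float = 0.1,
    gamma: float | str = "heuristic",
    n_restarts: int = 2,
    preimage_tol: float = 1e-8,
    preimage_max_iter: int = 10_000,
) -> SignificanceMap:
    """Permutation significance map of the one-class preimage components.

    The observed map comes from a model trained on the full target class with
    fixed ν and heuristic γ; each permutation refits on the artificial target
    set under the identical configuration.  A permutation whose preimage
    fails to converge is resampled once (fresh stream); if it fails again it
    is excluded and the denominator adjusted.  A warning is emitted if more
    than 1% of permutations failed.
    """
    order = [s for u in partition.units for s in u.subjects]
    feats = features.loc[order]
    subj = subjects.loc[order]
    X = feats.to_numpy(dtype=float)
    if gamma == "heuristic":
        gamma = heuristic_gamma(X.shape[1])
    pooled = Standardizer.fit(X)
    Z = pooled.transform(X)

    def map_for(table: pd.DataFrame, rng):
        is_target = (table.loc[order, "group"] == target_class).to_numpy()
        model = _fit_map_model(Z, is_target, nu, gamma)
        result = compute_preimage(
            model, tol=preimage_tol, max_iter=preimage_max_iter,
            n_restarts=n_restarts, rng=rng,
        )
        return result.z, model

    z_obs, obs_model = map_for(
        subj, np.random.default_rng(np.random.SeedSequence((plan.seed, 0x0B5E7ED)))
    )
    abs_obs = np.abs(z_obs)
    exceed = np.zeros(Z.shape[1], dtype=int)
    n_failed = 0
    n_effective = 0
    for b in range(plan.n_permutations):
        rng = plan.rng_for(b)
        permuted = permute_unit_labels(partition, subj, rng)
        try:
            z_null, _ = map_for(permuted, rng)
        except PreimageError:
            # one resample from a fresh stream, then exclusion
            rng2 = plan.rng_for(plan.n_permutations + b)
            permuted = permute_unit_labels(partition, subj, rng2)
            try:
                z_null, _ = map_for(permuted, rng2)
            except PreimageError:
                n_failed += 1
                continue
        exceed += (np.abs(z_null) > abs_obs).astype(int)
        n_effective += 1
    if n_failed > 0.01 * plan.n_permutations:
        warnings.warn(
            f"{n_failed} of {plan.n_permutations} permutations dropped for "
            "preimage non-convergence", stacklevel=2
        )
    if n_effective == 0:
        raise InferenceError("every permutation failed to produce a preimage")
    p = exceed / n_effective
    p_add_one = (exceed + 1) / (n_effective + 1)
    _, p_bh, _, _ = multipletests(p, alpha=plan.alpha, method="fdr_bh")
    table = pd.DataFrame(
        {
            "z_obs": z_obs,
            "exceedance": exceed,
            "n_effective": n_effective,
            "p": p,
            "p_add_one": p_add_one,
            "p_bh": p_bh,
            "significant": p < plan.alpha,
            "sign_trend": sign_trends(feats, subj).to_numpy(),
        },
        index=pd.Index(feats.columns, name="feature"),
    )
    return SignificanceMap(
        table=table,
        alpha=plan.alpha,
        nu=nu,
        gamma=float(gamma),
        n_permutations=plan.n_permutations,
        feature_index=features.attrs.get("feature_index"),
        observed_model_json=obs_model.to_json(),
        n_failed_permutations=n_failed,
    )


ARROWS = {"up": "^", "down": "v", "none": "-"}


def make_region_report(
    sig_map: SignificanceMap,
    alpha: float | None = None,
    feature_index: FeatureIndex | None = None,
) -> pd.DataFrame:
    """Region x measure table of significant features annotated with arrows.

    One row per (hemisphere, region) holding an arrow in each significant
    measure's column: ``^`` for case > control, ``v`` for case < control.
    """
    alpha = sig_map.alpha if alpha is None else alpha
    index = feature_index or sig_map.feature_index
    if index is None:
        raise InferenceError("a FeatureIndex is required to lay out the report")
    from .dkt import MEASURES, feature_name

    measures = sorted({m for _, _, m in index}, key=MEASURES.index)
    rows: dict[tuple[str, str], dict[str, str]] = {}
    for hemi, region, measure in index:
        name = feature_name(hemi, region, measure)
        if name not in sig_map.table.index:
            continue
        entry = sig_map.table.loc[name]
        if entry["p"] >= alpha:
            continue
        row = rows.setdefault((hemi, region), {m: "" for m in measures})
        row[measure] = ARROWS[entry["sign_trend"]]
    report = pd.DataFrame.from_dict(rows, orient="index")
    if report.empty:
        report = pd.DataFrame(columns=measures)
        report.index = pd.MultiIndex.from_tuples([], names=["hemisphere", "region"])
    else:
        report = report[measures]
        report.index = pd.MultiIndex.from_tuples(report.index, names=["hemisphere", "region"])
        report = report.sort_index()
    return report


def region_report_text(report: pd.DataFrame) -> str:
    if report.empty:
        return "No features significant at the requested level.\n"
    return report.to_string() + "\n"
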