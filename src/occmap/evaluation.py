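"""Matched-unit construction, leave-pair-out CV and ROC/AUC evaluation.

Cases and controls are matched one-to-one on standardized (age, NVIQ)
Euclidean distance by optimal assignment; a surplus case joins the pair whose
control is nearest, forming a triplet (two cases, one control), so a
21-case/20-control stratum yields 19 pairs + 1 triplet and M = 20 units.
Leave-pair-out cross-validation (LPO-CV) holds out one matched unit per
fold: every subject is tested exactly once, and because each unit contains
both classes every outer (and inner) test set is class-mixed.

The one-class classifier is trained on the *target-class* members of the
training units only — standardization statistics included — and scored on
both classes of the held-out unit.  Kernel parameters can be fixed
(ν = 0.1, heuristic γ = 1/d) or tuned by two sequential inner LPO-CV
searches on the training units: first γ over a coarse power-of-two grid
(2⁻¹⁵ … 2³) with ν held at 0.1, refined around the coarse optimum; then ν
over a coarse [0.01, 0.5] and a fine [0.01, 0.3] linear grid with γ fixed.
Ties break toward the smaller parameter value.

A standard soft-margin two-class SVM evaluated under the identical LPO-CV
contract provides the reference performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata
from sklearn import metrics as _skmetrics
from sklearn.svm import SVC

from .svm import KernelSpec, OCCModel, Standardizer, fit_one_class, heuristic_gamma


class EvaluationError(ValueError):
    pass


class UndefinedMetricError(EvaluationError):
    """Both classes are required to compute a ROC curve."""


@dataclass(frozen=True)
class MatchedUnit:
    cases: tuple[str, ...]
    controls: tuple[str, ...]

    @property
    def subjects(self) -> tuple[str, ...]:
        return self.cases + self.controls


@dataclass
class MatchedPartition:
    units: list[MatchedUnit]
    stratum: str = "pooled"

    @property
    def M(self) -> int:
        return len(self.units)

    @property
    def subjects(self) -> list[str]:
        return [s for u in self.units for s in u.subjects]


@dataclass
class OptGrid:
    """Kernel-parameter search grids for the nested LPO-CV optimization."""

    gamma_coarse: np.ndarray = field(default_factory=lambda: 2.0 ** np.arange(-15, 4))
    gamma_refine_halfwidth: float = 1.0   # in log2 units around the coarse argmax
    gamma_refine_step: float = 0.25
    nu_coarse: np.ndarray = field(default_factory=lambda: np.linspace(0.01, 0.5, 10))
    nu_fine: np.ndarray = field(default_factory=lambda: np.linspace(0.01, 0.3, 20))
    nu_init: float = 0.1

    def gamma_fine(self, gamma_opt: float) -> np.ndarray:
        center = np.log2(gamma_opt)
        exps = np.arange(
            center - self.gamma_refine_halfwidth,
            center + self.gamma_refine_halfwidth + 1e-12,
            self.gamma_refine_step,
        )
        return 2.0 ** exps


@dataclass
class CVResult:
    """Out-of-fold decision scores with per-fold chosen parameters."""

    scores: pd.Series            # one score per subject
    labels: pd.Series            # +1 case / -1 control
    fold_params: list[dict]      # per fold: unit index, gamma, nu
    target_class: str
    stratum: str


def _stratum_subjects(subjects: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "pooled":
        return subjects
    if stratum in ("male", "female"):
        return subjects[subjects["sex"] == ("M" if stratum == "male" else "F")]
    raise EvaluationError(f"unknown stratum {stratum!r}")


def match_pairs(subjects: pd.DataFrame, stratum: str = "pooled") -> MatchedPartition:
    """Minimum-cost one-to-one case-control matching on (age, NVIQ).

    Covariates are z-scored over the stratum; assignment minimizes the summed
    Euclidean distance.  Surplus cases (or controls) attach to the pair whose
    matched control (case) is nearest, forming triplets.  Deterministic.
    """
    table = _stratum_subjects(subjects, stratum)
    cases = table[table["group"] == "case"]
    controls = table[table["group"] == "control"]
    if cases.empty or controls.empty:
        raise EvaluationError(f"stratum {stratum!r} lacks cases or controls")
    cov = table[["age_months", "nviq"]].astype(float)
    z = (cov - cov.mean()) / cov.std(ddof=0).replace(0.0, 1.0)
    zc = z.loc[cases.index].to_numpy()
    zk = z.loc[controls.index].to_numpy()
    cost = np.linalg.norm(zc[:, None, :] - zk[None, :, :], axis=2)
    row, col = linear_sum_assignment(cost)
    pairs = [
        [list((cases.index[i],)), list((controls.index[j],))] for i, j in zip(row, col)
    ]
    matched_cases = set(row)
    matched_controls = set(col)
    for i in range(len(cases)):
        if i not in matched_cases:  # surplus case -> nearest matched control's pair
            j_best = min(matched_controls, key=lambda j: cost[i, j])
            k = list(col).index(j_best)
            pairs[k][0].append(cases.index[i])
    for j in range(len(controls)):
        if j not in matched_controls:  # surplus control -> nearest matched case's pair
            i_best = min(matched_cases, key=lambda i: cost[i, j])
            k = list(row).index(i_best)
            pairs[k][1].append(controls.index[j])
    units = [MatchedUnit(cases=tuple(sorted(c)), controls=tuple(sorted(k))) for c, k in pairs]
    units.sort(key=lambda u: u.subjects)
    return MatchedPartition(units=units, stratum=stratum)


def lpo_splits(partition: MatchedPartition):
    """Yield (training units, held-out unit) for each of the M folds."""
    if partition.M < 2:
        raise EvaluationError("leave-pair-out CV needs at least 2 matched units")
    for j in range(partition.M):
        train = [u for i, u in enumerate(partition.units) if i != j]
        yield train, partition.units[j]


def roc_auc(scores, labels, positive: int = 1):
    """AUC (Mann-Whitney with ties counted ½) and the full ROC step curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    neg = ~pos
    if not pos.any() or not neg.any():
        raise UndefinedMetricError("ROC needs both classes present")
    ranks = rankdata(scores)
    n1, n0 = int(pos.sum()), int(neg.sum())
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, thresholds = _skmetrics.roc_curve(pos.astype(int), scores)
    return float(auc), (fpr, tpr, thresholds)


def subgroup_auc(cv: CVResult, subjects: pd.DataFrame, predicate) -> float:
    """AUC restricted to subjects satisfying the predicate (no refitting)."""
    mask = subjects.loc[cv.scores.index].apply(predicate, axis=1).astype(bool)
    if mask.sum() == 0:
        raise UndefinedMetricError("empty subgroup")
    auc, _ = roc_auc(cv.scores[mask.to_numpy()], cv.labels[mask.to_numpy()])
    return auc


def _occ_fold_scores(X, is_target, train_idx, test_idx, gamma, nu):
    """Fit on the target members of the training rows, score the test rows."""
    target_rows = train_idx[is_target[train_idx]]
    if len(target_rows) == 0:
        raise EvaluationError("target class absent from a training fold")
    model = fit_one_class(X[target_rows], nu, KernelSpec("rbf", gamma))
    return model.decision_values(X[test_idx]), model


def _inner_cv_auc(X, is_target, y, units_idx, gamma, nu) -> float:
    scores = np.empty(sum(len(u) for u in units_idx))
    labels = np.empty_like(scores, dtype=int)
    pos = 0
    for j, test in enumerate(units_idx):
        train = np.concatenate([u for i, u in enumerate(units_idx) if i != j])
        s, _ = _occ_fold_scores(X, is_target, train, test, gamma, nu)
        scores[pos : pos + len(test)] = s
        labels[pos : pos + len(test)] = y[test]
        pos += len(test)
    auc, _ = roc_auc(scores, labels, positive=1)
    return auc


def nested_optimize(X, is_target, y, units_idx, grid: OptGrid) -> tuple[float, float]:
    """Two sequential inner LPO-CV searches: γ (ν = ν_init), then ν (γ fixed).

    Ties break toward the smaller γ, then the smaller ν.
    """
    if len(units_idx) < 2:
        raise EvaluationError("nested optimization needs >= 2 training units")

    def argmax_auc(values, evaluate):
        best_v, best_auc = None, -np.inf
        for v in values:
            auc = evaluate(v)
            if auc > best_auc + 1e-12:
                best_v, best_auc = v, auc
        return best_v, best_auc

    gamma_opt, _ = argmax_auc(
        np.sort(grid.gamma_coarse),
        lambda gmm: _inner_cv_auc(X, is_target, y, units_idx, gmm, grid.nu_init),
    )
    gamma_opt, _ = argmax_auc(
        np.sort(grid.gamma_fine(gamma_opt)),
        lambda gmm: _inner_cv_auc(X, is_target, y, units_idx, gmm, grid.nu_init),
    )
    nu_values = np.sort(np.concatenate([grid.nu_coarse, grid.nu_fine]))
    nu_opt, _ = argmax_auc(
        nu_values,
        lambda nv: _inner_cv_auc(X, is_target, y, units_idx, gamma_opt, nv),
    )
    return float(gamma_opt), float(nu_opt)


def _partition_index_sets(features: pd.DataFrame, partition: MatchedPartition):
    loc = {s: i for i, s in enumerate(features.index)}
    missing = [s for s in partition.subjects if s not in loc]
    if missing:
        raise EvaluationError(f"features missing for subject(s) {missing}")
    return [np.array([loc[s] for s in u.subjects], dtype=int) for u in partition.units]


def run_occ_cv(
    features: pd.DataFrame,
    subjects: pd.DataFrame,
    partition: MatchedPartition,
    target_class: str = "case",
    optimize: bool = False,
    nu: float = 0.1,
    gamma: float | str = "heuristic",
    grid: OptGrid | None = None,
) -> CVResult:
    """One-class LPO-CV: train on the target class, score both classes."""
    if target_class not in ("case", "control"):
        raise EvaluationError(f"target_class must be 'case' or 'control', got {target_class!r}")
    X = features.to_numpy(dtype=float)
    order = features.index
    y = subjects.loc[order, "y"].to_numpy(dtype=int)
    is_target = subjects.loc[order, "group"].to_numpy() == target_class
    units_idx = _partition_index_sets(features, partition)
    if gamma == "heuristic":
        gamma = heuristic_gamma(X.shape[1])
    grid = grid or OptGrid()
    scores: dict[str, float] = {}
    fold_params = []
    for j in range(len(units_idx)):
        test = units_idx[j]
        train_units = [u for i, u in enumerate(units_idx) if i != j]
        if optimize:
            g_j, nu_j = nested_optimize(X, is_target, y, train_units, grid)
        else:
            g_j, nu_j = float(gamma), float(nu)
        train = np.concatenate(train_units)
        s, _ = _occ_fold_scores(X, is_target, train, test, g_j, nu_j)
        for idx, val in zip(test, s):
            scores[order[idx]] = float(val)
        fold_params.append({"unit": j, "gamma": g_j, "nu": nu_j})
    subj_order = [s for u in partition.units for s in u.subjects]
    score_series = pd.Series([scores[s] for s in subj_order], index=subj_order, name="score")
    label_series = subjects.loc[subj_order, "y"].astype(int)
    return CVResult(
        scores=score_series,
        labels=label_series,
        fold_params=fold_params,
        target_class=target_class,
        stratum=partition.stratum,
    )


TWO_CLASS_C_GRID = 2.0 ** np.arange(-5, 16)


def run_two_class_cv(
    features: pd.DataFrame,
    subjects: pd.DataFrame,
    partition: MatchedPartition,
    kernel: str = "linear",
    optimize: bool = False,
    C: float = 1.0,
    gamma: float | str = "heuristic",
    grid: OptGrid | None = None,
    c_grid: np.ndarray | None = None,
) -> CVResult:
    """Reference soft-margin binary SVM under the same LPO-CV contract.

    Nested search is sequential like the one-class case: γ first at C = 1
    (RBF only), then C.  The C grid spans 2⁻⁵ … 2¹⁵ by powers of two.
    """
    if kernel not in ("linear", "rbf"):
        raise EvaluationError(f"kernel must be 'linear' or 'rbf', got {kernel!r}")
    X = features.to_numpy(dtype=float)
    order = features.index
    y = subjects.loc[order, "y"].to_numpy(dtype=int)
    units_idx = _partition_index_sets(features, partition)
    grid = grid or OptGrid()
    c_grid = TWO_CLASS_C_GRID if c_grid is None else np.asarray(c_grid, dtype=float)
    if gamma == "heuristic":
        gamma = heuristic_gamma(X.shape[1])

    def fold_scores(train_idx, test_idx, C_v, gamma_v):
        std = Standardizer.fit(X[train_idx])
        clf = SVC(C=C_v, kernel=kernel, gamma=gamma_v if kernel == "rbf" else "scale")
        clf.fit(std.transform(X[train_idx]), y[train_idx])
        return clf.decision_function(std.transform(X[test_idx]))

    def inner_auc(units, C_v, gamma_v):
        ss, ll = [], []
        for j, test in enumerate(units):
            train = np.concatenate([u for i, u in enumerate(units) if i != j])
            ss.append(fold_scores(train, test, C_v, gamma_v))
            ll.append(y[test])
        auc, _ = roc_auc(np.concatenate(ss), np.concatenate(ll))
        return auc

    scores: dict[str, float] = {}
    fold_params = []
    for j in range(len(units_idx)):
        test = units_idx[j]
        train_units = [u for i, u in enumerate(units_idx) if i != j]
        g_j = float(gamma)
        C_j = float(C)
        if optimize:
            if kernel == "rbf":
                best = max(
                    np.sort(grid.gamma_coarse),
                    key=lambda gv: (inner_auc(train_units, 1.0, gv), -gv),
                )
                g_j = float(best)
            C_j = float(
                max(np.sort(c_grid), key=lambda cv: (inner_auc(train_units, cv, g_j), -cv))
            )
        train = np.concatenate(train_units)
        s = fold_scores(train, test, C_j, g_j)
        for idx, val in zip(test, s):
            scores[order[idx]] = float(val)
        fold_params.append({"unit": j, "C": C_j, "gamma": g_j if kernel == "rbf" else None})
    subj_order = [s for u in partition.units for s in u.subjects]
    score_series = pd.Series([scores[s] for s in subj_order], index=subj_order, name="score")
    return CVResult(
        scores=score_series,
        labels=subjects.loc[subj_order, "y"].astype(int),
        fold_params=fold_params,
        target_class="both",
        stratum=partition.stratum,
    )
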