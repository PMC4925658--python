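"""The ν-one-class SVM, SVDD, and RBF kernel machinery.

The one-class SVM places a hyperplane in the kernel feature space separating
the target class from the origin with maximal margin.  Its dual is

    min_α  ½ Σ_ij α_i α_j k(x_i, x_j)   s.t.  0 ≤ α_i ≤ 1/(νN),  Σ_i α_i = 1,

with decision function f(x) = Σ_i α_i k(x_i, x) − ρ (positive: target-like).
ν ∈ (0, 1] is simultaneously an upper bound on the fraction of training
points left outside the boundary and a lower bound on the support-vector
fraction.  SVDD (the minimal enclosing hypersphere description) solves

    min_α  Σ_ij α_i α_j K_ij − Σ_i α_i K_ii   s.t.  0 ≤ α_i ≤ C,  Σ α_i = 1,

and with an RBF kernel (unit diagonal) and C = 1/(νN) the two duals share
the same minimizer, hence identical support vectors and rank-identical
scores.

Features on heterogeneous physical scales (mm², mm³, mm⁻¹ …) would otherwise
dominate RBF distances, so fitting z-scores each feature with target-class
training statistics by default and applies the same transform to test rows.

The SMO-style solver in :mod:`occmap._smo` is the production path; a generic
convex-QP reference (:func:`qp_reference`) is retained strictly as an
independent oracle for the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.spatial.distance import cdist

from ._smo import solve_box_simplex

#: Default heuristic: γ = 1 / (number of features).
def heuristic_gamma(n_features: int) -> float:
    return 1.0 / n_features


class SolverError(RuntimeError):
    """Dual optimization failed to converge."""


@dataclass(frozen=True)
class KernelSpec:
    family: str = "rbf"
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "rbf":
            if self.gamma is None or self.gamma <= 0:
                raise ValueError("rbf kernel requires gamma > 0")

    def gram(self, X: np.ndarray, X2: np.ndarray | None = None) -> np.ndarray:
        if X2 is None:
            X2 = X
        if X.shape[1] != X2.shape[1]:
            raise ValueError(f"feature dimension mismatch: {X.shape[1]} vs {X2.shape[1]}")
        if self.family == "linear":
            return X @ X2.T
        return rbf_kernel(X, X2, self.gamma)


def rbf_kernel(X: np.ndarray, X2: np.ndarray, gamma: float) -> np.ndarray:
    """Gram matrix exp(−γ‖x − x′‖²); entries in (0, 1], unit diagonal for X2=X."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X.shape[1] != X2.shape[1]:
        raise ValueError(f"feature dimension mismatch: {X.shape[1]} vs {X2.shape[1]}")
    d2 = cdist(X, X2, metric="sqeuclidean")
    return np.exp(-gamma * d2)


@dataclass
class Standardizer:
    """Per-feature z-scoring learned on the training target class.

    Zero-variance features get unit scale, so a constant column contributes a
    constant (zero) coordinate and leaves RBF distances unchanged.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scale + self.mean


@dataclass
class OCCModel:
    """Fitted ν-one-class SVM (support vectors, dual weights, offset)."""

    support_vectors: np.ndarray
    alphas: np.ndarray
    rho: float
    nu: float
    kernel: KernelSpec
    n_train: int
    standardizer: Standardizer | None = None
    support_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return decision_values(self, X)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model": "nu-one-class-svm",
            "nu": self.nu,
            "rho": self.rho,
            "n_train": self.n_train,
            "kernel": {"family": self.kernel.family, "gamma": self.kernel.gamma},
            "alphas": self.alphas.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "support_idx": self.support_idx.tolist(),
            "standardizer": None
            if self.standardizer is None
            else {"mean": self.standardizer.mean.tolist(), "scale": self.standardizer.scale.tolist()},
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "OCCModel":
        payload = json.loads(text)
        std = payload["standardizer"]
        return cls(
            support_vectors=np.asarray(payload["support_vectors"], dtype=float),
            alphas=np.asarray(payload["alphas"], dtype=float),
            rho=float(payload["rho"]),
            nu=float(payload["nu"]),
            kernel=KernelSpec(**payload["kernel"]),
            n_train=int(payload["n_train"]),
            standardizer=None
            if std is None
            else Standardizer(np.asarray(std["mean"]), np.asarray(std["scale"])),
            support_idx=np.asarray(payload["support_idx"], dtype=int),
        )


@dataclass
class SVDDModel:
    """Fitted support vector data description (minimal enclosing sphere)."""

    support_vectors: np.ndarray
    alphas: np.ndarray
    C: float
    radius2: float
    center_norm2: float
    kernel: KernelSpec
    n_train: int
    standardizer: Standardizer | None = None
    support_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """R² − ‖φ(x) − center‖²: positive inside the sphere."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.standardizer is not None:
            X = self.standardizer.transform(X)
        k_xx = np.ones(X.shape[0]) if self.kernel.family == "rbf" else np.sum(X * X, axis=1)
        cross = self.kernel.gram(X, self.support_vectors) @ self.alphas
        return self.radius2 - (k_xx - 2.0 * cross + self.center_norm2)


_SV_EPS = 1e-9


def _fit_dual(K: np.ndarray, p: np.ndarray, upper: float, tol: float, max_iter: int):
    alpha, n_iter, gap = solve_box_simplex(
        np.ascontiguousarray(K, dtype=float), np.ascontiguousarray(p, dtype=float),
        float(upper), float(tol), int(max_iter),
    )
    if gap > max(tol, 1e-8):
        raise SolverError(
            f"SMO did not converge: KKT gap {gap:.3e} after {n_iter} iterations"
        )
    return alpha


def fit_one_class(
    X_target: np.ndarray,
    nu: float,
    kernel: KernelSpec,
    standardize: bool = True,
    tol: float = 1e-10,
    max_iter: int = 10_000_000,
) -> OCCModel:
    """Solve the ν-one-class SVM dual on the target class.

    ρ is the average of Σ_j α_j k(x_j, x_s) over margin support vectors
    (0 < α_s < 1/(νN)); if every support vector sits at a bound, the midpoint
    of the max/min of that quantity over support vectors is used.  Support
    vectors are kept in training-row order (deterministic tie-breaking).
    """
    X = np.atleast_2d(np.asarray(X_target, dtype=float))
    if not 0.0 < nu <= 1.0:
        raise ValueError("nu must lie in (0, 1]")
    n = X.shape[0]
    if n < 1:
        raise ValueError("target set is empty")
    standardizer = Standardizer.fit(X) if standardize else None
    Z = standardizer.transform(X) if standardize else X
    upper = 1.0 / (nu * n)
    K = kernel.gram(Z)
    alpha = _fit_dual(K, np.zeros(n), upper, tol, max_iter)
    sv = alpha > _SV_EPS * upper
    f_train = K @ alpha
    free = sv & (alpha < upper * (1.0 - 1e-7))
    if free.any():
        rho = float(f_train[free].mean())
    else:
        vals = f_train[sv]
        rho = float(0.5 * (vals.max() + vals.min()))
    return OCCModel(
        support_vectors=Z[sv],
        alphas=alpha[sv],
        rho=rho,
        nu=nu,
        kernel=kernel,
        n_train=n,
        standardizer=standardizer,
        support_idx=np.flatnonzero(sv),
    )


def decision_values(model: OCCModel, X: np.ndarray) -> np.ndarray:
    """f(x) = Σ_i α_i k(x_i, x) − ρ; positive = target-like, negative = outlier."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.standardizer is not None:
        X = model.standardizer.transform(X)
    if X.shape[1] != model.support_vectors.shape[1]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match training ({model.support_vectors.shape[1]})"
        )
    return model.kernel.gram(X, model.support_vectors) @ model.alphas - model.rho


def fit_svdd(
    X_target: np.ndarray,
    C: float,
    kernel: KernelSpec,
    standardize: bool = True,
    tol: float = 1e-10,
    max_iter: int = 10_000_000,
) -> SVDDModel:
    """Solve the SVDD dual (minimal enclosing sphere with slack bound C)."""
    X = np.atleast_2d(np.asarray(X_target, dtype=float))
    n = X.shape[0]
    if C < 1.0 / n:
        raise ValueError(f"C = {C} is infeasible: C must be >= 1/N = {1.0 / n}")
    standardizer = Standardizer.fit(X) if standardize else None
    Z = standardizer.transform(X) if standardize else X
    K = kernel.gram(Z)
    diag = np.diag(K).copy()
    alpha = _fit_dual(K, 0.5 * diag, C, tol, max_iter)
    sv = alpha > _SV_EPS * C
    center_norm2 = float(alpha @ K @ alpha)
    # radius from margin support vectors (0 < alpha < C); fall back to all SVs
    dist2 = diag - 2.0 * (K @ alpha) + center_norm2
    free = sv & (alpha < C * (1.0 - 1e-7))
    radius2 = float(dist2[free].mean()) if free.any() else float(0.5 * (dist2[sv].max() + dist2[sv].min()))
    return SVDDModel(
        support_vectors=Z[sv],
        alphas=alpha[sv],
        C=C,
        radius2=radius2,
        center_norm2=center_norm2,
        kernel=kernel,
        n_train=n,
        standardizer=standardizer,
        support_idx=np.flatnonzero(sv),
    )


def qp_reference(K: np.ndarray, p: np.ndarray, upper: float) -> tuple[np.ndarray, float]:
    """Generic convex-QP solution of min ½αᵀKα − pᵀα on the box-simplex.

    Independent oracle for tests: SLSQP from a feasible interior start,
    followed by an exact KKT polish (equality-constrained linear solve on the
    detected active set).  Never used by the fitting path.
    """
    n = K.shape[0]
    K = np.asarray(K, dtype=float)
    p = np.asarray(p, dtype=float)

    def obj(a):
        return 0.5 * a @ K @ a - p @ a

    def grad(a):
        return K @ a - p

    x0 = np.full(n, min(upper, 1.0 / n))
    x0 *= 1.0 / x0.sum()
    res = optimize.minimize(
        obj,
        x0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, upper)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0, "jac": lambda a: np.ones(n)}],
        options={"maxiter": 2000, "ftol": 1e-16},
    )
    a = np.clip(res.x, 0.0, upper)
    # KKT polish: fix the active set implied by the SLSQP solution and solve
    # the reduced equality-constrained QP exactly.
    for _ in range(4):
        at_lo = a < 1e-7
        at_up = a > upper - 1e-7
        free = ~(at_lo | at_up)
        if not free.any():
            break
        idx = np.flatnonzero(free)
        m = len(idx)
        mass = 1.0 - upper * at_up.sum()
        A = np.zeros((m + 1, m + 1))
        A[:m, :m] = K[np.ix_(idx, idx)]
        A[:m, m] = 1.0
        A[m, :m] = 1.0
        b = np.zeros(m + 1)
        b[:m] = p[idx] - upper * K[np.ix_(idx, np.flatnonzero(at_up))].sum(axis=1)
        b[m] = mass
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            break
        a_new = a.copy()
        a_new[idx] = sol[:m]
        if (a_new < -1e-10).any() or (a_new > upper + 1e-10).any():
            break
        a_new = np.clip(a_new, 0.0, upper)
        if np.abs(a_new - a).max() < 1e-14:
            a = a_new
            break
        a = a_new
    return a, float(obj(a))
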