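"""Approximate RBF preimage of the one-class weight vector.

The fitted one-class SVM has weight vector w = Σ_i α_i φ(x_i) in the kernel
feature space.  Under the RBF map w generally has no exact preimage, but the
point z minimizing ‖w − φ(z)‖² (equivalently maximizing Σ_i α_i k(x_i, z))
satisfies the fixed-point condition

    z = Σ_i α_i exp(−γ‖z − x_i‖²) x_i  /  Σ_i α_i exp(−γ‖z − x_i‖²),

which is iterated to convergence.  Because every α_i ≥ 0, each iterate — and
hence the limit — lies in the convex hull of the support vectors.  The map
can have several basins of attraction, so the search is multi-start: the
default start is the α-weighted mean of the support vectors, with additional
restarts from individual support vectors sampled proportionally to α.  Among
converged runs the z with the largest feature-space objective is returned.

Each component of z corresponds to one input feature, so for morphometry
models z is a per-feature discriminative map.  z is computed on the model's
standardized scale; the native-unit back-transform is also reported when the
model carries a standardizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._smo import preimage_iterate
from .svm import OCCModel


class PreimageError(RuntimeError):
    """All restarts of the fixed-point iteration diverged."""

    def __init__(self, message: str, best: "PreimageResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass
class PreimageResult:
    z: np.ndarray
    converged: bool
    n_iterations: int
    residual: float
    restarts_used: int
    objective: float
    z_native: np.ndarray | None = None


def fixed_point_step(z: np.ndarray, model: OCCModel) -> np.ndarray:
    """One update of the preimage fixed-point map (RBF kernels only)."""
    if model.kernel.family != "rbf":
        raise ValueError("the fixed-point preimage map requires an RBF kernel")
    z = np.asarray(z, dtype=float)
    sv = model.support_vectors
    if z.shape[0] != sv.shape[1]:
        raise ValueError(f"z has dimension {z.shape[0]}, support vectors have {sv.shape[1]}")
    w = model.alphas * np.exp(-model.kernel.gamma * np.sum((sv - z) ** 2, axis=1))
    denom = w.sum()
    if denom < 1e-300:
        raise PreimageError("fixed-point denominator underflow: z escaped the data support")
    return (w @ sv) / denom


def compute_preimage(
    model: OCCModel,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    n_restarts: int = 5,
    rng: np.random.Generator | int | None = None,
) -> PreimageResult:
    """Multi-start fixed-point search for the preimage of the model weight vector.

    For a linear kernel the primal w = Σ α_i x_i is exact and returned
    directly.  For RBF, runs 1 + ``n_restarts`` starts (α-weighted SV mean,
    then SVs sampled by α weight) and returns the best converged iterate by
    the objective Σ_i α_i k(x_i, z).
    """
    sv = model.support_vectors
    alphas = model.alphas
    if model.kernel.family == "linear":
        z = alphas @ sv
        return _finalize(model, z, True, 0, 0.0, 0, float(alphas @ (sv @ z)))
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    gamma = model.kernel.gamma
    starts = [alphas @ sv / alphas.sum()]
    if len(sv) == 1:
        n_restarts = 0
    weights = alphas / alphas.sum()
    for _ in range(n_restarts):
        starts.append(sv[rng.choice(len(sv), p=weights)].astype(float).copy())
    best: PreimageResult | None = None
    restarts_used = 0
    for s, z0 in enumerate(starts):
        z0 = np.ascontiguousarray(z0, dtype=float)
        z, converged, n_iter, residual, obj, ok = preimage_iterate(
            np.ascontiguousarray(sv, dtype=float),
            np.ascontiguousarray(alphas, dtype=float),
            float(gamma), z0, float(tol), int(max_iter),
        )
        restarts_used = s
        cand = PreimageResult(
            z=z, converged=bool(converged and ok), n_iterations=int(n_iter),
            residual=float(residual), restarts_used=s, objective=float(obj),
        )
        if best is None or (cand.converged and not best.converged):
            best = cand
        elif cand.converged == best.converged and cand.objective > best.objective:
            best = cand
    assert best is not None
    if not best.converged:
        raise PreimageError(
            f"no restart converged within {max_iter} iterations "
            f"(best residual {best.residual:.3e})",
            best=best,
        )
    return _finalize(
        model, best.z, best.converged, best.n_iterations, best.residual,
        restarts_used, best.objective,
    )


def _finalize(model, z, converged, n_iter, residual, restarts, objective) -> PreimageResult:
    z_native = None
    if model.standardizer is not None:
        z_native = model.standardizer.inverse_transform(z)
    return PreimageResult(
        z=np.asarray(z, dtype=float),
        converged=converged,
        n_iterations=n_iter,
        residual=residual,
        restarts_used=restarts,
        objective=objective,
        z_native=z_native,
    )
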