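"""Cross-cohort merging via distance-weighted discrimination (DWD).

DWD finds the direction w (unit norm, with intercept b) minimising
``sum_i 1/r_i + C * sum_i xi_i`` with residuals
``r_i = y_i (w.x_i + b) + xi_i > 0``, ``xi_i >= 0`` — a margin criterion
that, unlike the SVM, lets every sample pull on the separating
hyperplane, which makes it well suited to estimating a systematic batch
direction. The slack variables have a closed-form optimum given the
margins, collapsing the problem to a smooth convex function of (w, b):

    V(m) = 1/m            if m >= 1/sqrt(C)
           2*sqrt(C)-C*m  otherwise

minimised under ||w|| <= 1. Because the objective depends on w only
through the projections w.x_i, the minimiser may be taken in the span of
the samples; the solve runs in those (at most n) coordinates, exactly.

Merging subtracts each cohort's mean projection along w, so both cohort
means on the batch direction become zero and all variation orthogonal to
w is untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial.distance import pdist

from .containers import ExpressionMatrix

__all__ = ["DWDModel", "dwd_direction", "dwd_adjust", "default_penalty"]


class DWDConvergenceError(RuntimeError):
    """Raised when the DWD solver fails; carries solver diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class DWDModel:
    """Fitted DWD direction over genes (unit norm) with diagnostics."""

    direction: pd.Series  # indexed by gene, ||.||_2 = 1
    intercept: float
    penalty: float
    objective: float
    converged: bool

    @property
    def w(self) -> np.ndarray:
        return self.direction.to_numpy()

    def project(self, expr: ExpressionMatrix) -> pd.Series:
        """Projection w.x of each sample onto the batch direction."""
        sub = expr.values.reindex(self.direction.index)
        if sub.isna().to_numpy().any():
            raise KeyError("expression matrix lacks genes of the DWD direction")
        return pd.Series(self.w @ sub.to_numpy(), index=expr.sample_ids)


def default_penalty(X: np.ndarray) -> float:
    """Customary DWD penalty: 100 / (median pairwise distance)^2."""
    n = X.shape[1]
    if n > 400:  # subsample pairs for the median; deterministic
        idx = np.linspace(0, n - 1, 400).astype(int)
        X = X[:, idx]
    d = pdist(X.T)
    med = np.median(d[d > 0]) if (d > 0).any() else 1.0
    return 100.0 / med**2


def _dwd_objective(C: float):
    thresh = 1.0 / np.sqrt(C)

    def value_grad(m: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        above = m >= thresh
        v = np.where(above, 1.0 / np.where(above, m, 1.0), 2.0 * np.sqrt(C) - C * m)
        g = np.where(above, -1.0 / np.where(above, m, 1.0) ** 2, -C)
        return v, g

    return value_grad


def dwd_direction(
    X: ExpressionMatrix,
    batch: np.ndarray,
    C: Optional[float] = None,
    pca_dim: Optional[int] = None,
) -> DWDModel:
    """Fit the DWD separating direction between two batches.

    Parameters
    ----------
    X : ExpressionMatrix (genes x samples)
    batch : array of +1/-1 labels per sample
    C : slack penalty; default ``100 / median pairwise distance squared``
    pca_dim : optionally truncate the sample-span coordinates to this many
        principal components before solving (speed knob for very wide
        matrices); by default the solve is exact in the full span.
    """
    y = np.asarray(batch, dtype=float)
    if set(np.unique(y)) - {1.0, -1.0}:
        raise ValueError("batch labels must be +1/-1")
    if (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("each batch needs at least 2 samples")
    M = X.values.to_numpy()
    d, n = M.shape
    if d < 1:
        raise ValueError("need at least one gene")
    if C is None:
        C = default_penalty(M)

    # exact reduction to the span of the samples
    center = M.mean(axis=1, keepdims=True)
    Mc = M - center
    U, s, _ = np.linalg.svd(Mc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 1
    if pca_dim is not None:
        rank = min(rank, pca_dim)
    U = U[:, :rank]
    Z = U.T @ Mc  # (rank, n) coordinates

    value_grad = _dwd_objective(C)

    def fun(theta):
        a, b = theta[:-1], theta[-1]
        m = y * (a @ Z + b)
        v, g = value_grad(m)
        grad_a = Z @ (g * y)
        grad_b = float((g * y).sum())
        return float(v.sum()), np.concatenate([grad_a, [grad_b]])

    def solve(theta0):
        return optimize.minimize(
            fun,
            theta0,
            jac=True,
            method="SLSQP",
            constraints=[
                {
                    "type": "ineq",
                    "fun": lambda t: 1.0 - t[:-1] @ t[:-1],
                    "jac": lambda t: np.concatenate([-2.0 * t[:-1], [0.0]]),
                }
            ],
            options={"maxiter": 500, "ftol": 1e-12},
        )

    def solve_normalized(theta0):
        """Unconstrained fallback over w = a/||a|| (optimum has ||w|| = 1)."""

        def fun_norm(theta):
            a, b = theta[:-1], theta[-1]
            na = np.linalg.norm(a)
            if na < 1e-12:
                return 1e12, np.zeros_like(theta)
            what = a / na
            m = y * (what @ Z + b)
            v, g = value_grad(m)
            grad_w = Z @ (g * y)
            grad_a = (grad_w - what * (what @ grad_w)) / na
            return float(v.sum()), np.concatenate([grad_a, [float((g * y).sum())]])

        res = optimize.minimize(
            fun_norm, theta0, jac=True, method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        a = res.x[:-1]
        na = np.linalg.norm(a)
        if na > 1e-12:  # report on the unit sphere
            res.x = np.concatenate([a / na, [res.x[-1]]])
        return res

    # init: normalised mean-difference direction
    mu_diff = Z[:, y == 1].mean(axis=1) - Z[:, y == -1].mean(axis=1)
    nd = np.linalg.norm(mu_diff)
    a0 = mu_diff / nd if nd > 0 else np.zeros(rank)
    res = solve(np.concatenate([0.9 * a0, [0.0]]))
    if not res.success:
        candidates = [res] if np.isfinite(res.fun) else []
        retry = solve_normalized(np.concatenate([0.9 * a0, [0.0]]))
        if np.isfinite(retry.fun):
            candidates.append(retry)
        rng = np.random.default_rng(0)
        for _ in range(2):
            theta0 = np.concatenate([0.5 * a0 + 0.1 * rng.standard_normal(rank), [0.0]])
            extra = solve(theta0)
            if extra.success:
                candidates.append(extra)
                break
        ok = [c for c in candidates if c.success]
        if ok:
            res = min(ok, key=lambda c: c.fun)
        elif candidates:
            # accept a stalled iterate if independent solves agree on the
            # objective (SLSQP line searches can fail at the optimum)
            best = min(candidates, key=lambda c: c.fun)
            others = [c for c in candidates if c is not best]
            if others and min(abs(c.fun - best.fun) for c in others) < 1e-4 * (
                1 + abs(best.fun)
            ):
                res = best
            else:
                raise DWDConvergenceError(
                    f"DWD solver did not converge: {res.message}",
                    diagnostics={"status": res.status, "objective": float(res.fun)},
                )
        else:
            raise DWDConvergenceError(
                f"DWD solver did not converge: {res.message}",
                diagnostics={"status": res.status, "objective": float(res.fun)},
            )

    a, b = res.x[:-1], float(res.x[-1])
    norm = np.linalg.norm(a)
    if norm <= 1e-8:
        # no separating direction (e.g. identical batches): fall back to
        # the leading principal component, a deterministic unit vector
        warnings.warn(
            "DWD found no separating direction; using the leading principal "
            "component (batches are indistinguishable)",
            UserWarning,
        )
        w = U[:, 0]
        b_full = -float(w @ center.ravel())
        m = y * (w @ M + b_full)
        v, _ = value_grad(m)
        return DWDModel(
            direction=pd.Series(w, index=X.gene_ids),
            intercept=b_full,
            penalty=float(C),
            objective=float(v.sum()),
            converged=True,
        )
    w = U @ (a / norm)
    # undo the centring: a.Z + b = w.x - w.center + b
    b_full = b / norm - float(w @ center.ravel())
    return DWDModel(
        direction=pd.Series(w, index=X.gene_ids),
        intercept=b_full,
        penalty=float(C),
        objective=float(res.fun),
        converged=True,
    )


def dwd_adjust(
    X_a: ExpressionMatrix,
    X_b: ExpressionMatrix,
    C: Optional[float] = None,
    pca_dim: Optional[int] = None,
    model: Optional[DWDModel] = None,
    return_model: bool = False,
):
    """Merge two cohorts by zeroing their mean projections on the DWD axis.

    The gene universes are intersected (dropping non-shared genes with a
    warning); the fitted direction w separates cohort a (+1) from cohort b
    (-1); each cohort is then translated along w so its mean projection is
    exactly 0. Variation orthogonal to w is untouched and cohort labels
    are preserved. Pass a pre-fitted ``model`` to reuse a direction.
    """
    shared = [g for g in X_a.gene_ids if g in set(X_b.gene_ids)]
    if not shared:
        raise ValueError("cohorts share no genes")
    if len(shared) < X_a.n_genes or len(shared) < X_b.n_genes:
        warnings.warn(
            f"gene universes differ; intersecting to {len(shared)} shared genes",
            UserWarning,
        )
    A = X_a.subset_genes(shared)
    B = X_b.subset_genes(shared)
    if A.n_samples < 2 or B.n_samples < 2:
        raise ValueError("each cohort needs at least 2 samples")

    overlap = set(A.sample_ids) & set(B.sample_ids)
    if overlap:
        warnings.warn("overlapping sample IDs; suffixing with |a and |b", UserWarning)
        A = ExpressionMatrix(
            A.values.rename(columns=lambda c: f"{c}|a"),
            A.cohort.rename(index=lambda c: f"{c}|a"),
        )
        B = ExpressionMatrix(
            B.values.rename(columns=lambda c: f"{c}|b"),
            B.cohort.rename(index=lambda c: f"{c}|b"),
        )

    merged_vals = pd.concat([A.values, B.values], axis=1)
    labels = np.concatenate([np.ones(A.n_samples), -np.ones(B.n_samples)])
    merged = ExpressionMatrix(merged_vals, pd.concat([A.cohort, B.cohort]))
    if model is None:
        model = dwd_direction(merged, labels, C=C, pca_dim=pca_dim)
    w = model.direction.reindex(merged.gene_ids)
    if w.isna().any():
        raise KeyError("supplied DWD model lacks genes of the merged matrix")
    w = w.to_numpy()
    proj = w @ merged_vals.to_numpy()
    out = merged_vals.to_numpy().copy()
    for mask in (labels == 1, labels == -1):
        out[:, mask] -= np.outer(w, np.full(mask.sum(), proj[mask].mean()))
    adjusted = ExpressionMatrix(
        pd.DataFrame(out, index=merged.gene_ids, columns=merged.sample_ids),
        merged.cohort,
    )
    if return_model:
        return adjusted, model
    return adjusted
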