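"""Batch-effect removal with Distance Weighted Discrimination (DWD).

Two cohorts profiled under different conditions show a systematic location
bias in gene-expression space.  DWD finds the direction that best separates
the two batches — minimizing the sum of inverse margins, which unlike the SVM
uses *every* sample and is well suited to the high-dimension/low-sample-size
regime of microarray data — and each batch is then translated along that
direction until its mean projection is zero.  Within-batch geometry is
untouched: the adjustment is a pure translation per batch.

The optimization solved here is

    minimize   sum_i 1/r_i + C * sum_i xi_i
    subject to r_i = y_i (w . x_i + b) + xi_i,  r_i > 0,  xi_i >= 0,
               ||w||_2 <= 1,

with y_i = -1 for batch A and +1 for batch B.  Eliminating the slacks
analytically turns this into the equivalent smooth convex problem

    minimize_{||w|| <= 1, b}  sum_i V_C( y_i (w . x_i + b) ),
    V_C(u) = 1/u              if u >= 1/sqrt(C)
           = 2*sqrt(C) - C*u  otherwise,

and because the objective depends on w only through inner products with the
samples, the minimizer lies in the span of the samples; the solve runs over
one coefficient per sample plus the intercept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = ["DwdModel", "fit_dwd", "dwd_adjust", "pca_project", "default_penalty"]


@dataclass
class DwdModel:
    """Fitted DWD separating direction between two batches.

    Attributes
    ----------
    direction : pandas.Series
        Unit-norm vector over genes; oriented so the batch-B mean projection
        is at least the batch-A mean projection.
    intercept : float
        Offset b of the separating function w.x + b.
    penalty : float
        The slack penalty C used in the fit.
    mean_projections : dict
        Mean projection of each training batch onto the direction.
    """

    direction: pd.Series
    intercept: float
    penalty: float
    mean_projections: dict

    def __post_init__(self):
        norm = float(np.linalg.norm(self.direction.to_numpy()))
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError(f"direction must have unit norm, got {norm:.6f}")
        if self.penalty <= 0:
            raise ValueError("penalty must be positive")

    def to_json(self, path) -> None:
        payload = {
            "genes": list(map(str, self.direction.index)),
            "direction": self.direction.to_numpy().tolist(),
            "intercept": self.intercept,
            "penalty": self.penalty,
            "mean_projections": {str(k): float(v) for k, v in self.mean_projections.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "DwdModel":
        with open(path) as fh:
            payload = json.load(fh)
        direction = pd.Series(payload["direction"], index=payload["genes"])
        return cls(
            direction=direction,
            intercept=payload["intercept"],
            penalty=payload["penalty"],
            mean_projections=payload["mean_projections"],
        )


def default_penalty(X_a: np.ndarray, X_b: np.ndarray) -> float:
    """Heuristic slack penalty: 100 / (median between-batch distance)^2."""
    d2 = (
        (X_a * X_a).sum(axis=1)[:, None]
        + (X_b * X_b).sum(axis=1)[None, :]
        - 2.0 * X_a @ X_b.T
    )
    med = float(np.median(np.sqrt(np.maximum(d2, 0.0))))
    if med == 0.0:
        return 100.0
    return 100.0 / med**2


def _dwd_loss_grad(u: np.ndarray, c: float):
    """DWD loss V_C and derivative, elementwise over signed margins u."""
    thresh = 1.0 / np.sqrt(c)
    big = u >= thresh
    val = np.where(big, 1.0 / np.where(big, u, 1.0), 2.0 * np.sqrt(c) - c * u)
    grad = np.where(big, -1.0 / np.where(big, u, 1.0) ** 2, -c)
    return val, grad


def fit_dwd(X_a: pd.DataFrame, X_b: pd.DataFrame, penalty: float | None = None) -> DwdModel:
    """Fit the DWD separating direction between two expression batches.

    Parameters
    ----------
    X_a, X_b : DataFrame
        Gene-by-sample expression matrices with identical gene lists; each
        batch needs at least 2 samples.
    penalty : float, optional
        Slack penalty C; defaults to 100 / (median between-batch distance)^2.
    """
    if not X_a.index.equals(X_b.index):
        raise ValueError("gene lists of the two batches do not match")
    if X_a.shape[1] < 2 or X_b.shape[1] < 2:
        raise ValueError("each batch needs at least 2 samples")

    A = X_a.to_numpy(dtype=float).T  # samples x genes
    B = X_b.to_numpy(dtype=float).T
    if penalty is None:
        penalty = default_penalty(A, B)
    if penalty <= 0:
        raise ValueError("penalty must be positive")

    X = np.vstack([A, B])
    y = np.concatenate([-np.ones(len(A)), np.ones(len(B))])
    K = X @ X.T
    n = len(y)

    # feasible start along the mean-difference direction
    alpha0 = np.where(y > 0, 1.0 / len(B), -1.0 / len(A))
    q = float(alpha0 @ K @ alpha0)
    alpha0 = alpha0 / np.sqrt(q) * 0.9 if q > 0 else np.zeros(n)
    proj0 = K @ alpha0
    b0 = -0.5 * (proj0[y < 0].mean() + proj0[y > 0].mean())
    z0 = np.append(alpha0, b0)

    def objective(z):
        alpha, b = z[:-1], z[-1]
        u = y * (K @ alpha + b)
        val, grad = _dwd_loss_grad(u, penalty)
        g_alpha = K @ (y * grad)
        g_b = float(np.dot(y, grad))
        return float(val.sum()), np.append(g_alpha, g_b)

    def constraint(z):
        alpha = z[:-1]
        return 1.0 - float(alpha @ K @ alpha)

    def constraint_jac(z):
        alpha = z[:-1]
        return np.append(-2.0 * (K @ alpha), 0.0)

    res = minimize(
        objective,
        z0,
        jac=True,
        method="SLSQP",
        constraints=[{"type": "ineq", "fun": constraint, "jac": constraint_jac}],
        options={"maxiter": 2000, "ftol": 1e-10},
    )
    if not res.success and res.status != 8:  # 8: positive directional derivative (flat)
        raise RuntimeError(
            f"DWD fit failed to converge: {res.message} (iterations={res.nit}, "
            f"objective={res.fun:.6g})"
        )

    alpha, b = res.x[:-1], res.x[-1]
    w = X.T @ alpha
    norm = np.linalg.norm(w)
    if norm == 0:
        raise RuntimeError("DWD fit failed: degenerate zero direction")
    w = w / norm
    b = b / norm

    proj_a = A @ w
    proj_b = B @ w
    if proj_b.mean() < proj_a.mean():
        w, b = -w, -b
        proj_a, proj_b = -proj_a, -proj_b

    return DwdModel(
        direction=pd.Series(w, index=X_a.index),
        intercept=float(b),
        penalty=float(penalty),
        mean_projections={"A": float(proj_a.mean()), "B": float(proj_b.mean())},
    )


def dwd_adjust(matrices, model: DwdModel, target: str = "zero") -> list[pd.DataFrame]:
    """Translate each batch along the DWD direction to a common mean projection.

    Every input matrix is treated as one batch and shifted along the
    direction so all batch mean projections agree; deviations of samples
    from their batch mean are untouched (pure translation per batch).

    target="zero" moves every batch's mean projection to zero (symmetric;
    neither batch serves as reference).  target="reference" keeps the first
    matrix fixed and moves the others onto its mean projection — used when a
    new cohort is brought into an already-established space, so centroids
    and frozen cut-points keep their frame.
    """
    if target not in ("zero", "reference"):
        raise ValueError("target must be 'zero' or 'reference'")
    w = model.direction
    wv = w.to_numpy()
    anchor = 0.0
    adjusted = []
    for i, mat in enumerate(matrices):
        if not mat.index.equals(w.index):
            raise ValueError("matrix gene list does not match the fitted model")
        proj_mean = float((wv @ mat.to_numpy(dtype=float)).mean())
        if i == 0 and target == "reference":
            anchor = proj_mean
            adjusted.append(mat.copy())
            continue
        adjusted.append(mat.sub((proj_mean - anchor) * wv, axis=0))
    return adjusted


class PcaProjection(NamedTuple):
    """Sample scores on leading principal axes plus explained variance."""

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca_project(matrix: pd.DataFrame, n_components: int = 2) -> PcaProjection:
    """Project samples onto the first principal axes of the gene-centered data.

    Used as the before/after diagnostic for batch adjustment: well-mixed
    batches overlap in PC1 x PC2 space.
    """
    n_genes, n_samples = matrix.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > min(n_genes, n_samples):
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, samples)={min(n_genes, n_samples)}"
        )
    centered = matrix.to_numpy(dtype=float) - matrix.to_numpy(dtype=float).mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = (vt[:n_components].T * s[:n_components])
    total = float((s**2).sum())
    evr = (s[:n_components] ** 2 / total) if total > 0 else np.zeros(n_components)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PcaProjection(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=cols),
        explained_variance_ratio=evr,
    )
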