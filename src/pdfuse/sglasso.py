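"""Sparse group lasso by block-coordinate proximal descent.

Minimizes, over coefficient vector beta partitioned into L groups,

    1/2 ||y - sum_l X_l beta_l||^2  +  lam1 sum_l ||beta_l||_2
                                    +  lam2 ||beta||_1

lam1 controls inter-group sparsity (whole groups zeroed), lam2 controls
intra-group sparsity. One outer sweep updates each group in turn: a
groupwise screening condition decides whether the group is exactly zero;
otherwise proximal-gradient steps alternate an elementwise
soft-threshold (lam2) with a group soft-threshold (lam1).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin


def soft_threshold(z: np.ndarray, t: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def group_soft_threshold(z: np.ndarray, t: float) -> np.ndarray:
    norm = np.linalg.norm(z)
    if norm <= t or norm == 0.0:
        return np.zeros_like(z)
    return (1.0 - t / norm) * z


def sglasso_objective(
    X: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    group_index: list[np.ndarray],
    lam1: float,
    lam2: float,
) -> float:
    resid = y - X @ beta
    group_pen = sum(np.linalg.norm(beta[idx]) for idx in group_index)
    return float(
        0.5 * resid @ resid + lam1 * group_pen + lam2 * np.abs(beta).sum()
    )


class SparseGroupLasso(BaseEstimator, RegressorMixin):
    """Sparse-group-lasso linear model.

    Parameters
    ----------
    groups : array-like of length n_features
        Group label per feature; every feature belongs to exactly one
        group. Labels can be any hashable values.
    lam1 : float
        Inter-group (group L2) penalty.
    lam2 : float
        Intra-group (elementwise L1) penalty.
    max_iter : int
        Maximum outer sweeps; a warning flag is set if the objective has
        not converged (decrease per sweep below ``tol``) by then.
    """

    def __init__(
        self,
        groups=None,
        lam1: float = 0.0,
        lam2: float = 0.0,
        max_iter: int = 1000,
        tol: float = 1e-8,
        inner_iter: int = 100,
        inner_tol: float = 1e-10,
    ):
        self.groups = groups
        self.lam1 = lam1
        self.lam2 = lam2
        self.max_iter = max_iter
        self.tol = tol
        self.inner_iter = inner_iter
        self.inner_tol = inner_tol

    def _group_index(self, p: int) -> list[np.ndarray]:
        groups = (
            np.zeros(p, int) if self.groups is None else np.asarray(self.groups)
        )
        if len(groups) != p:
            raise ValueError("groups must have one label per feature")
        labels = list(dict.fromkeys(groups.tolist()))  # stable order
        return [np.flatnonzero(groups == g) for g in labels]

    def fit(self, X, y):
        if self.lam1 < 0 or self.lam2 < 0:
            raise ValueError("penalties must be non-negative")
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        n, p = X.shape
        group_index = self._group_index(p)
        beta = np.zeros(p)
        # per-group Lipschitz constants (largest squared singular value)
        lips = []
        for idx in group_index:
            Xg = X[:, idx]
            s = np.linalg.svd(Xg, compute_uv=False)
            lips.append(max(s[0] ** 2, 1e-12))

        objective = sglasso_objective(X, y, beta, group_index, self.lam1, self.lam2)
        trace = [objective]
        resid = y - X @ beta
        converged = False
        for _ in range(self.max_iter):
            for idx, L in zip(group_index, lips):
                Xg = X[:, idx]
                bg = beta[idx]
                r_g = resid + Xg @ bg  # partial residual excluding group
                # screening: the whole group is zero iff the elementwise
                # soft-thresholded gradient fits inside the group penalty ball
                if (
                    np.linalg.norm(soft_threshold(Xg.T @ r_g, self.lam2))
                    <= self.lam1
                ):
                    new_bg = np.zeros_like(bg)
                else:
                    # accelerated (FISTA) proximal gradient on the group
                    step = 1.0 / L
                    new_bg = bg.copy()
                    z = new_bg.copy()
                    t_acc = 1.0
                    for _ in range(self.inner_iter):
                        grad = Xg.T @ (Xg @ z - r_g)
                        u = soft_threshold(
                            z - step * grad, step * self.lam2
                        )
                        u = group_soft_threshold(u, step * self.lam1)
                        t_next = 0.5 * (1 + np.sqrt(1 + 4 * t_acc**2))
                        z = u + ((t_acc - 1) / t_next) * (u - new_bg)
                        t_acc = t_next
                        if np.max(np.abs(u - new_bg)) < self.inner_tol:
                            new_bg = u
                            break
                        new_bg = u
                resid = r_g - Xg @ new_bg
                beta[idx] = new_bg
            new_objective = sglasso_objective(
                X, y, beta, group_index, self.lam1, self.lam2
            )
            trace.append(new_objective)
            if objective - new_objective < self.tol:
                converged = True
                objective = new_objective
                break
            objective = new_objective

        if not converged:
            warnings.warn(
                "sparse group lasso did not converge within max_iter; "
                "returning best iterate",
                RuntimeWarning,
            )
        self.coef_ = beta
        self.objective_trace_ = np.asarray(trace)
        self.objective_ = objective
        self.converged_ = converged
        self.group_index_ = group_index
        self.group_nonzero_ = [
            bool(np.any(beta[idx] != 0)) for idx in group_index
        ]
        return self

    def predict(self, X):
        return np.asarray(X, float) @ self.coef_


def sglasso_fit(
    X,
    y_coded,
    groups=None,
    lam1: float = 0.0,
    lam2: float = 0.0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> SparseGroupLasso:
    """Fit the sparse group lasso; labels should be coded +/-1."""
    model = SparseGroupLasso(
        groups=groups, lam1=lam1, lam2=lam2, max_iter=max_iter, tol=tol
    )
    return model.fit(X, y_coded)
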