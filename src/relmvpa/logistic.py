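"""One-vs-rest binary logistic regression fitted by iteratively reweighted
least squares (ridge-stabilised Newton–Raphson).

Each category gets its own binary logistic model (that category vs. the rest);
the predicted label is the argmax of the per-class linear scores, with ties
broken toward the lowest category index.  A small L2 penalty (default 1e-4,
never on the intercept) keeps the Newton step well-posed on separable data;
the iteration count is capped (default 5000) and non-convergence yields a
warning, not an error.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import linalg

__all__ = ["OneVsRestLogistic", "IRLSConvergenceWarning"]


class IRLSConvergenceWarning(UserWarning):
    pass


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -35.0, 35.0)))


def _penalized_deviance(eta: np.ndarray, t: np.ndarray, w: np.ndarray,
                        pen: np.ndarray) -> float:
    # numerically stable sum of softplus(eta) - t*eta
    loss = np.logaddexp(0.0, eta).sum() - float(t @ eta)
    return loss + 0.5 * float(pen @ (w ** 2))


def irls_binary(
    X: np.ndarray,
    t: np.ndarray,
    ridge: float = 1e-4,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> np.ndarray:
    """Fit one penalised binary logistic model; X must include the intercept
    column last.  Minimises sum log-loss + (ridge/2)*||w[:-1]||^2.

    Newton steps are safeguarded by step halving on the penalised deviance,
    which keeps quasi-separable problems (saturated sigmoids, near-singular
    working weights) from oscillating.
    """
    n, p = X.shape
    w = np.zeros(p)
    pen = np.full(p, ridge)
    pen[-1] = 0.0
    obj = _penalized_deviance(X @ w, t, w, pen)
    grad_tol = 1e-9 * max(1.0, n)
    for _ in range(max_iter):
        mu = _sigmoid(X @ w)
        g = X.T @ (mu - t) + pen * w
        if np.max(np.abs(g)) < grad_tol:
            break
        W = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (X * W[:, None]).T @ X
        H[np.diag_indices_from(H)] += pen + 1e-12
        try:
            step = linalg.solve(H, g, assume_a="pos")
        except linalg.LinAlgError:  # pragma: no cover - degenerate Hessian
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        alpha = 1.0
        for _half in range(30):
            w_new = w - alpha * step
            obj_new = _penalized_deviance(X @ w_new, t, w_new, pen)
            if obj_new <= obj:
                break
            alpha *= 0.5
        moved = alpha * np.max(np.abs(step))
        w = w_new
        converged = moved < tol or (obj - obj_new) < 1e-12 * (1.0 + abs(obj))
        obj = obj_new
        if converged:
            break
    else:
        warnings.warn(
            f"IRLS did not converge within {max_iter} iterations; "
            "returning the current iterate",
            IRLSConvergenceWarning,
        )
    return w


def irls_multi(
    X: np.ndarray,
    T: np.ndarray,
    ridge: float = 1e-4,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> np.ndarray:
    """Fit K independent penalised binary logistic models in one batched IRLS
    loop (same objective, updates and safeguards as :func:`irls_binary`, with
    the per-class Newton systems solved in a batch).  ``T`` is (n, K) binary
    targets; returns (K, p) weights.  X must include the intercept column
    last."""
    n, p = X.shape
    K = T.shape[1]
    W = np.zeros((K, p))
    pen = np.full(p, ridge)
    pen[-1] = 0.0

    def objectives(Wmat, cols):
        eta = X @ Wmat.T  # (n, k)
        loss = np.logaddexp(0.0, eta).sum(axis=0) - np.einsum(
            "nk,nk->k", T[:, cols], eta
        )
        return loss + 0.5 * (Wmat ** 2) @ pen

    obj = objectives(W, np.arange(K))
    grad_tol = 1e-9 * max(1.0, n)
    active = np.ones(K, dtype=bool)
    for _ in range(max_iter):
        idx = np.where(active)[0]
        if idx.size == 0:
            break
        eta = X @ W[idx].T
        mu = _sigmoid(eta)
        G = X.T @ (mu - T[:, idx]) + (pen[:, None] * W[idx].T)  # (p, k)
        gmax = np.abs(G).max(axis=0)
        done = gmax < grad_tol
        if done.any():
            active[idx[done]] = False
            idx = idx[~done]
            if idx.size == 0:
                continue
            G = G[:, ~done]
            mu = mu[:, ~done]
        Wk = np.clip(mu * (1.0 - mu), 1e-10, None)  # (n, k)
        XW = X[None, :, :] * Wk.T[:, :, None]  # (k, n, p)
        H = XW.transpose(0, 2, 1) @ X[None]
        H[:, np.arange(p), np.arange(p)] += pen + 1e-12
        try:
            steps = np.linalg.solve(H, G.T[:, :, None])[:, :, 0]  # (k, p)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate Hessian
            steps = np.stack(
                [np.linalg.lstsq(H[i], G.T[i], rcond=None)[0]
                 for i in range(idx.size)]
            )
        alpha = np.ones(idx.size)
        new_w = W[idx] - steps
        new_obj = objectives(new_w, idx)
        for _half in range(30):
            worse = new_obj > obj[idx]
            if not worse.any():
                break
            alpha[worse] *= 0.5
            new_w[worse] = W[idx[worse]] - alpha[worse, None] * steps[worse]
            new_obj[worse] = objectives(new_w[worse], idx[worse])
        moved = alpha * np.abs(steps).max(axis=1)
        decrease = obj[idx] - new_obj
        W[idx] = new_w
        converged = (moved < tol) | (decrease < 1e-12 * (1.0 + np.abs(obj[idx])))
        obj[idx] = new_obj
        active[idx[converged]] = False
    if active.any():
        warnings.warn(
            f"IRLS did not converge within {max_iter} iterations for "
            f"{int(active.sum())} class(es); returning the current iterate",
            IRLSConvergenceWarning,
        )
    return W


class OneVsRestLogistic:
    """Multiclass classifier built from per-class IRLS logistic regressions."""

    def __init__(
        self,
        ridge: float = 1e-4,
        max_iter: int = 5000,
        tol: float = 1e-8,
        fit_intercept: bool = True,
    ):
        self.ridge = ridge
        self.max_iter = max_iter
        self.tol = tol
        self.fit_intercept = fit_intercept
        self.classes_: Optional[np.ndarray] = None
        self.coef_: Optional[np.ndarray] = None
        self.intercept_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneVsRestLogistic":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite features")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 distinct labels to fit a classifier")
        if self.fit_intercept:
            Xd = np.hstack([X, np.ones((X.shape[0], 1))])
        else:
            Xd = np.hstack([X, np.zeros((X.shape[0], 1))])
        T = (y[:, None] == self.classes_[None, :]).astype(float)
        W = irls_multi(Xd, T, self.ridge, self.max_iter, self.tol)
        self.coef_ = W[:, :-1]
        self.intercept_ = W[:, -1]
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise ValueError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_.T + self.intercept_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-class one-vs-rest sigmoid probabilities (not normalised)."""
        return _sigmoid(self.decision_function(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        # np.argmax takes the first maximum -> ties break to the lowest class
        return self.classes_[np.argmax(scores, axis=1)]
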