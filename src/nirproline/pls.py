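"""Univariate-response partial least squares (NIPALS) with cross-validation.

This is the regression engine behind the full-spectrum model, interval PLS
and simulated-annealing feature selection.  For a single response the
NIPALS sequence is deterministic (no random initialization) and equivalent
to SIMPLS; predictors and response are mean-centered, never
variance-scaled, the convention for absorbance spectra.

Model complexity is the number of latent variables (LVs).  The LV count is
chosen by K-fold cross-validation: RMSECV per LV over pooled out-of-fold
residuals, global minimum, ties resolved toward the smaller LV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PlsModel", "CvCurve", "fit_pls", "cross_validate"]


@dataclass
class PlsModel:
    """A fitted PLS regression: y_hat = y_mean + (x - x_mean) . coef."""

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, k) NIPALS weight vectors
    loadings: np.ndarray  # (p, k) X loadings
    y_loadings: np.ndarray  # (k,) regression of y on each score
    coef: np.ndarray  # (p,) on the original (centered) variables
    variable_subset: np.ndarray  # indices into the full grid, bookkeeping
    scores: np.ndarray | None = None  # (n, k) training scores, mutually orthogonal

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.coef.size:
            raise ValueError(
                f"X has {X.shape[1]} variables, model expects {self.coef.size}"
            )
        return self.y_mean + (X - self.x_mean) @ self.coef

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_lv": int(self.n_lv),
            "y_mean": float(self.y_mean),
            "x_mean": self.x_mean.tolist(),
            "coef": self.coef.tolist(),
            "variable_subset": self.variable_subset.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


@dataclass
class CvCurve:
    """RMSECV as a function of the LV count."""

    rmsecv: np.ndarray  # index k-1 holds RMSECV at k LVs
    chosen_n_lv: int
    fold_description: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.chosen_n_lv <= self.rmsecv.size:
            raise ValueError("chosen_n_lv outside the evaluated range")


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """Sequential NIPALS extraction on centered data.

    Returns (W, P, q) possibly truncated below ``n_lv`` if the residual
    covariance vanishes first (exactly collinear or exhausted data).
    """
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    X = Xc.copy()
    y = yc.copy()
    scale = np.linalg.norm(Xc) * np.linalg.norm(yc)
    k = 0
    for k in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= max(scale, 1.0) * 1e-14:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= 0.0:
            break
        P[:, k] = X.T @ t / tt
        q[k] = float(y @ t) / tt
        W[:, k] = w
        T[:, k] = t
        X = X - np.outer(t, P[:, k])
        y = y - q[k] * t
        k += 1
    return W[:, :k], P[:, :k], q[:k], T[:, :k]


def _coef_from_factors(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    """Regression coefficients using the first k components."""
    if k == 0:
        return np.zeros(W.shape[0])
    R = P[:, :k].T @ W[:, :k]  # unit upper triangular
    return W[:, :k] @ np.linalg.solve(R, q[:k])


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    variable_subset: np.ndarray | None = None,
) -> PlsModel:
    """Fit a univariate PLS regression with ``n_lv`` latent variables.

    ``variable_subset`` records which grid columns ``X`` holds; it does not
    re-index ``X``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on the number of samples")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("X and y must be finite")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must satisfy 1 <= n_lv <= min(n-1, p) = {min(n - 1, p)}")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; nothing to regress")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T = _nipals(X - x_mean, y - y_mean, n_lv)
    k = W.shape[1]
    coef = _coef_from_factors(W, P, q, k)
    if variable_subset is None:
        variable_subset = np.arange(p)
    return PlsModel(
        n_lv=k,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        y_loadings=q,
        coef=coef,
        variable_subset=np.asarray(variable_subset, dtype=int),
        scores=T,
    )


def _fold_indices(n: int, n_folds: int, seed: int | None) -> list[np.ndarray]:
    order = np.arange(n) if seed is None else np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(order, n_folds)]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 10,
    n_folds: int = 10,
    seed: int | None = None,
) -> CvCurve:
    """K-fold RMSECV curve over 1..max_lv latent variables.

    ``seed=None`` assigns contiguous blocks; otherwise folds are a seeded
    random partition.  The chosen LV count is the curve's global minimum,
    ties resolved toward fewer LVs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n // n_folds < 2:
        raise ValueError("folds would have fewer than 2 samples")
    folds = _fold_indices(n, n_folds, seed)
    min_train = n - max(f.size for f in folds)
    if not 1 <= max_lv <= min(min_train - 1, p):
        raise ValueError("max_lv infeasible in at least one training fold")

    press = np.zeros(max_lv)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        Xtr, ytr = X[mask], y[mask]
        x_mean = Xtr.mean(axis=0)
        y_mean = ytr.mean()
        W, P, q, _ = _nipals(Xtr - x_mean, ytr - y_mean, max_lv)
        Xte_c = X[fold] - x_mean
        for k in range(1, max_lv + 1):
            coef = _coef_from_factors(W, P, q, min(k, W.shape[1]))
            resid = y[fold] - (y_mean + Xte_c @ coef)
            press[k - 1] += float(resid @ resid)
    rmsecv = np.sqrt(press / n)
    chosen = int(np.argmin(rmsecv)) + 1  # argmin takes the first (smaller LV) on ties
    desc = "contiguous blocks" if seed is None else f"random folds (seed={seed})"
    return CvCurve(rmsecv=rmsecv, chosen_n_lv=chosen, fold_description=f"{n_folds}-fold, {desc}")
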