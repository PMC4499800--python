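"""NIPALS PLS1 regression, cross-validation, and VIP variable selection.

The calibration model is partial least squares with a single response
(PLS1), fitted by the classical NIPALS deflation algorithm on mean-centered
data (no per-channel variance scaling: absorbance channels share units).
For each latent factor ``a`` on the current residual matrices ``X_a``,
``y_a``::

    w_a = X_a' y_a / ||X_a' y_a||        (unit-norm weight)
    t_a = X_a w_a                        (score)
    p_a = X_a' t_a / (t_a' t_a)          (x-loading)
    q_a = y_a' t_a / (t_a' t_a)          (y-loading)
    X_{a+1} = X_a - t_a p_a',   y_{a+1} = y_a - q_a t_a

The regression vector in centered coordinates is
``b = W (P' W)^{-1} q``, so ``yhat = (x - x_mean) b + y_mean``.

Variable importance in projection (VIP) scores each channel by its
contribution to the response variance explained across factors (Wold's
formulation)::

    VIP_j = sqrt( p * sum_a SS_a w_{aj}^2 / sum_a SS_a ),
    SS_a  = q_a^2 (t_a' t_a)

with ``w_a`` unit-norm, so that ``sum_j VIP_j^2 = p``; channels with
VIP > 1 are conventionally retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .errors import (
    DegenerateModelError,
    ParameterError,
    RankError,
    ShapeError,
)

# relative threshold below which a weight or score norm counts as zero
_RANK_RTOL = 1e-12


@dataclass
class PLSModel:
    """Fitted NIPALS PLS1 state, sufficient for prediction and VIP.

    ``variable_subset`` records which columns of the original channel grid
    the model was fitted on (identity for full-variable models).
    """

    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray  # (p, A), unit-norm columns
    P: np.ndarray  # (p, A)
    q: np.ndarray  # (A,)
    T: np.ndarray  # (n, A), pairwise-orthogonal columns
    b: np.ndarray  # (p,), centered-form regression vector
    variable_subset: np.ndarray  # indices into the original channels

    def to_json(self, pretreatment_label: str = "raw") -> str:
        """Serialize what is needed to re-predict without refitting."""
        return json.dumps(
            {
                "n_factors": self.n_factors,
                "x_mean": self.x_mean.tolist(),
                "y_mean": self.y_mean,
                "b": self.b.tolist(),
                "variable_subset": self.variable_subset.tolist(),
                "pretreatment": pretreatment_label,
            },
            indent=1,
        )


def _nipals(X0: np.ndarray, y0: np.ndarray, A: int):
    """Run NIPALS PLS1 on centered data; returns (W, P, q, T)."""
    n, p = X0.shape
    X, y = X0.copy(), y0.copy()
    W = np.empty((p, A))
    P = np.empty((p, A))
    q = np.empty(A)
    T = np.empty((n, A))
    y_scale = np.linalg.norm(y0) or 1.0
    for a in range(A):
        w = X.T @ y
        wn = np.linalg.norm(w)
        if wn <= _RANK_RTOL * y_scale or np.linalg.norm(y) <= _RANK_RTOL * y_scale:
            raise RankError(
                f"response variance exhausted at factor {a}; "
                f"at most {a} factors are achievable",
                max_factors=a,
            )
        w /= wn
        t = X @ w
        tt = t @ t
        if tt <= (_RANK_RTOL * max(1.0, np.abs(X0).max())) ** 2:
            raise RankError(
                f"zero score norm at factor {a}; at most {a} factors are achievable",
                max_factors=a,
            )
        pa = X.T @ t / tt
        qa = y @ t / tt
        X = X - np.outer(t, pa)
        y = y - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
    return W, P, q, T


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls(
    Xc: np.ndarray,
    yc: np.ndarray,
    A: int,
    variable_subset: np.ndarray | None = None,
) -> PLSModel:
    """Fit a PLS1 model with ``A`` latent factors on calibration data.

    ``Xc`` and ``yc`` are used as given (already pretreated); only mean
    centering is applied internally.  Raises :class:`ParameterError` if
    ``A`` exceeds ``min(n-1, p)`` and :class:`RankError` (naming the
    achievable maximum) if the response is exhausted earlier.
    """
    Xc = np.atleast_2d(np.asarray(Xc, dtype=float))
    yc = np.asarray(yc, dtype=float).ravel()
    n, p = Xc.shape
    if len(yc) != n:
        raise ShapeError(f"y has length {len(yc)} but X has {n} rows")
    if not 1 <= A <= min(n - 1, p):
        raise ParameterError(f"n_factors must be in [1, {min(n - 1, p)}], got {A}")
    x_mean = Xc.mean(axis=0)
    y_mean = float(yc.mean())
    W, P, q, T = _nipals(Xc - x_mean, yc - y_mean, A)
    subset = (
        np.arange(p) if variable_subset is None else np.asarray(variable_subset, dtype=int)
    )
    return PLSModel(
        n_factors=A,
        x_mean=x_mean,
        y_mean=y_mean,
        W=W,
        P=P,
        q=q,
        T=T,
        b=_regression_vector(W, P, q),
        variable_subset=subset,
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict responses: ``yhat = (X - x_mean) b + y_mean``.

    ``X`` must already be restricted to the model's variable subset.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.b):
        raise ShapeError(
            f"X has {X.shape[1]} channels but model expects {len(model.b)}"
        )
    return (X - model.x_mean) @ model.b + model.y_mean


def max_cv_factors(n: int, p: int, k: int) -> int:
    """Largest latent-factor count feasible in every k-fold CV training set."""
    return min(n - ceil(n / k) - 1, p)


def cross_validate(
    Xc: np.ndarray, yc: np.ndarray, A_max: int, k: int = 10
) -> np.ndarray:
    """k-fold cross-validated RMSE for every factor count 1..A_max.

    Folds are venetian-blind (sample ``i`` goes to fold ``i mod k``, in
    calibration order), which makes the procedure deterministic.  Held-out
    predictions are pooled over folds before the RMSE is taken.
    """
    Xc = np.atleast_2d(np.asarray(Xc, dtype=float))
    yc = np.asarray(yc, dtype=float).ravel()
    n, p = Xc.shape
    if not 2 <= k <= n:
        raise ParameterError(f"fold count k must be in [2, {n}], got {k}")
    feasible = max_cv_factors(n, p, k)
    if not 1 <= A_max <= feasible:
        raise ParameterError(
            f"A_max must be in [1, {feasible}] for n={n}, k={k}, got {A_max}"
        )
    folds = np.arange(n) % k
    pred = np.empty((A_max, n))
    for fold in range(k):
        test = folds == fold
        Xt, yt = Xc[~test], yc[~test]
        x_mean = Xt.mean(axis=0)
        y_mean = yt.mean()
        W, P, q, _ = _nipals(Xt - x_mean, yt - y_mean, A_max)
        Xh = Xc[test] - x_mean
        for a in range(1, A_max + 1):
            b = _regression_vector(W[:, :a], P[:, :a], q[:a])
            pred[a - 1, test] = Xh @ b + y_mean
    resid = pred - yc
    return np.sqrt(np.mean(resid**2, axis=1))


@dataclass
class VIPResult:
    """VIP scores plus the threshold decision that produced ``selected``."""

    scores: np.ndarray
    threshold: float
    selected: np.ndarray
    model_factors: int


def vip_scores(model: PLSModel) -> np.ndarray:
    """Wold VIP score per channel; ``sum(scores**2) == p`` by construction."""
    ss = model.q**2 * np.einsum("na,na->a", model.T, model.T)
    total = ss.sum()
    if total <= 0:
        raise DegenerateModelError("model explains no response variance; VIP undefined")
    p = model.W.shape[0]
    return np.sqrt(p * (model.W**2 @ ss) / total)


def select_variables(
    scores: np.ndarray, threshold: float = 1.0, A: int = 1
) -> np.ndarray:
    """Channels with VIP above the threshold, in ascending index order.

    Fallback: if fewer than ``max(2, A)`` channels survive, the
    ``max(2, A)`` highest-VIP channels are returned instead (ties toward
    the lower index), so a refit at up to ``A`` factors stays feasible.
    """
    scores = np.asarray(scores, dtype=float)
    selected = np.flatnonzero(scores > threshold)
    floor = max(2, A)
    if len(selected) < floor:
        order = np.argsort(-scores, kind="stable")[:floor]
        selected = np.sort(order)
    return selected


def vip_select(model: PLSModel, threshold: float = 1.0) -> VIPResult:
    """Score a fitted model's channels and apply the VIP threshold rule."""
    scores = vip_scores(model)
    selected = select_variables(scores, threshold, model.n_factors)
    return VIPResult(
        scores=scores,
        threshold=threshold,
        selected=selected,
        model_factors=model.n_factors,
    )
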