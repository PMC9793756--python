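"""PLS1 regression, Monte Carlo cross-validation and error metrics.

The calibration model is a mean-centered NIPALS PLS1: no variance scaling
is applied because absorbance channels share a common unit.  Model
selection and wrapper fitness both use Monte Carlo cross-validation
(MCCV): repeated random calibration/validation splits of the training set,
with the root mean squared error pooled over every held-out residual so
that unequal holdout sizes cannot bias the estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import SpectrumSet, TargetVector

__all__ = [
    "CVConfig",
    "PLSModel",
    "fit_pls",
    "predict",
    "rmse",
    "r_squared",
    "draw_mccv_splits",
    "mccv_rmsecv",
    "mccv_rmsecv_path",
    "select_n_lv",
]

_EPS = 1e-12


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SpectrumSet):
        return X.absorbance
    return np.atleast_2d(np.asarray(X, dtype=float))


def _as_vector(y) -> np.ndarray:
    if isinstance(y, TargetVector):
        return y.values
    return np.asarray(y, dtype=float).ravel()


@dataclass(frozen=True)
class CVConfig:
    """Monte Carlo cross-validation settings.

    ``n_splits`` random splits are drawn; in each, a fraction
    ``calibration_fraction`` of the training samples fits the model and the
    remainder is predicted.  Splits are a pure function of ``seed`` and the
    sample count, so any quantity computed from them is deterministic.
    """

    n_splits: int = 50
    calibration_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.calibration_fraction < 1.0):
            raise ValueError("calibration_fraction must be in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


@dataclass
class PLSModel:
    """A fitted centered PLS1 model.

    ``coefficients`` act on the original (masked) variable scale:
    ``yhat = (X - x_mean) @ coefficients + y_mean``.  ``n_lv_eff`` can fall
    below the requested ``n_lv`` when deflation exhausts the covariance
    (for example on rank-deficient X); the remaining components are zero.
    """

    n_lv: int
    n_lv_eff: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # (n_vars, n_lv_eff)
    x_loadings: np.ndarray   # (n_vars, n_lv_eff)
    y_loadings: np.ndarray   # (n_lv_eff,)
    coefficients: np.ndarray  # (n_vars,)
    mask: np.ndarray | None = None

    @property
    def n_vars(self) -> int:
        return self.coefficients.size


def _nipals_path(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS decomposition of centered data, returning W, P, q truncated
    to the effectively extractable number of components."""
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    X = Xc.copy()
    y = yc.copy()
    k_eff = 0
    for k in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= _EPS:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= _EPS:
            break
        P[:, k] = X.T @ t / tt
        q[k] = float(y @ t) / tt
        W[:, k] = w
        X -= np.outer(t, P[:, k])
        y = y - q[k] * t
        k_eff = k + 1
    return W[:, :k_eff], P[:, :k_eff], q[:k_eff]


def _coef_from_decomposition(W, P, q, k: int) -> np.ndarray:
    """Regression vector using the first ``k`` latent variables."""
    if k == 0:
        return np.zeros(W.shape[0])
    Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
    # B = W (P'W)^{-1} q ; P'W is unit upper triangular for NIPALS.
    return Wk @ np.linalg.solve(Pk.T @ Wk, qk)


def _coef_path(Xc, yc, max_lv: int) -> np.ndarray:
    """Coefficient vectors for every component count 1..max_lv.

    Returns an array of shape (max_lv, n_vars); rows beyond the effective
    rank repeat the last extractable model.
    """
    W, P, q = _nipals_path(Xc, yc, max_lv)
    k_eff = q.size
    p = Xc.shape[1]
    out = np.zeros((max_lv, p))
    for k in range(1, max_lv + 1):
        out[k - 1] = _coef_from_decomposition(W, P, q, min(k, k_eff))
    return out


def fit_pls(X, y, n_lv: int, mask: np.ndarray | None = None) -> PLSModel:
    """Fit a centered NIPALS PLS1 model.

    Parameters
    ----------
    X : array (n_samples, n_vars) or SpectrumSet
        Predictor block (already restricted to the selected variables).
    y : array or TargetVector
        Response values.
    n_lv : int
        Number of latent variables, ``1 <= n_lv <= min(n_samples - 1,
        n_vars)``.
    mask : optional binary vector
        Recorded on the model for provenance; not applied to ``X``.
    """
    Xm = _as_matrix(X)
    yv = _as_vector(y)
    n, p = Xm.shape
    if n < 2 or p < 1:
        raise ValueError("X must have at least 2 rows and 1 column")
    if yv.size != n:
        raise ValueError(f"X has {n} rows but y has {yv.size} values")
    if not (1 <= n_lv <= min(n - 1, p)):
        raise ValueError(
            f"n_lv={n_lv} out of range [1, {min(n - 1, p)}] for shape {Xm.shape}"
        )
    if np.ptp(yv) <= _EPS:
        raise ValueError("y has zero variance; nothing to calibrate")

    x_mean = Xm.mean(axis=0)
    y_mean = float(yv.mean())
    W, P, q = _nipals_path(Xm - x_mean, yv - y_mean, n_lv)
    coef = _coef_from_decomposition(W, P, q, q.size)
    return PLSModel(
        n_lv=n_lv,
        n_lv_eff=q.size,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=coef,
        mask=None if mask is None else np.asarray(mask).copy(),
    )


def predict(model: PLSModel, X) -> np.ndarray:
    """Predict responses for new samples with a fitted model."""
    Xm = _as_matrix(X)
    if Xm.shape[1] != model.n_vars:
        raise ValueError(
            f"X has {Xm.shape[1]} columns but model was fit on {model.n_vars}"
        )
    return (Xm - model.x_mean) @ model.coefficients + model.y_mean


def rmse(y_true, y_pred) -> float:
    """Root mean squared error between two equal-length vectors."""
    yt = _as_vector(y_true)
    yp = _as_vector(y_pred)
    if yt.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    if yt.size != yp.size:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((yt - yp) ** 2)))


def r_squared(y_true, y_pred) -> float:
    """Determination coefficient 1 - SS_res / SS_tot (SS_tot about the
    mean of ``y_true``)."""
    yt = _as_vector(y_true)
    yp = _as_vector(y_pred)
    if yt.size != yp.size or yt.size < 2:
        raise ValueError("need equal-length vectors with at least 2 entries")
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot <= _EPS:
        raise ValueError("y_true has zero variance; R^2 undefined")
    ss_res = float(np.sum((yt - yp) ** 2))
    return 1.0 - ss_res / ss_tot


def draw_mccv_splits(n_samples: int, cv: CVConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw the seeded Monte Carlo calibration/validation index pairs.

    The calibration size is ``floor(fraction * n)`` clamped so that both
    parts are non-empty.  Indices refer to row positions of the training
    block.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples for MCCV")
    n_cal = int(np.floor(cv.calibration_fraction * n_samples))
    n_cal = min(max(n_cal, 2), n_samples - 1)
    rng = np.random.default_rng(cv.seed)
    splits = []
    for _ in range(cv.n_splits):
        perm = rng.permutation(n_samples)
        splits.append((np.sort(perm[:n_cal]), np.sort(perm[n_cal:])))
    return splits


def mccv_rmsecv_path(X, y, max_lv: int, cv: CVConfig, splits=None) -> np.ndarray:
    """RMSECV for every latent-variable count 1..max_lv in one pass.

    Residuals are pooled over all held-out samples of all splits.  Within a
    split whose calibration part cannot support ``k`` latent variables the
    count is clamped to the feasible maximum (a warning is emitted once).
    """
    Xm = _as_matrix(X)
    yv = _as_vector(y)
    if yv.size != Xm.shape[0]:
        raise ValueError("X rows and y length differ")
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if splits is None:
        splits = draw_mccv_splits(Xm.shape[0], cv)

    sq_sum = np.zeros(max_lv)
    n_held = 0
    clamped = False
    for cal, val in splits:
        Xc = Xm[cal]
        yc = yv[cal]
        feasible = min(max_lv, len(cal) - 1, Xm.shape[1])
        if feasible < max_lv:
            clamped = True
        x_mean = Xc.mean(axis=0)
        y_mean = yc.mean()
        coefs = _coef_path(Xc - x_mean, yc - y_mean, feasible)  # (feasible, p)
        preds = (Xm[val] - x_mean) @ coefs.T + y_mean            # (n_val, feasible)
        resid2 = (preds - yv[val][:, None]) ** 2
        sq = resid2.sum(axis=0)
        # clamp: LV counts beyond the feasible max reuse the last model
        full = np.empty(max_lv)
        full[:feasible] = sq
        full[feasible:] = sq[-1]
        sq_sum += full
        n_held += len(val)
    if clamped:
        warnings.warn(
            "latent-variable count clamped to the feasible maximum in at "
            "least one MCCV split",
            stacklevel=2,
        )
    return np.sqrt(sq_sum / n_held)


def mccv_rmsecv(X, y, n_lv: int, cv: CVConfig, splits=None) -> float:
    """Monte Carlo cross-validated RMSE at a fixed latent-variable count."""
    return float(mccv_rmsecv_path(X, y, n_lv, cv, splits=splits)[n_lv - 1])


def select_n_lv(X, y, max_lv: int, cv: CVConfig) -> int:
    """Pick the latent-variable count in 1..max_lv minimizing RMSECV.

    Ties break toward the smaller count (parsimony).
    """
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    path = mccv_rmsecv_path(X, y, max_lv, cv)
    return int(np.argmin(path)) + 1
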