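"""Orthogonal projections to latent structures (OPLS) for a single response.

The model separates predictive from y-orthogonal variation in X before
fitting one predictive PLS component. For each orthogonal component:

    w      = X'y / ||X'y||          predictive weight direction
    t      = X w                    predictive scores
    p      = X't / (t't)            loadings
    w_orth = (p - (w'p) w) / ||.||  orthogonal weight direction
    t_orth = X w_orth               orthogonal scores
    p_orth = X't_orth / (t_orth't_orth)
    X     <- X - t_orth p_orth'     orthogonal variation removed

followed by one NIPALS PLS component on the filtered X, giving the
regression y_hat = t q with q = y't/(t't). Regression coefficients are
reported on the autoscaled (unit-variance) scale, mapped back through
the orthogonal filter so they apply to the original scaled variables.

Variable importance in projection (VIP) is computed over the predictive
component only; with a single predictive component and unit-norm w,
VIP_j = sqrt(p) * |w_j|, so sum_j VIP_j^2 equals the number of retained
variables. Constant columns are dropped at scaling time and reported
with coefficient and VIP equal to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OPLSConfig",
    "OPLSModel",
    "autoscale",
    "fit_opls1",
    "fit_opls",
    "vip",
    "cross_validate",
    "pls1_fit",
]


@dataclass(frozen=True)
class OPLSConfig:
    n_orthogonal: int = 1
    scaling: str = "uv"
    cv_folds: int | None = None

    def __post_init__(self) -> None:
        if self.n_orthogonal < 0:
            raise ValueError("n_orthogonal must be >= 0")
        if self.scaling not in {"uv", "center", "none"}:
            raise ValueError(f"unknown scaling {self.scaling!r}")


@dataclass
class ScalingParams:
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    kept: np.ndarray  # boolean mask over original columns
    scaling: str = "uv"


@dataclass
class OPLSModel:
    """Fitted single-response OPLS model on the scaled scale.

    ``coefficients_scaled`` and ``vip`` are indexed over the *original*
    variable set; dropped (constant) columns carry zeros.
    """

    weights: np.ndarray  # predictive w, unit norm (kept columns)
    scores: np.ndarray  # predictive t
    loadings: np.ndarray  # predictive p
    q: float  # y-side regression on t
    ortho_weights: np.ndarray  # (n_orth, n_kept)
    ortho_scores: np.ndarray  # (n, n_orth)
    ortho_loadings: np.ndarray  # (n_orth, n_kept)
    coefficients_scaled: np.ndarray  # full-length, scaled scale
    vip: np.ndarray  # full-length
    r2y: float
    params: ScalingParams
    q2: float | None = None
    peak_ids: list | None = None
    n_orthogonal: int = 1

    def coefficients_raw(self) -> np.ndarray:
        """Coefficients back-transformed to the original X and y units."""
        p = self.params
        b = np.zeros_like(self.coefficients_scaled)
        nz = p.x_scale != 0
        b[nz] = self.coefficients_scaled[nz] * p.y_scale / p.x_scale[nz]
        return b

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict the response in original units for original-unit X."""
        p = self.params
        Xs = (np.asarray(X, dtype=float)[:, p.kept] - p.x_mean[p.kept]) / np.where(
            p.x_scale[p.kept] == 0, 1.0, p.x_scale[p.kept]
        )
        for wo, po in zip(self.ortho_weights, self.ortho_loadings):
            Xs = Xs - np.outer(Xs @ wo, po)
        ys = (Xs @ self.weights) * self.q
        return ys * p.y_scale + p.y_mean

    def summary_frame(self) -> pd.DataFrame:
        ids = self.peak_ids or [str(j + 1) for j in range(self.vip.size)]
        return pd.DataFrame(
            {"coefficient_scaled": self.coefficients_scaled, "vip": self.vip},
            index=[str(i) for i in ids],
        )


def autoscale(X, y, scaling: str = "uv"):
    """Center (and for "uv" unit-variance scale) X columns and y.

    Constant columns cannot be scaled; they are dropped with a warning
    and recorded in the returned params so downstream reports assign
    them zero coefficient and VIP.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("X must be 2-d with at least 3 rows")
    if X.shape[0] != y.size:
        raise ValueError("X and y row counts differ")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    kept = x_sd > 0
    if not kept.any():
        raise ValueError("all columns are constant")
    if not kept.all():
        logger.warning("dropping %d constant column(s)", int((~kept).sum()))
    if scaling == "uv":
        x_scale = np.where(kept, x_sd, 0.0)
        y_scale = float(y.std(ddof=1))
    elif scaling == "center":
        x_scale = np.where(kept, 1.0, 0.0)
        y_scale = 1.0
    elif scaling == "none":
        Xs = X[:, kept]
        params = ScalingParams(np.zeros_like(x_mean), np.where(kept, 1.0, 0.0), 0.0, 1.0, kept, scaling)
        return Xs, y.copy(), params
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    if scaling == "uv" and y_scale == 0:
        raise ValueError("response has zero variance")
    Xs = (X[:, kept] - x_mean[kept]) / x_sd[kept]
    ys = (y - y.mean()) / (y_scale if y_scale else 1.0)
    params = ScalingParams(x_mean, x_scale, float(y.mean()), y_scale or 1.0, kept, scaling)
    return Xs, ys, params


def pls1_fit(Xs: np.ndarray, ys: np.ndarray):
    """One-component NIPALS PLS1 on pre-scaled data: returns (w, t, p, q)."""
    w = Xs.T @ ys
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("X carries no covariance with y")
    w = w / nw
    t = Xs @ w
    tt = float(t @ t)
    p = Xs.T @ t / tt
    q = float(ys @ t / tt)
    return w, t, p, q


def fit_opls1(
    X_scaled: np.ndarray,
    y_scaled: np.ndarray,
    config: OPLSConfig | None = None,
    params: ScalingParams | None = None,
    peak_ids=None,
) -> OPLSModel:
    """Fit OPLS on already-scaled data (see module docstring for the steps)."""
    cfg = config or OPLSConfig()
    Xf = np.array(X_scaled, dtype=float)
    ys = np.asarray(y_scaled, dtype=float).ravel()
    n, k = Xf.shape
    if n < 3 or k < 1:
        raise ValueError("need at least 3 rows and 1 column")
    if np.allclose(ys, ys[0]):
        raise ValueError("response has zero variance")
    rank = np.linalg.matrix_rank(Xf)
    if cfg.n_orthogonal >= rank:
        raise ValueError(
            f"n_orthogonal={cfg.n_orthogonal} must be below rank(X)={rank}"
        )

    W_o, T_o, P_o = [], [], []
    for _ in range(cfg.n_orthogonal):
        w, t, p, _ = pls1_fit(Xf, ys)
        w_orth = p - (w @ p) * w
        norm = np.linalg.norm(w_orth)
        if norm < 1e-12:
            logger.warning("no orthogonal variation left; stopping early")
            break
        w_orth /= norm
        t_orth = Xf @ w_orth
        p_orth = Xf.T @ t_orth / (t_orth @ t_orth)
        Xf = Xf - np.outer(t_orth, p_orth)
        W_o.append(w_orth)
        T_o.append(t_orth)
        P_o.append(p_orth)

    w, t, p, q = pls1_fit(Xf, ys)

    # coefficients on the scaled scale, through the orthogonal filter:
    # x_filtered = x * prod(I - w_o p_o'), so b = [prod(I - w_o p_o')] w q
    b_kept = w * q
    for wo, po in zip(reversed(W_o), reversed(P_o)):
        b_kept = b_kept - wo * (po @ b_kept)

    yhat = t * q
    ss = float(ys @ ys)
    r2y = 1.0 - float((ys - yhat) @ (ys - yhat)) / ss

    if params is None:
        params = ScalingParams(
            x_mean=np.zeros(k), x_scale=np.ones(k), y_mean=0.0, y_scale=1.0,
            kept=np.ones(k, dtype=bool), scaling="uv",
        )
    coef_full = np.zeros(params.kept.size)
    coef_full[params.kept] = b_kept
    vip_full = np.zeros(params.kept.size)
    vip_full[params.kept] = _vip_from_weights(w)

    return OPLSModel(
        weights=w,
        scores=t,
        loadings=p,
        q=q,
        ortho_weights=np.array(W_o) if W_o else np.zeros((0, w.size)),
        ortho_scores=np.array(T_o).T if T_o else np.zeros((n, 0)),
        ortho_loadings=np.array(P_o) if P_o else np.zeros((0, w.size)),
        coefficients_scaled=coef_full,
        vip=vip_full,
        r2y=float(r2y),
        params=params,
        peak_ids=list(peak_ids) if peak_ids is not None else None,
        n_orthogonal=len(W_o),
    )


def _vip_from_weights(w: np.ndarray) -> np.ndarray:
    # single predictive component: VIP_j = sqrt(p) |w_j| / ||w|| with ||w|| = 1
    return np.sqrt(w.size) * np.abs(w) / np.linalg.norm(w)


def vip(model: OPLSModel) -> np.ndarray:
    """Variable importance in projection over the predictive component."""
    if model.weights is None:
        raise RuntimeError("model is not fitted")
    return model.vip


def fit_opls(
    X,
    y,
    config: OPLSConfig | None = None,
    peak_ids=None,
) -> OPLSModel:
    """Autoscale raw data, fit OPLS, and (optionally) cross-validate.

    ``X`` may be a DataFrame, in which case column labels become peak
    ids. When ``config.cv_folds`` is set, Q2 is attached to the model.
    """
    cfg = config or OPLSConfig()
    if isinstance(X, pd.DataFrame):
        if peak_ids is None:
            peak_ids = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    if isinstance(y, pd.Series):
        y = y.to_numpy(dtype=float)
    Xs, ys, params = autoscale(X, y, cfg.scaling)
    model = fit_opls1(Xs, ys, cfg, params=params, peak_ids=peak_ids)
    if cfg.cv_folds:
        model.q2 = cross_validate(X, y, cfg)
    return model


def cross_validate(X, y, config: OPLSConfig | None = None, seed: int = 0) -> float:
    """k-fold cross-validated Q2 = 1 - PRESS/SS with per-fold rescaling."""
    cfg = config or OPLSConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    folds = cfg.cv_folds or min(7, n)
    if folds < 2 or folds > n:
        raise ValueError("need 2 <= folds <= n rows")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = np.array_split(order, folds)
    press = 0.0
    for test_idx in assignments:
        train_idx = np.setdiff1d(order, test_idx)
        Xs, ys, params = autoscale(X[train_idx], y[train_idx], cfg.scaling)
        n_orth = min(cfg.n_orthogonal, max(0, np.linalg.matrix_rank(Xs) - 1))
        sub_cfg = OPLSConfig(n_orthogonal=n_orth, scaling=cfg.scaling)
        model = fit_opls1(Xs, ys, sub_cfg, params=params)
        pred = model.predict(X[test_idx])
        press += float(((y[test_idx] - pred) ** 2).sum())
    ss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss
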