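"""Two-class partial least squares discriminant analysis (PLS1).

The predictors are autoscaled (column mean 0, SD 1) and the binary class
membership is coded {0, 1} and centred. Components are extracted by
NIPALS-style deflation: for component a,

    w_a = X' y / ||X' y||        (weights)
    t_a = X w_a                  (scores)
    p_a = X' t_a / (t_a' t_a)    (X loadings)
    q_a = y' t_a / (t_a' t_a)    (y loading)
    X <- X - t_a p_a',  y <- y - q_a t_a

The number of latent variables is the minimiser of the cross-validated
PRESS (leave-one-out by default — the natural choice for a two-dozen
accession collection — with k-fold available). Variable importance in
projection (VIP) uses the standard formula; the mean squared VIP is 1 by
construction, and variables with VIP above 0.8 are conventionally the
ones worth discussing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PLSDAModel:
    """Fitted discriminant model with its CV trace and VIP scores."""

    variables: list[str]
    classes: tuple[str, str]          # (code 0, code 1)
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    x_weights: np.ndarray             # (m, A)
    x_loadings: np.ndarray            # (m, A)
    x_scores: np.ndarray              # (n, A), training scores
    y_loadings: np.ndarray            # (A,)
    n_lv: int
    press_by_lv: dict[int, float] = field(default_factory=dict)
    vip: pd.Series | None = None
    training_rate: float | None = None
    dropped_constant: list[str] = field(default_factory=list)
    imputed: dict[str, int] = field(default_factory=dict)

    @property
    def coefficients(self) -> np.ndarray:
        """Regression vector b with ŷ_centred = X_scaled b, using n_lv
        components: b = W (P'W)^{-1} q."""
        a = self.n_lv
        w, p, q = self.x_weights[:, :a], self.x_loadings[:, :a], self.y_loadings[:a]
        return w @ np.linalg.solve(p.T @ w, q)


def _nipals_pls1(x: np.ndarray, y: np.ndarray, n_components: int):
    """Core extraction on already-scaled x and centred y."""
    n, m = x.shape
    xr, yr = x.copy(), y.copy()
    ws, ps, ts, qs = [], [], [], []
    for _ in range(n_components):
        w = xr.T @ yr
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w = w / norm
        # sign convention: first non-zero weight element non-negative
        pivot = np.flatnonzero(np.abs(w) > 1e-12)
        if pivot.size and w[pivot[0]] < 0:
            w = -w
        t = xr @ w
        tt = t @ t
        if tt < 1e-12:
            break
        p = xr.T @ t / tt
        q = (yr @ t) / tt
        xr = xr - np.outer(t, p)
        yr = yr - q * t
        ws.append(w); ps.append(p); ts.append(t); qs.append(q)
    if not ws:
        raise ValueError("no extractable component (X carries no y-covariance)")
    return (np.column_stack(ws), np.column_stack(ps),
            np.column_stack(ts), np.asarray(qs))


def _prepare_xy(x: pd.DataFrame, y: pd.Series):
    """Column screening (constants dropped), mean imputation, class coding."""
    x = x.copy()
    imputed = {}
    for col in x.columns:
        n_na = int(x[col].isna().sum())
        if n_na:
            x[col] = x[col].fillna(x[col].mean())
            imputed[col] = n_na
    stds = x.std(ddof=1)
    dropped = [c for c in x.columns if not np.isfinite(stds[c]) or stds[c] == 0.0]
    if dropped:
        warnings.warn(f"dropping constant columns: {dropped}", stacklevel=3)
        x = x.drop(columns=dropped)
    classes = tuple(sorted(pd.unique(y.astype(str))))
    if len(classes) != 2:
        raise ValueError(f"PLS-DA needs exactly two classes, got {classes}")
    y01 = (y.astype(str) == classes[1]).to_numpy(float)
    return x, y01, classes, dropped, imputed


def _fit_arrays(xs: np.ndarray, yc: np.ndarray, n_components: int):
    return _nipals_pls1(xs, yc, n_components)


def _predict_centred(xs, w, p, q, a):
    b = w[:, :a] @ np.linalg.solve(p[:, :a].T @ w[:, :a], q[:a])
    return xs @ b


def fit_plsda(
    x: pd.DataFrame,
    y: pd.Series,
    max_lv: int = 10,
    cv: str = "loo",
    n_folds: int = 7,
    seed: int | None = None,
) -> PLSDAModel:
    """Fit a two-class PLS-DA with PRESS-selected component count.

    ``cv`` is "loo" (default) or "kfold" (``n_folds`` folds, shuffled with
    ``seed``). Missing predictor values are mean-imputed within column
    (reported on the model); constant columns are dropped with a warning.
    """
    x, y01, classes, dropped, imputed = _prepare_xy(x, y)
    n, m = x.shape
    rank_bound = min(n - 1, m)
    if max_lv > rank_bound:
        warnings.warn(f"max_lv truncated to rank bound {rank_bound}", stacklevel=2)
        max_lv = rank_bound
    if max_lv < 1:
        raise ValueError("not enough samples/variables for one component")

    xm = x.to_numpy(float)
    mu, sd = xm.mean(axis=0), xm.std(axis=0, ddof=1)
    xs = (xm - mu) / sd
    ym = y01.mean()
    yc = y01 - ym

    # cross-validated PRESS per candidate component count
    if cv == "loo":
        folds = [[i] for i in range(n)]
    elif cv == "kfold":
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = [list(order[k::n_folds]) for k in range(n_folds)]
        folds = [f for f in folds if f]
    else:
        raise ValueError(f"unknown cv scheme {cv!r}")

    press = {a: 0.0 for a in range(1, max_lv + 1)}
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        if len(np.unique(y01[train])) < 2:
            raise ValueError("a CV fold removes an entire class; use fewer folds")
        mu_f, sd_f = xm[train].mean(0), xm[train].std(0, ddof=1)
        sd_f[sd_f == 0.0] = 1.0
        xs_f = (xm[train] - mu_f) / sd_f
        ym_f = y01[train].mean()
        try:
            w, p, _, q = _fit_arrays(xs_f, y01[train] - ym_f, max_lv)
        except ValueError:
            continue
        a_max = w.shape[1]
        xs_out = (xm[fold] - mu_f) / sd_f
        for a in range(1, max_lv + 1):
            yhat = _predict_centred(xs_out, w, p, q, min(a, a_max)) + ym_f
            press[a] += float(((y01[fold] - yhat) ** 2).sum())

    n_lv = min(press, key=lambda a: (press[a], a))

    w, p, t, q = _fit_arrays(xs, yc, max_lv)
    n_lv = min(n_lv, w.shape[1])
    model = PLSDAModel(
        variables=list(x.columns), classes=classes, x_mean=mu, x_std=sd,
        y_mean=ym, x_weights=w, x_loadings=p, x_scores=t, y_loadings=q,
        n_lv=n_lv, press_by_lv=press, dropped_constant=dropped, imputed=imputed,
    )
    model.vip = vip_scores(model)
    pred, rates = classify(model, x, y)
    model.training_rate = rates["overall"]
    return model


def vip_scores(model: PLSDAModel) -> pd.Series:
    """Variable importance in projection over the retained components.

    VIP_j = sqrt( m * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ) with
    SSY_a = q_a^2 t_a' t_a, so mean(VIP^2) = 1.
    """
    a = model.n_lv
    w = model.x_weights[:, :a]
    t = model.x_scores[:, :a]
    q = model.y_loadings[:a]
    ssy = q**2 * np.einsum("ij,ij->j", t, t)
    wn = w / np.linalg.norm(w, axis=0, keepdims=True)
    m = len(model.variables)
    vip = np.sqrt(m * (wn**2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=model.variables, name="VIP")


def select_important(vip: pd.Series, threshold: float = 0.8) -> pd.Series:
    """Variables above the VIP threshold, sorted by descending importance."""
    return vip[vip > threshold].sort_values(ascending=False)


def transform(model: PLSDAModel, x: pd.DataFrame) -> np.ndarray:
    """Project new samples onto the retained score dimensions (t1, t2, ...)."""
    xs = (x[model.variables].to_numpy(float) - model.x_mean) / model.x_std
    a = model.n_lv
    w, p = model.x_weights[:, :a], model.x_loadings[:, :a]
    return xs @ (w @ np.linalg.inv(p.T @ w))


def classify(
    model: PLSDAModel, x: pd.DataFrame, y_true: pd.Series | None = None
) -> tuple[pd.Series, dict]:
    """Predict class labels; optionally score correct-classification rates.

    The continuous prediction is thresholded at the midpoint of the class
    codes (0.5 on the {0,1} scale). Rates are reported overall and per
    class; the overall rate is the sample-weighted mean of per-class rates.
    """
    missing = [v for v in model.variables if v not in x.columns]
    if missing:
        raise ValueError(f"missing variables: {missing}")
    xs = (x[model.variables].to_numpy(float) - model.x_mean) / model.x_std
    yhat = xs @ model.coefficients + model.y_mean
    labels = np.where(yhat > 0.5, model.classes[1], model.classes[0])
    pred = pd.Series(labels, index=x.index, name="predicted")
    rates: dict = {}
    if y_true is not None:
        truth = y_true.astype(str).to_numpy()
        rates["overall"] = float((labels == truth).mean())
        for c in model.classes:
            mask = truth == c
            rates[c] = float((labels[mask] == c).mean()) if mask.any() else np.nan
    return pred, rates
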