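"""Single-response orthogonal projections to latent structures (O-PLS).

The model separates variation in X predictive of a continuous response y
from variation orthogonal to it: orthogonal components are extracted
iteratively (w_o proportional to p - (w'p) w, where p is the loading of the
provisional predictive score), X is deflated, and a single predictive PLS
component is fitted on the filtered matrix.  With zero orthogonal
components the model coincides with one-component PLS1.

Model quality is summarised by R2Y (training goodness of fit) and Q2Y
(cross-validated goodness of prediction, leave-one-out by default), and
model validity by permutation of y.  Feature selection combines variable
importance in projection (VIP, predictive-component variant) with the
significance of correlation-scaled loadings after Benjamini-Hochberg
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FerrofluxError, warn
from .assoc import bh_adjust

__all__ = [
    "OplsModel",
    "PermutationResult",
    "fit_opls",
    "predict",
    "q2_loocv",
    "permutation_test",
    "vip",
    "select_features",
    "choose_n_orth",
]


# ---------------------------------------------------------------------------
# array-level internals (no pandas, reused by cross-validation loops)


def _scale_params(X: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    if scaling == "uv":
        s = X.std(axis=0, ddof=1)
    elif scaling == "pareto":
        s = np.sqrt(X.std(axis=0, ddof=1))
    elif scaling == "none":
        s = np.ones(X.shape[1])
    else:
        raise FerrofluxError(f"unknown scaling {scaling!r}")
    # constant-in-fold features contribute 0 after centering
    return mean, np.where(s == 0, 1.0, s)


def _fit_arrays(Xs: np.ndarray, yc: np.ndarray, n_orth: int):
    """Fit on centered/scaled arrays.  Returns (w, c, t, p, W_o, P_o, T_o)."""
    Xd = Xs
    Wo, Po, To = [], [], []
    for _ in range(n_orth):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w = w / nw
        t = Xd @ w
        tt = t @ t
        if tt < 1e-14:
            break
        p = Xd.T @ t / tt
        wo = p - (w @ p) * w
        nwo = np.linalg.norm(wo)
        if nwo < 1e-10 * max(np.linalg.norm(p), 1.0):
            break  # no orthogonal variation left
        wo = wo / nwo
        to = Xd @ wo
        po = Xd.T @ to / (to @ to)
        if Xd is Xs:
            Xd = Xd - np.outer(to, po)
        else:
            Xd -= np.outer(to, po)
        Wo.append(wo)
        Po.append(po)
        To.append(to)
    w = Xd.T @ yc
    nw = np.linalg.norm(w)
    if nw < 1e-14:
        raise FerrofluxError("X carries no covariance with y; cannot fit")
    w = w / nw
    t = Xd @ w
    tt = t @ t
    p = Xd.T @ t / tt
    c = (t @ yc) / tt
    k = len(Wo)
    stack = lambda v: np.column_stack(v) if k else np.zeros((Xs.shape[1], 0))
    return w, c, t, p, stack(Wo), stack(Po), (
        np.column_stack(To) if k else np.zeros((Xs.shape[0], 0))
    )


def _project_scores(Xs: np.ndarray, W_o: np.ndarray, P_o: np.ndarray, w: np.ndarray):
    Xd = Xs
    for i in range(W_o.shape[1]):
        to = Xd @ W_o[:, i]
        if Xd is Xs:
            Xd = Xd - np.outer(to, P_o[:, i])
        else:
            Xd -= np.outer(to, P_o[:, i])
    return Xd @ w


def _fit_predict_fold(Xtr, ytr, Xte, n_orth, scaling):
    mean, scale = _scale_params(Xtr, scaling)
    Xs = (Xtr - mean) / scale
    ym = ytr.mean()
    w, c, _, _, W_o, P_o, _ = _fit_arrays(Xs, ytr - ym, n_orth)
    t_new = _project_scores((Xte - mean) / scale, W_o, P_o, w)
    return c * t_new + ym


def _q2_arrays(X, y, n_orth, scaling, cv) -> float:
    n = X.shape[0]
    if cv == "loo":
        folds = [np.array([i]) for i in range(n)]
    else:
        k = int(cv)
        folds = [np.arange(n)[i::k] for i in range(k)]
    press = 0.0
    mask = np.ones(n, dtype=bool)
    for test in folds:
        mask[:] = True
        mask[test] = False
        yhat = _fit_predict_fold(X[mask], y[mask], X[test], n_orth, scaling)
        press += float(((y[test] - yhat) ** 2).sum())
    return 1.0 - press / float(((y - y.mean()) ** 2).sum())


def _r2_arrays(X, y, n_orth, scaling) -> float:
    mean, scale = _scale_params(X, scaling)
    ym = y.mean()
    _, c, t, _, _, _, _ = _fit_arrays((X - mean) / scale, y - ym, n_orth)
    resid = (y - ym) - c * t
    return 1.0 - float(resid @ resid) / float(((y - ym) ** 2).sum())


# ---------------------------------------------------------------------------
# public interface


@dataclass
class OplsModel:
    """Fitted single-response O-PLS model."""

    feature_ids: pd.Index
    scaling: str
    n_orth: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    w: np.ndarray        # predictive weights, ||w|| = 1
    t: np.ndarray        # predictive scores (training)
    p_load: np.ndarray   # predictive loadings
    c: float             # inner regression coefficient y ~ t
    W_o: np.ndarray      # orthogonal weights (p x n_orth_used)
    P_o: np.ndarray      # orthogonal loadings
    T_o: np.ndarray      # orthogonal scores
    r2y: float
    q2y: float | None = None

    @property
    def n_orth_used(self) -> int:
        return self.W_o.shape[1]


def _as_matrix(X) -> tuple[np.ndarray, pd.Index]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.columns
    X = np.asarray(X, dtype=float)
    return X, pd.Index([f"x{j}" for j in range(X.shape[1])])


def fit_opls(X, y, n_orth: int = 1, scaling: str = "uv") -> OplsModel:
    """Fit an O-PLS model of a continuous response on a feature matrix.

    Parameters
    ----------
    X : (n, p) array or DataFrame
    y : (n,) response vector
    n_orth : number of orthogonal components to extract before the single
        predictive component.
    scaling : "uv" (unit variance), "pareto" or "none"; centering always.
    """
    Xm, fids = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if Xm.shape[0] != y.shape[0]:
        raise FerrofluxError("X and y sample counts differ")
    if Xm.shape[0] < 3:
        raise FerrofluxError("need at least 3 samples")
    if np.isnan(Xm).any() or np.isnan(y).any():
        raise FerrofluxError("NaN values in input")
    if y.std() == 0:
        raise FerrofluxError("constant response")
    sd = Xm.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warn(f"dropping {int((~keep).sum())} zero-variance feature(s)")
        Xm, fids = Xm[:, keep], fids[keep]
    if n_orth < 0:
        raise FerrofluxError("n_orth must be >= 0")
    if n_orth > 0 and n_orth >= np.linalg.matrix_rank(Xm - Xm.mean(axis=0)):
        raise FerrofluxError("n_orth must be smaller than rank(X)")

    mean, scale = _scale_params(Xm, scaling)
    Xs = (Xm - mean) / scale
    ym = float(y.mean())
    w, c, t, p_load, W_o, P_o, T_o = _fit_arrays(Xs, y - ym, n_orth)
    resid = (y - ym) - c * t
    r2y = 1.0 - float(resid @ resid) / float(((y - ym) ** 2).sum())
    return OplsModel(
        feature_ids=fids, scaling=scaling, n_orth=n_orth,
        x_mean=mean, x_scale=scale, y_mean=ym,
        w=w, t=t, p_load=p_load, c=c, W_o=W_o, P_o=P_o, T_o=T_o, r2y=r2y,
    )


def predict(model: OplsModel, Xnew) -> np.ndarray:
    """Predict the response for new samples with the trained filters."""
    if isinstance(Xnew, pd.DataFrame):
        if not Xnew.columns.equals(model.feature_ids):
            if set(Xnew.columns) != set(model.feature_ids):
                raise FerrofluxError("feature mismatch between model and new data")
            Xnew = Xnew.loc[:, model.feature_ids]
        Xm = Xnew.to_numpy(dtype=float)
    else:
        Xm = np.asarray(Xnew, dtype=float)
        if Xm.shape[1] != len(model.feature_ids):
            raise FerrofluxError("feature mismatch between model and new data")
    Xs = (Xm - model.x_mean) / model.x_scale
    t = _project_scores(Xs, model.W_o, model.P_o, model.w)
    return model.c * t + model.y_mean


def q2_loocv(X, y, n_orth: int = 1, scaling: str = "uv", cv="loo") -> float:
    """Cross-validated Q2Y = 1 - PRESS/SS_tot.

    ``cv="loo"`` (default) leaves one sample out per fold; an integer gives
    deterministic interleaved k-fold assignment.  Centering and scaling are
    re-estimated inside each training fold.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if Xm.shape[0] < 4:
        raise FerrofluxError("need at least 4 samples for cross-validation")
    return _q2_arrays(Xm, y, n_orth, scaling, cv)


@dataclass
class PermutationResult:
    """Observed R2Y/Q2Y against their y-permutation null distributions."""

    r2y: float
    q2y: float
    null_r2y: np.ndarray
    null_q2y: np.ndarray
    p_r2y: float
    p_q2y: float
    n_permutations: int


def permutation_test(
    X,
    y,
    n_orth: int = 1,
    n_permutations: int = 1000,
    seed: int | None = None,
    scaling: str = "uv",
    cv="loo",
) -> PermutationResult:
    """Permutation validation of an O-PLS model.

    y is permuted uniformly at random ``n_permutations`` times; R2Y and Q2Y
    are recomputed per permutation and each p-value is the +1-smoothed
    exceedance probability (1 + #{null >= observed}) / (1 + B).
    """
    if n_permutations < 1:
        raise FerrofluxError("n_permutations must be >= 1")
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    r2_obs = _r2_arrays(Xm, y, n_orth, scaling)
    q2_obs = _q2_arrays(Xm, y, n_orth, scaling, cv)
    rng = np.random.default_rng(seed)
    null_r2 = np.empty(n_permutations)
    null_q2 = np.empty(n_permutations)
    for b in range(n_permutations):
        yp = rng.permutation(y)
        null_r2[b] = _r2_arrays(Xm, yp, n_orth, scaling)
        null_q2[b] = _q2_arrays(Xm, yp, n_orth, scaling, cv)
    p_r2 = (1 + int((null_r2 >= r2_obs - 1e-12).sum())) / (1 + n_permutations)
    p_q2 = (1 + int((null_q2 >= q2_obs - 1e-12).sum())) / (1 + n_permutations)
    return PermutationResult(r2_obs, q2_obs, null_r2, null_q2, p_r2, p_q2, n_permutations)


def vip(model: OplsModel, variant: str = "pred") -> np.ndarray:
    """Variable importance in projection.

    ``variant="pred"`` (default) scores features on the predictive component
    only; with one predictive component this reduces to sqrt(p) * |w_j| and
    satisfies mean(VIP^2) = 1 exactly.  ``variant="total"`` additionally
    weighs orthogonal components by the X-variance they explain.
    """
    p = len(model.w)
    if variant == "pred":
        return np.sqrt(p) * np.abs(model.w)
    if variant != "total":
        raise FerrofluxError(f"unknown VIP variant {variant!r}")
    comps = [(model.w, model.t, model.p_load)]
    for i in range(model.n_orth_used):
        comps.append((model.W_o[:, i], model.T_o[:, i], model.P_o[:, i]))
    ssx = np.array([float(t @ t) * float(pl @ pl) for _, t, pl in comps])
    W2 = np.column_stack([wv**2 for wv, _, _ in comps])
    v2 = p * (W2 @ ssx) / ssx.sum()
    return np.sqrt(v2)


def select_features(
    X,
    y,
    model: OplsModel,
    fdr_primary: float = 0.05,
    fdr_relaxed: float = 0.10,
    vip_cut: float = 1.0,
) -> pd.DataFrame:
    """Loading-significance + VIP feature selection.

    Each feature's correlation with the predictive score t is tested
    two-sided (t distribution, df = n - 2), BH-adjusted across features.
    A feature is selected iff pFDR < ``fdr_primary`` or
    (pFDR < ``fdr_relaxed`` and VIP > ``vip_cut``).
    """
    Xm, fids = _as_matrix(X)
    if isinstance(X, pd.DataFrame):
        Xm = X.loc[:, model.feature_ids].to_numpy(dtype=float)
        fids = model.feature_ids
    n = Xm.shape[0]
    Xs = (Xm - model.x_mean) / model.x_scale
    t = model.t
    tc = t - t.mean()
    xc = Xs - Xs.mean(axis=0)
    denom = np.linalg.norm(xc, axis=0) * np.linalg.norm(tc)
    denom = np.where(denom == 0, 1.0, denom)
    r = np.clip(xc.T @ tc / denom, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    pfdr = bh_adjust(pvals)
    v = vip(model)
    selected = (pfdr < fdr_primary) | ((pfdr < fdr_relaxed) & (v > vip_cut))
    return pd.DataFrame(
        {
            "feature_id": fids,
            "loading_corr": r,
            "p": pvals,
            "pFDR": pfdr,
            "vip": v,
            "selected": selected,
        }
    ).set_index("feature_id")


def choose_n_orth(
    X, y, scaling: str = "uv", max_orth: int = 5, min_gain: float = 0.01, cv="loo"
) -> int:
    """Add orthogonal components while cross-validated Q2Y improves.

    Starts at 0 and accepts each additional component only if Q2Y rises by
    more than ``min_gain`` — a common chemometrics stopping heuristic.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    best_q2 = _q2_arrays(Xm, y, 0, scaling, cv)
    best = 0
    for k in range(1, max_orth + 1):
        try:
            q2 = _q2_arrays(Xm, y, k, scaling, cv)
        except FerrofluxError:
            break
        if q2 > best_q2 + min_gain:
            best_q2, best = q2, k
        else:
            break
    return best
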