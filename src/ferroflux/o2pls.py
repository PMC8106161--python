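"""Two-block O2-PLS integration.

O2-PLS decomposes two blocks measured on the same samples into a joint part
(shared covariance), block-specific orthogonal parts and residuals:

    X = T W' + T_Yosc P_Yosc' + E_X
    Y = U C' + U_Xosc P_Xosc' + E_Y,   U ~ T B (inner relation)

Joint weights come from the singular vectors of Y'X; orthogonal components
are estimated per block as the dominant structured variation of the residual
after the joint part and removed before the joint weights are re-estimated.
Component counts are chosen by symmetric k-fold cross-validation (both
prediction directions).  Joint loadings rescaled as feature-component
correlations (pcorr for X, qcorr for Y) support correlation-circle reading:
strongly positively associated features sit at ~0 degrees of each other,
negatively associated at ~180, uncorrelated at ~90.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FerrofluxError, warn

__all__ = ["O2plsModel", "fit_o2pls", "predict_y_from_x", "predict_x_from_y",
           "crossval_components", "correlation_loadings"]


def _center_scale(M: np.ndarray, scaling: str):
    mean = M.mean(axis=0)
    if scaling == "uv":
        s = M.std(axis=0, ddof=1)
    elif scaling == "pareto":
        s = np.sqrt(M.std(axis=0, ddof=1))
    elif scaling == "none":
        s = np.ones(M.shape[1])
    else:
        raise FerrofluxError(f"unknown scaling {scaling!r}")
    s = np.where(s == 0, 1.0, s)
    return (M - mean) / s, mean, s


def _orth_filter(M: np.ndarray, W_joint: np.ndarray, n_orth: int):
    """Extract ``n_orth`` block-specific orthogonal components from M.

    At each step the joint scores are recomputed (T = M W), the residual of
    the joint reconstruction E = M - T W' is formed, and the dominant left
    singular vector of E'T gives the orthogonal weight: the direction of
    structured M-variation present in the joint scores but not in the joint
    weight subspace.  M is deflated by the corresponding score/loading pair.
    """
    Wo, To, Po = [], [], []
    Md = M
    for _ in range(n_orth):
        T = Md @ W_joint
        E = Md - T @ W_joint.T
        u, s, _ = np.linalg.svd(E.T @ T, full_matrices=False)
        if s.size == 0 or s[0] < 1e-10:
            break
        wo = u[:, 0]
        to = Md @ wo
        tt = to @ to
        if tt < 1e-12:
            break
        po = Md.T @ to / tt
        Md = Md - np.outer(to, po)
        Wo.append(wo)
        To.append(to)
        Po.append(po)
    k = len(Wo)
    p = M.shape[1]
    n = M.shape[0]
    pack = lambda v, d: np.column_stack(v) if k else np.zeros((d, 0))
    return Md, pack(Wo, p), pack(To, n), pack(Po, p)


@dataclass
class O2plsModel:
    n_joint: int
    n_xorth: int
    n_yorth: int
    x_features: pd.Index
    y_features: pd.Index
    scaling: str
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    W: np.ndarray   # X joint loadings (p x a), orthonormal columns
    C: np.ndarray   # Y joint loadings (q x a)
    T: np.ndarray   # X joint scores
    U: np.ndarray   # Y joint scores
    W_xo: np.ndarray
    P_xo: np.ndarray
    W_yo: np.ndarray
    P_yo: np.ndarray
    B_t: np.ndarray  # inner relation U ~ T B_t
    B_u: np.ndarray  # inner relation T ~ U B_u
    r2: dict         # per-block {"joint", "orth", "residual"} fractions


def _as_matrix(M, label: str):
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float), M.columns
    M = np.asarray(M, dtype=float)
    return M, pd.Index([f"{label}{j}" for j in range(M.shape[1])])


def fit_o2pls(
    X, Y, n_joint: int = 1, n_xorth: int = 0, n_yorth: int = 0, scaling: str = "uv"
) -> O2plsModel:
    """Fit an O2-PLS model on two sample-matched blocks.

    Joint weight pairs (W, C) are the leading singular vectors of Y'X;
    orthogonal components are removed per block, after which the joint part
    is re-estimated and the inner relations U ~ T B and T ~ U B' fitted by
    least squares.
    """
    Xm, xf = _as_matrix(X, "x")
    Ym, yf = _as_matrix(Y, "y")
    if Xm.shape[0] != Ym.shape[0]:
        raise FerrofluxError("blocks have different sample counts")
    if isinstance(X, pd.DataFrame) and isinstance(Y, pd.DataFrame):
        if not X.index.equals(Y.index):
            raise FerrofluxError("blocks have mismatched sample IDs/order")
    if n_joint < 1:
        raise FerrofluxError("n_joint must be >= 1")
    if n_joint > min(Xm.shape[1], Ym.shape[1], Xm.shape[0] - 1):
        raise FerrofluxError("n_joint exceeds the attainable rank")

    Xs, xm, xs = _center_scale(Xm, scaling)
    Ys, ym, ys = _center_scale(Ym, scaling)

    def joint(Xc, Yc):
        Uc, s, Vt = np.linalg.svd(Yc.T @ Xc, full_matrices=False)
        W = Vt[:n_joint].T
        C = Uc[:, :n_joint]
        return W, C

    W, C = joint(Xs, Ys)
    Xf, W_xo, T_xo, P_xo = _orth_filter(Xs, W, n_xorth)
    Yf, W_yo, U_yo, P_yo = _orth_filter(Ys, C, n_yorth)
    if n_xorth or n_yorth:
        W, C = joint(Xf, Yf)
    T, U = Xf @ W, Yf @ C
    B_t = np.linalg.lstsq(T, U, rcond=None)[0]
    B_u = np.linalg.lstsq(U, T, rcond=None)[0]

    def r2_parts(Ms, scores, loadings, T_o, P_o):
        tot = float((Ms**2).sum())
        jnt = float(((scores @ loadings.T) ** 2).sum())
        orth = float(((T_o @ P_o.T) ** 2).sum()) if T_o.shape[1] else 0.0
        return {"joint": jnt / tot, "orth": orth / tot,
                "residual": max(0.0, 1.0 - (jnt + orth) / tot)}

    r2 = {"X": r2_parts(Xs, T, W, T_xo, P_xo), "Y": r2_parts(Ys, U, C, U_yo, P_yo)}
    return O2plsModel(
        n_joint=n_joint, n_xorth=W_xo.shape[1], n_yorth=W_yo.shape[1],
        x_features=xf, y_features=yf, scaling=scaling,
        x_mean=xm, x_scale=xs, y_mean=ym, y_scale=ys,
        W=W, C=C, T=T, U=U, W_xo=W_xo, P_xo=P_xo, W_yo=W_yo, P_yo=P_yo,
        B_t=B_t, B_u=B_u, r2=r2,
    )


def _filter_new(Ms: np.ndarray, W_o: np.ndarray, P_o: np.ndarray) -> np.ndarray:
    Md = Ms
    for i in range(W_o.shape[1]):
        to = Md @ W_o[:, i]
        Md = Md - np.outer(to, P_o[:, i])
    return Md


def predict_y_from_x(model: O2plsModel, Xnew) -> np.ndarray:
    """Predict the Y block from new X samples (on the original Y scale)."""
    Xm, _ = _as_matrix(Xnew, "x")
    Xs = (Xm - model.x_mean) / model.x_scale
    T = _filter_new(Xs, model.W_xo, model.P_xo) @ model.W
    Ys_hat = T @ model.B_t @ model.C.T
    return Ys_hat * model.y_scale + model.y_mean


def predict_x_from_y(model: O2plsModel, Ynew) -> np.ndarray:
    """Predict the X block from new Y samples (on the original X scale)."""
    Ym, _ = _as_matrix(Ynew, "y")
    Ys = (Ym - model.y_mean) / model.y_scale
    U = _filter_new(Ys, model.W_yo, model.P_yo) @ model.C
    Xs_hat = U @ model.B_u @ model.W.T
    return Xs_hat * model.x_scale + model.x_mean


def crossval_components(
    X,
    Y,
    joint_grid=(1, 2, 3),
    xorth_grid=(0, 1, 2),
    yorth_grid=(0, 1, 2),
    folds: int = 7,
    seed: int | None = None,
    scaling: str = "uv",
):
    """Choose (n_joint, n_xorth, n_yorth) by symmetric k-fold CV.

    The objective sums, over folds, the standardized squared prediction
    error of Y-from-X plus X-from-Y.  Ties go to the smallest total
    component count.  Returns (best triple, error surface DataFrame).
    """
    Xm, _ = _as_matrix(X, "x")
    Ym, _ = _as_matrix(Y, "y")
    n = Xm.shape[0]
    if folds < 2:
        raise FerrofluxError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds
    if np.bincount(fold_of, minlength=folds).min() < 2:
        raise FerrofluxError("every fold needs at least 2 samples")

    grid = [
        (a, px, qy)
        for a, px, qy in itertools.product(joint_grid, xorth_grid, yorth_grid)
    ]
    rows = []
    best = None
    for a, px, qy in grid:
        err = 0.0
        ok = True
        for f in range(folds):
            tr, te = fold_of != f, fold_of == f
            try:
                m = fit_o2pls(Xm[tr], Ym[tr], a, px, qy, scaling=scaling)
            except FerrofluxError:
                ok = False
                break
            ry = Ym[te] - predict_y_from_x(m, Xm[te])
            rx = Xm[te] - predict_x_from_y(m, Ym[te])
            err += float(((ry / m.y_scale) ** 2).sum()) / Ym.shape[1]
            err += float(((rx / m.x_scale) ** 2).sum()) / Xm.shape[1]
        if not ok:
            rows.append((a, px, qy, np.nan))
            continue
        rows.append((a, px, qy, err))
        key = (err, a + px + qy)
        if best is None or key < best[0]:
            best = (key, (a, px, qy))
    surface = pd.DataFrame(rows, columns=["n_joint", "n_xorth", "n_yorth", "cv_error"])
    if best is None:
        raise FerrofluxError("no grid point could be fitted")
    return best[1], surface


def correlation_loadings(model: O2plsModel, X, Y):
    """Correlation-scaled joint loadings (pcorr, qcorr).

    pcorr[j, k] = Pearson corr(x_j, t_k) and qcorr[j, k] = corr(y_j, u_k);
    zero-variance features get 0 with a warning.  Entries lie in [-1, 1]
    and give the correlation-circle coordinates.
    """
    Xm, _ = _as_matrix(X, "x")
    Ym, _ = _as_matrix(Y, "y")

    def corr(M, scores, fids):
        Mc = M - M.mean(axis=0)
        Sc = scores - scores.mean(axis=0)
        mn = np.linalg.norm(Mc, axis=0)
        sn = np.linalg.norm(Sc, axis=0)
        bad = mn == 0
        if bad.any():
            warn(f"zero-variance feature(s) in correlation loadings: {list(fids[bad][:5])}")
        mn = np.where(bad, 1.0, mn)
        R = (Mc.T @ Sc) / np.outer(mn, np.where(sn == 0, 1.0, sn))
        R[bad] = 0.0
        cols = [f"joint{k + 1}" for k in range(scores.shape[1])]
        return pd.DataFrame(np.clip(R, -1, 1), index=fids, columns=cols)

    return corr(Xm, model.T, model.x_features), corr(Ym, model.U, model.y_features)
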