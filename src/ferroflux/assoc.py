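"""Univariate confirmation statistics and auxiliary tests.

Covers covariate-adjusted partial Spearman correlation (the confirmation
step for multivariate selections), Benjamini-Hochberg FDR adjustment,
the Mann-Kendall monotone-trend test across ordered groups, the
Wilcoxon-Mann-Whitney rank-sum test and hypergeometric over-representation
analysis of gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import FerrofluxError

__all__ = [
    "partial_spearman",
    "bh_adjust",
    "mann_kendall_trend",
    "TrendResult",
    "wilcoxon_rank_sum",
    "hypergeom_ora",
    "OraResult",
    "read_gmt",
]


def _covariate_design(Z, n: int) -> np.ndarray:
    """Build the adjustment design: rank continuous columns, dummy-encode
    categorical/string columns (binary numeric columns pass through)."""
    if Z is None:
        return np.empty((n, 0))
    if isinstance(Z, pd.Series):
        Z = Z.to_frame()
    if isinstance(Z, pd.DataFrame):
        cols = []
        for name in Z.columns:
            col = Z[name]
            if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
                dummies = pd.get_dummies(col, drop_first=True, dtype=float)
                cols.append(dummies.to_numpy())
            else:
                vals = col.to_numpy(dtype=float)
                if len(np.unique(vals)) <= 2:
                    cols.append(vals[:, None])
                else:
                    cols.append(stats.rankdata(vals)[:, None])
        return np.hstack(cols) if cols else np.empty((n, 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    return np.column_stack([stats.rankdata(Z[:, j]) for j in range(Z.shape[1])])


def partial_spearman(x, y, Z=None) -> tuple[float, float]:
    """Partial Spearman correlation of x and y adjusting for covariates Z.

    x, y and continuous covariates are rank-transformed (average ranks for
    ties); rho is the Pearson correlation of the rank residuals after
    regressing both ranked variables on [1, Z]; the p-value comes from
    t = rho * sqrt((n - 2 - k) / (1 - rho^2)) with k adjustment columns,
    two-sided.  With empty Z this is the ordinary Spearman correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if y.shape[0] != n:
        raise FerrofluxError("x and y lengths differ")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise FerrofluxError("correlation undefined for constant input")
    D = _covariate_design(Z, n)
    k = D.shape[1]
    if n <= k + 2:
        raise FerrofluxError("need n > #covariate columns + 2")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    design = np.column_stack([np.ones(n), D])
    coef_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ coef_x
    ey = ry - design @ coef_y
    denom = np.linalg.norm(ex) * np.linalg.norm(ey)
    if denom == 0:
        raise FerrofluxError("correlation undefined: residuals are constant")
    rho = float(np.clip(ex @ ey / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return rho, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise FerrofluxError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class TrendResult:
    """Mann-Kendall monotone-trend statistics across ordered groups."""

    S: int
    tau: float
    z: float
    p: float


def mann_kendall_trend(values, ordered_groups) -> TrendResult:
    """Mann-Kendall test for a monotone trend of ``values`` across ordered
    group levels (e.g. response quartiles).

    S = sum over sample pairs of sign(group diff) * sign(value diff);
    tau is Kendall's tau-b between group rank and value; the normal
    approximation uses the tie-corrected variance of S and a +-1 continuity
    correction.
    """
    v = np.asarray(values, dtype=float).ravel()
    g = pd.Series(list(ordered_groups))
    if isinstance(g.dtype, pd.CategoricalDtype):
        codes = g.cat.codes.to_numpy(dtype=float)
    else:
        codes = pd.factorize(g, sort=True)[0].astype(float)
    if np.unique(codes).size < 2:
        raise FerrofluxError("trend test needs >= 2 distinct group levels")
    n = v.shape[0]
    dg = np.sign(codes[:, None] - codes[None, :])
    dv = np.sign(v[:, None] - v[None, :])
    S = int(np.triu(dg * dv, k=1).sum())

    def tie_sizes(a):
        _, counts = np.unique(a, return_counts=True)
        return counts[counts > 1].astype(float)

    tg, tv = tie_sizes(codes), tie_sizes(v)
    n0 = n * (n - 1) / 2.0
    n1 = float((tg * (tg - 1) / 2.0).sum())
    n2 = float((tv * (tv - 1) / 2.0).sum())
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    tau = S / denom if denom > 0 else 0.0

    v0 = n * (n - 1) * (2 * n + 5)
    vt = float((tg * (tg - 1) * (2 * tg + 5)).sum())
    vu = float((tv * (tv - 1) * (2 * tv + 5)).sum())
    var = (v0 - vt - vu) / 18.0
    if n > 2:
        var += (
            float((tg * (tg - 1) * (tg - 2)).sum())
            * float((tv * (tv - 1) * (tv - 2)).sum())
            / (9.0 * n * (n - 1) * (n - 2))
        )
    var += (
        float((tg * (tg - 1)).sum()) * float((tv * (tv - 1)).sum()) / (2.0 * n * (n - 1))
    )
    if var <= 0:
        return TrendResult(S, float(tau), 0.0, 1.0)
    z = (S - np.sign(S)) / np.sqrt(var) if S != 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TrendResult(S, float(tau), float(z), min(p, 1.0))


def wilcoxon_rank_sum(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test; returns (U of sample a, p).

    ``mode="auto"`` enumerates the exact null when the combined sample size
    is <= 20 and there are no ties, and otherwise uses the tie-corrected
    normal approximation with continuity correction; ``"exact"`` and
    ``"normal"`` force a method.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise FerrofluxError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if mode == "auto":
        mode = "exact" if (a.size + b.size <= 20 and not has_ties) else "normal"
    if mode == "exact":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif mode == "normal":
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise FerrofluxError(f"unknown mode {mode!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass
class OraResult:
    set_id: str
    overlap: int
    set_size: int
    selected_size: int
    universe_size: int
    p: float
    p_adjusted: float


def hypergeom_ora(
    selected, gene_sets: dict, universe, correction: str = "bonferroni"
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` IDs in gene sets.

    Each set is intersected with the universe before testing; the p-value is
    the upper tail P(X >= k).  Correction across tested sets is Bonferroni
    (default) or Benjamini-Hochberg.
    """
    universe = set(universe)
    if not universe:
        raise FerrofluxError("empty universe")
    selected = set(selected)
    if not selected <= universe:
        raise FerrofluxError("selected IDs must be a subset of the universe")
    N, n = len(universe), len(selected)
    rows = []
    for set_id, members in gene_sets.items():
        members = set(members) & universe
        K = len(members)
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(OraResult(set_id, k, K, n, N, min(p, 1.0), np.nan))
    if not rows:
        return pd.DataFrame(
            columns=["set_id", "overlap", "set_size", "selected_size",
                     "universe_size", "p", "p_adjusted"]
        ).set_index("set_id")
    pvals = np.array([r.p for r in rows])
    if correction == "bonferroni":
        adj = np.minimum(pvals * len(pvals), 1.0)
    elif correction == "bh":
        adj = bh_adjust(pvals)
    else:
        raise FerrofluxError(f"unknown correction {correction!r}")
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("set_id")
    df["p_adjusted"] = adj
    return df


def read_gmt(path) -> dict:
    """Read gene sets from a GMT file (set name, description, members...)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = set(m for m in parts[2:] if m)
    return sets
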