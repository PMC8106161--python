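"""Feature-table preparation and ecology summaries.

Filtering and transforms preserve sample order and identifiers.  Diversity
indices, ordination and PERMANOVA follow the standard community-ecology
definitions (Shannon entropy in nats, bias-corrected Chao1, classical
metric scaling, Anderson's one-way pseudo-F with label permutation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import DistanceMatrix, FerrofluxError, OmicsBlock, warn

__all__ = [
    "filter_features",
    "relative_abundance",
    "log10_transform",
    "zscore",
    "assign_quartiles",
    "alpha_diversity",
    "beta_diversity",
    "pcoa",
    "Ordination",
    "permanova",
    "PermanovaResult",
]


def relative_abundance(block: OmicsBlock) -> OmicsBlock:
    """Close each sample to sum 1 (compositional normalisation)."""
    if block.kind != "counts":
        raise FerrofluxError("relative_abundance expects a counts block")
    vals = block.values()
    totals = vals.sum(axis=1)
    zero = totals == 0
    if zero.any():
        bad = list(block.sample_ids[zero])
        raise FerrofluxError(f"all-zero samples cannot be closed: {bad}")
    data = pd.DataFrame(
        vals / totals[:, None], index=block.sample_ids, columns=block.feature_ids
    )
    return OmicsBlock(block.name, data, kind="intensity")


def filter_features(
    block: OmicsBlock,
    abundance_threshold: float = 0.20,
    prevalence_threshold: float = 0.20,
) -> OmicsBlock:
    """Keep features whose per-sample relative abundance exceeds
    ``abundance_threshold`` in at least ``prevalence_threshold`` of samples.

    Counts input is closed to relative abundance internally; the returned
    block keeps the original values of the surviving features, in order.
    """
    for t in (abundance_threshold, prevalence_threshold):
        if not 0.0 <= t <= 1.0:
            raise FerrofluxError("thresholds must be in [0, 1]")
    vals = block.values()
    totals = vals.sum(axis=1)
    totals[totals == 0] = 1.0
    rel = vals / totals[:, None]
    frac_exceeding = (rel > abundance_threshold).mean(axis=0)
    keep = frac_exceeding >= prevalence_threshold
    if not keep.any():
        warn(f"block {block.name!r}: no feature passes the abundance/prevalence filter")
    return block.with_data(block.data.loc[:, keep])


def log10_transform(block: OmicsBlock, pseudocount: float = 0.0) -> OmicsBlock:
    """Elementwise log10(value + pseudocount)."""
    vals = block.values() + pseudocount
    if (vals <= 0).any():
        bad = np.argwhere(vals <= 0)
        cells = [(block.sample_ids[i], block.feature_ids[j]) for i, j in bad[:5]]
        raise FerrofluxError(
            f"log10 undefined for {len(bad)} nonpositive cells, e.g. {cells}"
        )
    data = pd.DataFrame(np.log10(vals), index=block.sample_ids, columns=block.feature_ids)
    return OmicsBlock(block.name, data, kind="intensity")


def zscore(block: OmicsBlock) -> OmicsBlock:
    """Standardize each feature across samples to mean 0, SD 1 (ddof=1).

    Constant features are dropped with a warning.
    """
    vals = block.values()
    sd = vals.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(block.feature_ids[~keep])
        warn(f"block {block.name!r}: dropping constant features {dropped[:5]}")
    vals = vals[:, keep]
    z = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
    data = pd.DataFrame(z, index=block.sample_ids, columns=block.feature_ids[keep])
    return OmicsBlock(block.name, data, kind="intensity")


def assign_quartiles(values) -> pd.Series:
    """Assign Q1..Q4 labels from the 25/50/75 empirical percentiles.

    Percentiles use the linear-interpolation (type 7) definition; values
    equal to a cut point go to the lower quartile.
    """
    ser = pd.Series(values)
    v = ser.to_numpy(dtype=float)
    if v.size < 4:
        raise FerrofluxError("quartile assignment needs at least 4 values")
    q25, q50, q75 = np.quantile(v, [0.25, 0.50, 0.75])
    if q25 == q75:
        warn("degenerate value distribution: all samples assigned Q1")
    labels = np.where(v <= q25, "Q1", np.where(v <= q50, "Q2", np.where(v <= q75, "Q3", "Q4")))
    return pd.Series(pd.Categorical(labels, categories=["Q1", "Q2", "Q3", "Q4"], ordered=True),
                     index=ser.index, name="quartile")


def _chao1(counts: np.ndarray, bias_corrected: bool) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        # classic form undefined; fall back to the bias-corrected estimate
        return s_obs + f1 * (f1 - 1) / 2.0
    return s_obs + f1 * f1 / (2.0 * f2)


def alpha_diversity(block: OmicsBlock, chao1_bias_corrected: bool = True) -> pd.DataFrame:
    """Per-sample Shannon H (nats), Chao1 richness estimate and observed species.

    Shannon uses natural log over nonzero relative abundances; Chao1 defaults
    to the bias-corrected form S_obs + F1(F1-1)/(2(F2+1)).
    """
    if block.kind != "counts":
        raise FerrofluxError("alpha_diversity expects a counts block")
    vals = block.values()
    if (vals.sum(axis=1) == 0).any():
        raise FerrofluxError("empty sample(s) in alpha_diversity input")
    rows = []
    for i in range(vals.shape[0]):
        c = vals[i]
        p = c[c > 0] / c.sum()
        rows.append(
            {
                "shannon": float(-(p * np.log(p)).sum()),
                "chao1": _chao1(c, chao1_bias_corrected),
                "observed_species": int((c > 0).sum()),
            }
        )
    return pd.DataFrame(rows, index=block.sample_ids)


_METRICS = {"canberra", "bray_curtis", "euclidean"}


def beta_diversity(block: OmicsBlock, metric: str = "canberra") -> DistanceMatrix:
    """Pairwise sample distances (Canberra, Bray-Curtis or Euclidean).

    Canberra skips coordinates where both entries are zero (SciPy's
    convention).  Bray-Curtis with an all-zero sample yields distance 1 to
    every other sample, with a warning.
    """
    if metric not in _METRICS:
        raise FerrofluxError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    vals = block.values()
    scipy_metric = {"bray_curtis": "braycurtis"}.get(metric, metric)
    D = squareform(pdist(vals, metric=scipy_metric))
    if metric == "bray_curtis":
        zero = vals.sum(axis=1) == 0
        if zero.any():
            warn("all-zero sample(s) in Bray-Curtis input; distances set to 1")
            D[zero, :] = 1.0
            D[:, zero] = 1.0
            np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return DistanceMatrix(block.sample_ids, D)


@dataclass
class Ordination:
    """Classical-scaling result: sample scores, eigenvalues, proportions."""

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(D: DistanceMatrix, k: int | None = None) -> Ordination:
    """Principal coordinate analysis (classical metric scaling).

    Double-centers -0.5 * D^2, eigendecomposes, scales eigenvectors by the
    square root of their (positive) eigenvalues.  Negative eigenvalues are
    reported but excluded from the proportion-explained denominator, and
    their axes are dropped.
    """
    n = D.n_samples
    if k is None:
        k = n - 1
    if k > n - 1:
        raise FerrofluxError("k must be <= n - 1")
    A = -0.5 * D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    evals, evecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0.0) * 1e-12
    denom = evals[pos].sum() if pos.any() else 1.0
    n_axes = min(k, int(pos.sum()))
    scores = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    cols = [f"PCo{i + 1}" for i in range(n_axes)]
    return Ordination(
        scores=pd.DataFrame(scores, index=D.sample_ids, columns=cols),
        eigenvalues=evals[:k],
        proportion_explained=np.clip(evals[:k], 0.0, None) / denom,
    )


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int


def _pseudo_f(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = D2.shape[0]
    ss_total = D2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = codes == g
        ng = idx.sum()
        ss_within += D2[np.ix_(idx, idx)].sum() / (2.0 * ng)
    ss_among = ss_total - ss_within
    f = (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_among / ss_total


def permanova(
    D: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA pseudo-F with a label-permutation p-value.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).  With
    ``exact=True`` every distinct relabeling is enumerated instead (only
    sensible for small n).
    """
    codes, uniques = pd.factorize(pd.Series(list(groups)))
    a = len(uniques)
    if a < 2:
        raise FerrofluxError("PERMANOVA needs at least two groups")
    if len(codes) != D.n_samples:
        raise FerrofluxError("group labels / distance matrix length mismatch")
    if n_permutations < 1 and not exact:
        raise FerrofluxError("n_permutations must be >= 1")
    D2 = D.values**2
    f_obs, r2 = _pseudo_f(D2, codes, a)

    if exact:
        perms = set(itertools.permutations(codes.tolist()))
        count = sum(
            _pseudo_f(D2, np.array(p), a)[0] >= f_obs - 1e-12 for p in perms
        )
        return PermanovaResult(f_obs, r2, count / len(perms), len(perms))

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(D2, perm, a)[0] >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(f_obs, r2, p, n_permutations)
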