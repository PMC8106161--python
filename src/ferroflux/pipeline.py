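"""End-to-end discovery -> validation -> integration workflow.

Per omics block the discovery stage fits an O-PLS model of the response,
gates it by permutation validation of Q2Y, selects features by the
VIP/pFDR rule (pFDR < 0.05, or pFDR < 0.10 with VIP > 1) and confirms each
selection by covariate-adjusted partial Spearman correlation.  A parallel
penalized-regression track (Mnet with unpenalized covariates) reports
nonzero coefficients and overlap with the O-PLS track.  Integration fits an
O2-PLS model between two selected feature subsets and an all-pairs partial
Spearman heatmap table with display (p < 0.05) and highlight (pFDR < 0.05)
masks.  Clustering support orders z-scored matrices by Ward linkage on
Euclidean distances.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from . import preprocess
from .assoc import bh_adjust, partial_spearman
from .containers import CohortTable, FerrofluxError, OmicsBlock
from .mnet import MnetConfig, cv_mnet
from .o2pls import correlation_loadings, crossval_components, fit_o2pls
from .opls import fit_opls, permutation_test, select_features
from .synthetic import SyntheticDataset

__all__ = ["PipelineConfig", "run_discovery", "run_mnet_discovery",
           "run_integration", "hca_order", "ClusterOrder", "make_report"]


@dataclass
class PipelineConfig:
    """Per-stage parameters of the discovery workflow."""

    response: str = "ferritin"
    covariates: tuple = ("age", "bmi", "sex", "country")
    n_orth: int = 1
    n_permutations: int = 1000
    permutation_cv: object = "loo"   # Q2 estimator inside the permutation test
    gate_alpha: float = 0.05         # permutation p_Q2Y threshold to proceed
    fdr_primary: float = 0.05
    fdr_relaxed: float = 0.10
    vip_cut: float = 1.0
    psc_alpha: float = 0.05
    abundance_threshold: float = 0.20
    prevalence_threshold: float = 0.20
    pseudocount: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        for t in (self.gate_alpha, self.fdr_primary, self.fdr_relaxed, self.psc_alpha):
            if not 0.0 < t < 1.0:
                raise FerrofluxError("thresholds must be in (0, 1)")


def prepare_block(block: OmicsBlock, config: PipelineConfig) -> OmicsBlock:
    """Closure + abundance/prevalence filter + log10 for counts blocks;
    log10 only for intensity blocks."""
    if block.kind == "counts":
        filtered = preprocess.filter_features(
            block, config.abundance_threshold, config.prevalence_threshold
        )
        if filtered.n_features == 0:
            return filtered
        rel = preprocess.relative_abundance(
            OmicsBlock(filtered.name, filtered.data, kind="counts")
        )
        return preprocess.log10_transform(rel, pseudocount=config.pseudocount)
    return preprocess.log10_transform(block, pseudocount=0.0)


@dataclass
class DiscoveryResult:
    block: str
    validated: bool
    r2y: float
    q2y: float
    p_r2y: float
    p_q2y: float
    table: pd.DataFrame | None  # per-feature associations, None if not validated


def run_discovery(
    cohort: CohortTable, blocks: list[OmicsBlock], config: PipelineConfig
) -> dict[str, DiscoveryResult]:
    """O-PLS discovery with permutation gating and pSC confirmation.

    For every block: preprocess, fit O-PLS of the response, permutation-test
    Q2Y; if p_Q2Y >= gate_alpha the block is recorded as "model not valid"
    and selection is skipped.  Otherwise features pass the VIP/pFDR rule and
    each selection is confirmed by partial Spearman correlation with the
    response, adjusted for the configured covariates.
    """
    y = cohort.response_values()
    Z = cohort.table[list(config.covariates)] if config.covariates else None
    out: dict[str, DiscoveryResult] = {}
    for raw in blocks:
        prepped = prepare_block(raw, config)
        if prepped.n_features == 0:
            out[raw.name] = DiscoveryResult(raw.name, False, np.nan, np.nan,
                                            np.nan, np.nan, None)
            continue
        X = prepped.data
        model = fit_opls(X, y, n_orth=config.n_orth)
        perm = permutation_test(
            X, y, n_orth=config.n_orth,
            n_permutations=config.n_permutations,
            seed=config.seed, cv=config.permutation_cv,
        )
        if perm.p_q2y >= config.gate_alpha:
            out[raw.name] = DiscoveryResult(
                raw.name, False, perm.r2y, perm.q2y, perm.p_r2y, perm.p_q2y, None
            )
            continue
        table = select_features(
            X, y, model,
            fdr_primary=config.fdr_primary,
            fdr_relaxed=config.fdr_relaxed,
            vip_cut=config.vip_cut,
        )
        rho = np.full(len(table), np.nan)
        psc_p = np.full(len(table), np.nan)
        sel_idx = np.flatnonzero(table["selected"].to_numpy())
        for i in sel_idx:
            rho[i], psc_p[i] = partial_spearman(
                X.iloc[:, i].to_numpy(), y, Z
            )
        table = table.assign(psc_rho=rho, psc_p=psc_p)
        table["confirmed"] = table["selected"] & (table["psc_p"] < config.psc_alpha)
        out[raw.name] = DiscoveryResult(
            raw.name, True, perm.r2y, perm.q2y, perm.p_r2y, perm.p_q2y, table
        )
    return out


def run_mnet_discovery(
    cohort: CohortTable,
    block: OmicsBlock,
    config: PipelineConfig,
    mnet_config: MnetConfig | None = None,
    mnet_covariates: tuple = ("age", "bmi", "country", "hscrp"),
) -> pd.DataFrame:
    """CV-tuned Mnet regression of the response on one block.

    Covariates enter unpenalized; returns the per-feature coefficient table
    with a ``selected`` flag for nonzero coefficients.
    """
    prepped = prepare_block(block, config)
    if prepped.n_features == 0:
        raise FerrofluxError(f"block {block.name!r}: nothing to fit after filtering")
    y = cohort.response_values()
    cov = [c for c in mnet_covariates if c in cohort.table.columns]
    Z = cohort.table[cov] if cov else None
    mc = mnet_config or MnetConfig(seed=config.seed)
    fit = cv_mnet(prepped.data, y, Z, mc)
    return pd.DataFrame(
        {
            "coefficient": fit.beta,
            "selected": fit.beta != 0,
            "lambda": fit.lam,
            "alpha": fit.alpha,
            "gamma": fit.gamma,
        }
    )


@dataclass
class IntegrationResult:
    model: object
    pcorr: pd.DataFrame
    qcorr: pd.DataFrame
    psc_rho: pd.DataFrame
    psc_p: pd.DataFrame
    psc_pfdr: pd.DataFrame
    displayed: pd.DataFrame  # mask, p < 0.05
    highlighted: pd.DataFrame  # mask, pFDR < 0.05


def run_integration(
    cohort: CohortTable,
    block_a: OmicsBlock,
    block_b: OmicsBlock,
    config: PipelineConfig,
    features_a=None,
    features_b=None,
    joint_grid=(1, 2), xorth_grid=(0, 1), yorth_grid=(0, 1),
    folds: int = 7,
) -> IntegrationResult:
    """O2-PLS integration of two (typically response-associated) feature
    subsets plus the all-pairs partial Spearman heatmap table.

    Component counts come from symmetric k-fold CV (7 folds by default);
    the heatmap display mask keeps raw p < 0.05 and the highlight mask
    keeps BH pFDR < 0.05 (highlight is nested in display whenever BH does
    not reorder significance, which it preserves by monotonicity).
    """
    pa = prepare_block(block_a, config)
    pb = prepare_block(block_b, config)
    A = pa.data if features_a is None else pa.data.loc[:, list(features_a)]
    B = pb.data if features_b is None else pb.data.loc[:, list(features_b)]
    if A.shape[1] == 0 or B.shape[1] == 0:
        raise FerrofluxError("integration needs nonempty feature subsets")
    (nj, nx, ny), surface = crossval_components(
        A, B, joint_grid, xorth_grid, yorth_grid, folds=folds, seed=config.seed
    )
    model = fit_o2pls(A, B, nj, nx, ny)
    pcorr, qcorr = correlation_loadings(model, A, B)

    Z = cohort.table[list(config.covariates)] if config.covariates else None
    rho = np.zeros((A.shape[1], B.shape[1]))
    pmat = np.ones_like(rho)
    for i in range(A.shape[1]):
        xi = A.iloc[:, i].to_numpy()
        for j in range(B.shape[1]):
            rho[i, j], pmat[i, j] = partial_spearman(xi, B.iloc[:, j].to_numpy(), Z)
    pfdr = bh_adjust(pmat.ravel()).reshape(pmat.shape)
    mk = lambda M: pd.DataFrame(M, index=A.columns, columns=B.columns)
    res = IntegrationResult(
        model=model, pcorr=pcorr, qcorr=qcorr,
        psc_rho=mk(rho), psc_p=mk(pmat), psc_pfdr=mk(pfdr),
        displayed=mk(pmat < 0.05), highlighted=mk(pfdr < 0.05),
    )
    res.cv_surface = surface
    return res


@dataclass
class ClusterOrder:
    linkage: np.ndarray   # SciPy linkage matrix (Ward.D2 on Euclidean)
    leaf_order: np.ndarray

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise FerrofluxError("non-monotone merge heights")


def hca_order(matrix) -> ClusterOrder:
    """Ward-linkage hierarchical clustering order of the rows.

    Uses the Ward.D2 criterion on Euclidean distances; the leaf order is
    SciPy's deterministic recursive child ordering (lower original index
    first on ties).  Input rows are expected z-scored.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise FerrofluxError("need a 2-D matrix with >= 2 rows")
    if np.isnan(M).any():
        raise FerrofluxError("NaN values in clustering input")
    Lk = linkage(pdist(M, metric="euclidean"), method="ward")
    return ClusterOrder(linkage=Lk, leaf_order=np.asarray(leaves_list(Lk)))


def make_report(
    outdir: str | Path,
    config: PipelineConfig,
    discovery: dict[str, DiscoveryResult] | None = None,
    mnet_tables: dict[str, pd.DataFrame] | None = None,
    integration: IntegrationResult | None = None,
    truth: pd.DataFrame | None = None,
) -> Path:
    """Write per-stage TSVs, a YAML run manifest and a plain-text summary.

    When a nonempty ground-truth table is supplied, recovery metrics
    (sensitivity of planted effects, false-discovery fraction among
    confirmed features) are computed per block and included.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "outputs": {}}
    lines = ["ferroflux run summary", "=" * 21, ""]

    if discovery:
        for name, res in discovery.items():
            lines.append(
                f"block {name}: "
                + (
                    f"validated (R2Y={res.r2y:.3f}, Q2Y={res.q2y:.3f}, "
                    f"p_R2Y={res.p_r2y:.4g}, p_Q2Y={res.p_q2y:.4g})"
                    if res.validated
                    else f"model not valid (p_Q2Y={res.p_q2y:.4g})"
                )
            )
            if res.table is not None:
                path = outdir / f"discovery_{name}.tsv"
                res.table.to_csv(path, sep="\t", float_format="%.12g")
                manifest["outputs"][f"discovery_{name}"] = path.name
                n_sel = int(res.table["selected"].sum())
                n_conf = int(res.table["confirmed"].sum())
                lines.append(f"  selected={n_sel} confirmed={n_conf}")
                if truth is not None and len(truth):
                    planted = set(
                        truth.loc[
                            (truth["block"] == name) & (truth["kind"] == "effect"),
                            "feature_id",
                        ]
                    )
                    if planted:
                        confirmed = set(res.table.index[res.table["confirmed"]])
                        tp = len(planted & confirmed)
                        sens = tp / len(planted)
                        fdr = (len(confirmed - planted) / len(confirmed)) if confirmed else 0.0
                        lines.append(f"  recovery: sensitivity={sens:.3f} fdr={fdr:.3f}")
                        manifest["outputs"][f"recovery_{name}"] = {
                            "sensitivity": sens, "fdr": fdr,
                        }
    if mnet_tables:
        for name, tab in mnet_tables.items():
            path = outdir / f"mnet_{name}.tsv"
            tab.to_csv(path, sep="\t", float_format="%.12g")
            manifest["outputs"][f"mnet_{name}"] = path.name
            lines.append(f"mnet {name}: nonzero={int(tab['selected'].sum())}")
    if integration is not None:
        for label, df in (
            ("pcorr", integration.pcorr), ("qcorr", integration.qcorr),
            ("psc_rho", integration.psc_rho), ("psc_p", integration.psc_p),
            ("psc_pfdr", integration.psc_pfdr),
        ):
            path = outdir / f"integration_{label}.tsv"
            df.to_csv(path, sep="\t", float_format="%.12g")
            manifest["outputs"][f"integration_{label}"] = path.name
        lines.append(
            f"integration: joint={integration.model.n_joint} "
            f"xorth={integration.model.n_xorth} yorth={integration.model.n_yorth} "
            f"displayed={int(integration.displayed.to_numpy().sum())} "
            f"highlighted={int(integration.highlighted.to_numpy().sum())}"
        )

    hashes = {}
    for f in sorted(outdir.glob("*.tsv")):
        hashes[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest["output_hashes"] = hashes
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(manifest, default=str)), fh, sort_keys=False)
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return outdir / "manifest.yaml"
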