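"""Seeded simulator for coupled phenotype / multi-omics datasets.

The generator emulates the statistical structure of post-processing feature
tables from an obesity/NAFLD-style cohort study:

* a skewed, strictly positive continuous response (e.g. serum ferritin),
  drawn log-normal;
* covariates (age, BMI, sex, country, hs-CRP) with controlled rank
  correlation to the response, induced through a Gaussian copula;
* overdispersed compositional taxa count tables (Dirichlet-multinomial);
* log-normal metabolite / transcript intensity tables;
* planted response->feature effects (a per-unit shift of feature
  log-abundance per unit of the standardized log-response) and planted
  cross-block feature pairs coupled through shared latent factors.

All randomness derives from a single integer master seed through a stable
label-based sub-seeding scheme (`SeedSequence` spawn keys computed from
CRC32 of string labels), so adding a block never perturbs the draws of the
cohort or of earlier blocks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .containers import CohortTable, FerrofluxError, OmicsBlock

__all__ = [
    "CovariateDef",
    "CohortSpec",
    "BlockSpec",
    "SyntheticDataset",
    "generate_cohort",
    "generate_block",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]


def _rng(seed: int, *labels) -> np.random.Generator:
    """Deterministic per-purpose RNG derived from the master seed.

    The spawn key is the CRC32 of each string label, so streams are stable
    across sessions and independent across labels.
    """
    key = tuple(zlib.crc32(str(lab).encode("utf-8")) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


@dataclass
class CovariateDef:
    """Marginal definition of one covariate.

    kind = "continuous": params {"mean", "sd"} (normal) or
        {"log_mean", "log_sd"} (log-normal, e.g. hs-CRP).
    kind = "binary": params {"p"} (probability of 1).
    kind = "categorical": params {"levels": {label: prob, ...}}.
    """

    name: str
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise FerrofluxError(f"covariate {self.name!r}: unknown kind {self.kind!r}")


def _default_covariates() -> list[CovariateDef]:
    # Middle-aged cohort with obesity recruited in two countries.
    return [
        CovariateDef("age", "continuous", {"mean": 45.0, "sd": 9.0}),
        CovariateDef("bmi", "continuous", {"mean": 35.0, "sd": 5.0}),
        CovariateDef("sex", "binary", {"p": 0.5}),
        CovariateDef("country", "categorical", {"levels": {"IT": 0.5, "ES": 0.5}}),
        CovariateDef("hscrp", "continuous", {"log_mean": 0.5, "log_sd": 0.9}),
    ]


@dataclass
class CohortSpec:
    """Specification of the simulated cohort.

    The response is log-normal: ``exp(N(response_log_mean, response_log_sd))``.
    ``confounding`` lists (covariate name, latent correlation in [-1, 1])
    pairs; each requested correlation is induced between the covariate's
    Gaussian copula latent and the response latent, so for continuous-normal
    covariates it equals the Pearson correlation with log-response.
    """

    n_samples: int = 200
    response_name: str = "ferritin"
    response_log_mean: float = 4.0
    response_log_sd: float = 0.8
    covariate_defs: list[CovariateDef] = field(default_factory=_default_covariates)
    confounding: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise FerrofluxError("n_samples must be >= 4")
        if self.response_log_sd < 0:
            raise FerrofluxError("response_log_sd must be >= 0")
        names = [d.name for d in self.covariate_defs]
        if len(set(names)) != len(names):
            raise FerrofluxError("duplicate covariate names")
        for cov, rho in self.confounding:
            if cov not in names:
                raise FerrofluxError(f"confounding names unknown covariate {cov!r}")
            if not -1.0 <= rho <= 1.0:
                raise FerrofluxError("confounding correlation must be in [-1, 1]")


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a cohort table from ``spec`` (deterministic given ``spec.seed``).

    Covariate-response dependence uses a Gaussian copula: each covariate's
    latent is ``rho * z_response + sqrt(1 - rho^2) * noise`` and is pushed
    through the covariate's marginal inverse CDF.
    """
    n = spec.n_samples
    rho_map = dict(spec.confounding)
    rng = _rng(spec.seed, "cohort")
    z_resp = rng.standard_normal(n)
    response = np.exp(spec.response_log_mean + spec.response_log_sd * z_resp)

    cols: dict[str, np.ndarray | pd.Series] = {spec.response_name: response}
    for d in spec.covariate_defs:
        rho = float(rho_map.get(d.name, 0.0))
        eps = _rng(spec.seed, "covariate", d.name).standard_normal(n)
        z = rho * z_resp + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
        if d.kind == "continuous":
            if "log_mean" in d.params:
                vals = np.exp(d.params["log_mean"] + d.params.get("log_sd", 1.0) * z)
            else:
                vals = d.params.get("mean", 0.0) + d.params.get("sd", 1.0) * z
            cols[d.name] = vals
        elif d.kind == "binary":
            p = float(d.params.get("p", 0.5))
            cols[d.name] = (stats.norm.cdf(z) < p).astype(int)
        else:  # categorical
            levels = d.params["levels"]
            labels = list(levels.keys())
            cum = np.cumsum([levels[k] for k in labels])
            if not np.isclose(cum[-1], 1.0):
                raise FerrofluxError(f"covariate {d.name!r}: level probs must sum to 1")
            u = stats.norm.cdf(z)
            idx = np.searchsorted(cum, u, side="left").clip(max=len(labels) - 1)
            cols[d.name] = pd.Categorical([labels[i] for i in idx], categories=labels)

    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")
    table = pd.DataFrame(cols, index=sample_ids)
    return CohortTable(
        table=table,
        response=spec.response_name,
        covariates=[d.name for d in spec.covariate_defs],
        seed=spec.seed,
    )


@dataclass
class BlockSpec:
    """Specification of one omics block.

    For ``kind="counts"`` the dispersion is the Dirichlet-multinomial
    concentration (smaller = more overdispersed); for ``kind="intensity"``
    it is the log-scale residual SD.  ``planted_effects`` maps feature index
    -> effect size beta, a shift of the feature's log-abundance per unit of
    the standardized log-response.  ``cross_block_links`` lists
    (feature_here, other_block_name, feature_there, loading) tuples realised
    through shared standard-normal latent factors.
    """

    name: str
    kind: str = "counts"
    n_features: int = 100
    baseline_log_abundance: tuple[float, float] | np.ndarray = (0.0, 1.0)
    dispersion: float = 50.0
    depth_log_mean: float = np.log(20000.0)
    depth_log_sd: float = 0.25
    planted_effects: list[tuple[int, float]] = field(default_factory=list)
    cross_block_links: list[tuple[int, str, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "intensity"):
            raise FerrofluxError(f"block {self.name!r}: unknown kind {self.kind!r}")
        if self.n_features < 1:
            raise FerrofluxError("n_features must be positive")
        if self.dispersion <= 0:
            raise FerrofluxError("dispersion must be positive")
        idx = [j for j, _ in self.planted_effects]
        if len(set(idx)) != len(idx):
            raise FerrofluxError("planted feature indices must be unique")
        for j in idx + [j for j, _, _, _ in self.cross_block_links]:
            if not 0 <= j < self.n_features:
                raise FerrofluxError(f"planted/linked feature index {j} out of range")

    def feature_ids(self) -> pd.Index:
        return pd.Index([f"{self.name}_f{j:04d}" for j in range(self.n_features)])


def _link_factor(cohort: CohortTable, here: str, other: str, j: int, k: int, n: int) -> np.ndarray:
    """Shared latent factor for one cross-block link.

    The key is canonical in the block pair so both ends regenerate the same
    factor regardless of which block is generated first.
    """
    (b1, f1), (b2, f2) = sorted([(here, j), (other, k)])
    rng = _rng(cohort.seed or 0, "link", b1, f1, b2, f2)
    return rng.standard_normal(n)


def _standardized_log_response(cohort: CohortTable) -> np.ndarray:
    logy = np.log(cohort.response_values())
    sd = logy.std(ddof=1)
    if sd == 0:
        return np.zeros_like(logy)
    return (logy - logy.mean()) / sd


def generate_block(cohort: CohortTable, spec: BlockSpec) -> OmicsBlock:
    """Draw one omics block coupled to the cohort's response.

    Counts: per-sample Dirichlet-multinomial with log-composition
    ``baseline + beta * z(log response) + link loadings * shared factors``;
    each sample's total equals its drawn sequencing depth.
    Intensity: exp of a Gaussian with the same systematic structure.
    """
    if cohort.n_samples == 0:
        raise FerrofluxError("cohort is empty")
    n = cohort.n_samples
    p = spec.n_features
    seed = cohort.seed or 0
    rng = _rng(seed, "block", spec.name)

    base = np.asarray(spec.baseline_log_abundance, dtype=float)
    if base.ndim == 0 or base.shape == (2,):
        mu, sd = (float(base), 0.0) if base.ndim == 0 else (float(base[0]), float(base[1]))
        base = mu + sd * rng.standard_normal(p)
    elif base.shape != (p,):
        raise FerrofluxError("baseline_log_abundance vector has wrong length")

    z = _standardized_log_response(cohort)
    eta = np.tile(base, (n, 1))
    for j, beta in spec.planted_effects:
        eta[:, j] += float(beta) * z
    for j, other, k, loading in spec.cross_block_links:
        eta[:, j] += float(loading) * _link_factor(cohort, spec.name, other, j, k, n)

    if spec.kind == "counts":
        depths = np.maximum(
            1, np.round(np.exp(rng.normal(spec.depth_log_mean, spec.depth_log_sd, size=n)))
        ).astype(int)
        comp = np.exp(eta - eta.max(axis=1, keepdims=True))
        comp /= comp.sum(axis=1, keepdims=True)
        counts = np.empty((n, p), dtype=int)
        for i in range(n):
            probs = rng.dirichlet(spec.dispersion * comp[i])
            counts[i] = rng.multinomial(depths[i], probs)
        data = pd.DataFrame(counts, index=cohort.sample_ids, columns=spec.feature_ids())
        return OmicsBlock(spec.name, data, kind="counts")

    vals = np.exp(eta + spec.dispersion * rng.standard_normal((n, p)))
    data = pd.DataFrame(vals, index=cohort.sample_ids, columns=spec.feature_ids())
    return OmicsBlock(spec.name, data, kind="intensity")


@dataclass
class SyntheticDataset:
    """Cohort + blocks + ground-truth table of planted structure."""

    cohort: CohortTable
    blocks: list[OmicsBlock]
    truth: pd.DataFrame  # columns: block, feature_id, kind, partner, value

    def __post_init__(self) -> None:
        for b in self.blocks:
            if not b.sample_ids.equals(self.cohort.sample_ids):
                raise FerrofluxError(f"block {b.name!r} sample IDs differ from cohort")

    def block(self, name: str) -> OmicsBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)


def truth_table(block_specs: list[BlockSpec]) -> pd.DataFrame:
    rows = []
    for spec in block_specs:
        fids = spec.feature_ids()
        for j, beta in spec.planted_effects:
            rows.append((spec.name, fids[j], "effect", "", float(beta)))
        for j, other, k, loading in spec.cross_block_links:
            rows.append((spec.name, fids[j], "link", f"{other}:{k}", float(loading)))
    return pd.DataFrame(rows, columns=["block", "feature_id", "kind", "partner", "value"])


def generate_dataset(cohort_spec: CohortSpec, block_specs: list[BlockSpec]) -> SyntheticDataset:
    """Generate the cohort and every block under one master seed."""
    names = [s.name for s in block_specs]
    if len(set(names)) != len(names):
        raise FerrofluxError("duplicate block names")
    cohort = generate_cohort(cohort_spec)
    blocks = [generate_block(cohort, spec) for spec in block_specs]
    return SyntheticDataset(cohort, blocks, truth_table(block_specs))


def write_dataset(ds: SyntheticDataset, directory: str | Path) -> Path:
    """Write TSVs (blocks features x samples, metadata, truth) plus a YAML manifest.

    Returns the manifest path.  Block tables are written features-in-rows
    with a header row of sample IDs, floats at full precision, so they
    round-trip losslessly through :func:`read_dataset`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "response": ds.cohort.response,
        "covariates": list(ds.cohort.covariates),
        "seed": ds.cohort.seed,
        "orientation": "features_x_samples",
        "metadata": "metadata.tsv",
        "truth": "truth.tsv",
        "blocks": [],
    }
    ds.cohort.table.to_csv(directory / "metadata.tsv", sep="\t", index_label="sample_id")
    ds.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
    for b in ds.blocks:
        fname = f"block_{b.name}.tsv"
        b.data.T.to_csv(directory / fname, sep="\t", index_label="feature_id", float_format="%.17g")
        manifest["blocks"].append({"name": b.name, "kind": b.kind, "file": fname})
    if not ds.truth.shape[0]:
        (directory / "truth.tsv").write_text("block\tfeature_id\tkind\tpartner\tvalue\n")
    path = directory / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def read_dataset(directory: str | Path) -> SyntheticDataset:
    """Read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    meta = pd.read_csv(directory / manifest["metadata"], sep="\t", index_col="sample_id")
    cohort = CohortTable(
        table=meta,
        response=manifest["response"],
        covariates=list(manifest["covariates"]),
        seed=manifest.get("seed"),
    )
    blocks = []
    for entry in manifest["blocks"]:
        df = pd.read_csv(directory / entry["file"], sep="\t", index_col="feature_id").T
        df.index.name = "sample_id"
        if entry["kind"] == "counts":
            df = df.round().astype(int)
        blocks.append(OmicsBlock(entry["name"], df, kind=entry["kind"]))
    truth = pd.read_csv(directory / manifest["truth"], sep="\t")
    if truth.empty:
        truth = pd.DataFrame(columns=["block", "feature_id", "kind", "partner", "value"])
    else:
        truth["partner"] = truth["partner"].fillna("")
    return SyntheticDataset(cohort, blocks, truth)
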