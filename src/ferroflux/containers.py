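"""In-memory containers shared across the pipeline.

An :class:`OmicsBlock` is a named samples-by-features numeric table with a
block kind (``counts`` for taxa count tables, ``intensity`` for metabolite or
transcript levels).  A :class:`CohortTable` carries per-sample phenotype and
covariate information, with the continuous response (serum ferritin in the
motivating application) identified by name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OmicsBlock", "CohortTable", "DistanceMatrix", "FerrofluxError"]


class FerrofluxError(ValueError):
    """Base error for invalid specifications or degenerate inputs."""


@dataclass
class OmicsBlock:
    """A named samples x features numeric matrix.

    Parameters
    ----------
    name : str
        Block label (e.g. ``"taxa"``, ``"metabolome"``).
    data : pandas.DataFrame
        Samples in rows, features in columns.  Index = sample IDs,
        columns = feature IDs.
    kind : {"counts", "intensity"}
        ``counts`` requires nonnegative integers.
    """

    name: str
    data: pd.DataFrame
    kind: str = "intensity"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "intensity"):
            raise FerrofluxError(f"unknown block kind {self.kind!r}")
        if self.data.index.has_duplicates:
            raise FerrofluxError(f"block {self.name!r}: duplicate sample IDs")
        if self.data.columns.has_duplicates:
            raise FerrofluxError(f"block {self.name!r}: duplicate feature IDs")
        if self.kind == "counts":
            vals = self.data.to_numpy()
            if (vals < 0).any():
                raise FerrofluxError(f"block {self.name!r}: negative counts")
            if not np.allclose(vals, np.round(vals)):
                raise FerrofluxError(f"block {self.name!r}: non-integer counts")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, kind: str | None = None) -> "OmicsBlock":
        return OmicsBlock(self.name, data, self.kind if kind is None else kind)


@dataclass
class CohortTable:
    """Per-sample phenotype/covariate records.

    ``table`` is indexed by sample ID and holds the response column plus any
    covariates (continuous, binary, or categorical stored as strings).
    """

    table: pd.DataFrame
    response: str
    covariates: list[str] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.response not in self.table.columns:
            raise FerrofluxError(f"response column {self.response!r} missing")
        missing = [c for c in self.covariates if c not in self.table.columns]
        if missing:
            raise FerrofluxError(f"covariate columns missing: {missing}")
        if self.table.index.has_duplicates:
            raise FerrofluxError("duplicate sample IDs in cohort table")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def response_values(self) -> np.ndarray:
        return self.table[self.response].to_numpy(dtype=float)

    def covariate_frame(self) -> pd.DataFrame:
        return self.table[self.covariates]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative sample-by-sample distance matrix."""

    sample_ids: pd.Index
    values: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.values, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise FerrofluxError("distance matrix must be square")
        if D.shape[0] != len(self.sample_ids):
            raise FerrofluxError("distance matrix / sample ID length mismatch")
        if not np.allclose(D, D.T, atol=1e-12):
            raise FerrofluxError("distance matrix must be symmetric")
        if np.abs(np.diag(D)).max(initial=0.0) > 1e-12:
            raise FerrofluxError("distance matrix diagonal must be zero")
        self.values = D

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def warn(message: str) -> None:
    warnings.warn(message, UserWarning, stacklevel=3)
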