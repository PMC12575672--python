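"""Tabular containers and delimited-text I/O for connectome features.

Feature tables hold one row per subject and one column per connectome edge
(the strict upper triangle of a symmetric node-by-node matrix); phenotype
tables hold one or more named target columns, optionally tagged as
trait-like or state-like.  Everything round-trips through plain TSV/CSV
with a header row and a subject-id first column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "PhenotypeTable",
    "FormatError",
    "vectorize_symmetric",
    "devectorize",
    "edge_labels_for_nodes",
    "read_feature_table",
    "write_feature_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_connectome_matrix",
    "filter_outliers",
    "align",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("trait", "state", "unspecified")


class FormatError(ValueError):
    """Raised when an input table violates the expected format."""


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class FeatureTable:
    """Subjects x edges feature matrix with aligned identifiers."""

    subject_ids: np.ndarray
    edge_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("feature values must be a 2-d matrix")
        if len(self.subject_ids) != self.values.shape[0]:
            raise FormatError("row count does not match number of subject ids")
        if len(self.edge_labels) != self.values.shape[1]:
            raise FormatError("column count does not match number of edge labels")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise FormatError("subject ids must be unique")
        if not np.isfinite(self.values).all():
            raise FormatError("feature table contains missing/non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.edge_labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass
class PhenotypeTable:
    """Named target columns per subject with trait/state category tags."""

    subject_ids: np.ndarray
    data: pd.DataFrame
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if len(self.subject_ids) != len(self.data):
            raise FormatError("row count does not match number of subject ids")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise FormatError("subject ids must be unique")
        for col, cat in self.categories.items():
            if cat not in CATEGORIES:
                raise FormatError(f"unknown category {cat!r} for column {col!r}")
        for col in self.data.columns:
            self.categories.setdefault(col, "unspecified")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


def edge_labels_for_nodes(node_labels) -> list[str]:
    """Labels of the strict upper triangle, row-major: ``"a-b"`` per pair."""
    node_labels = list(node_labels)
    iu, ju = np.triu_indices(len(node_labels), k=1)
    return [f"{node_labels[i]}-{node_labels[j]}" for i, j in zip(iu, ju)]


def vectorize_symmetric(
    matrix: np.ndarray, node_labels=None, rtol: float = 1e-8
) -> tuple[np.ndarray, list[str]]:
    """Strict upper triangle of a symmetric matrix, row-major.

    Returns the edge vector of length n(n-1)/2 and its labels.  Asymmetry
    beyond ``rtol`` (relative to the matrix scale) raises a
    :class:`FormatError` naming the worst entry.
    """
    matrix = np.asarray(matrix, float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise FormatError(f"matrix must be square, got shape {matrix.shape}")
    n = matrix.shape[0]
    asym = np.abs(matrix - matrix.T)
    scale = max(np.abs(matrix).max(), 1.0)
    if asym.max() > rtol * scale:
        i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
        raise FormatError(
            f"matrix is not symmetric: |M[{i},{j}] - M[{j},{i}]| = {asym[i, j]:g} "
            f"exceeds tolerance {rtol * scale:g}"
        )
    if node_labels is None:
        node_labels = [f"n{k + 1:03d}" for k in range(n)]
    iu, ju = np.triu_indices(n, k=1)
    return matrix[iu, ju].copy(), edge_labels_for_nodes(node_labels)


def devectorize(vector: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric matrix (zero diagonal) from an edge vector."""
    vector = np.asarray(vector, float)
    m = len(vector)
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise FormatError(f"vector length {m} is not n(n-1)/2 for integer n")
    out = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    out[iu, ju] = vector
    out[ju, iu] = vector
    return out


def read_connectome_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a square delimited matrix with node labels as header row/column."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"connectome matrix must be square, got {df.shape}")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_feature_table(table: FeatureTable, path) -> None:
    # %.17g keeps the round-trip bit-exact
    table.to_dataframe().to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if df.shape[1] < 2:
        raise FormatError("feature table needs a subject-id column and >= 1 edge")
    ids = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise FormatError(f"missing values in feature table {path}")
    return FeatureTable(ids, [str(c) for c in df.columns[1:]], values)


def write_phenotype_table(table: PhenotypeTable, path) -> None:
    df = table.data.copy()
    df.insert(0, "subject_id", table.subject_ids)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")
    cats = pd.DataFrame(
        {"column": table.columns, "category": [table.categories[c] for c in table.columns]}
    )
    cats.to_csv(f"{path}.categories", sep="\t", index=False)


def read_phenotype_table(path, categories: dict[str, str] | None = None) -> PhenotypeTable:
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    ids = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
    data = df.iloc[:, 1:]
    if categories is None:
        import os

        sidecar = f"{path}.categories"
        if os.path.exists(sidecar):
            cat = pd.read_csv(sidecar, sep="\t")
            categories = dict(zip(cat["column"].astype(str), cat["category"]))
        else:
            categories = {}
    return PhenotypeTable(ids, data.reset_index(drop=True), dict(categories))


def filter_outliers(y: np.ndarray, k: float = 3.0) -> tuple[np.ndarray, dict]:
    """Indices of subjects within k standard deviations of the mean.

    Mean and standard deviation are computed once on the full vector.  This
    filter is a supplementary variant and is never applied by default; when
    used it runs once, before any discovery/replication splitting.  A
    zero-variance target keeps everyone and warns.
    """
    y = np.asarray(y, float)
    if len(y) < 3:
        raise ValueError("need at least 3 values to screen for outliers")
    if k <= 0:
        raise ValueError("k must be positive")
    sd = y.std(ddof=1)
    if sd == 0.0:
        warnings.warn("target has zero variance; no outliers removed", stacklevel=2)
        kept = np.arange(len(y))
        return kept, {"n_total": len(y), "n_removed": 0, "k": k}
    z = np.abs(y - y.mean()) / sd
    kept = np.flatnonzero(z <= k)
    report = {
        "n_total": len(y),
        "n_removed": int(len(y) - len(kept)),
        "k": k,
        "removed_indices": np.flatnonzero(z > k).tolist(),
    }
    return kept, report


def align(
    features: FeatureTable, phenotypes: PhenotypeTable, target: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inner-join features and one phenotype column, preserving feature order.

    Subjects with a missing value in ``target`` are dropped (logged).
    Returns ``(X, y, subject_ids)``.
    """
    if target not in phenotypes.columns:
        raise KeyError(f"unknown phenotype column {target!r}")
    pheno = pd.Series(
        phenotypes.data[target].to_numpy(), index=phenotypes.subject_ids
    )
    mask = np.array([sid in pheno.index for sid in features.subject_ids])
    y = np.array(
        [pheno[sid] for sid in features.subject_ids[mask]], dtype=float
    )
    finite = np.isfinite(y)
    if (~finite).any():
        logger.info(
            "dropping %d subjects with missing %r", int((~finite).sum()), target
        )
    keep = np.flatnonzero(mask)[finite]
    y = y[finite]
    if len(np.unique(y)) < 2:
        raise FormatError(f"target {target!r} has fewer than 2 distinct values")
    return features.values[keep], y, features.subject_ids[keep]
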