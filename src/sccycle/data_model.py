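"""Core dataset container and I/O for single-cell circadian time series.

The universal input to every downstream module is an
:class:`ExpressionDataset`: a genes x cells matrix of non-negative
normalized expression values together with per-cell metadata (collection
timepoint in hours, cluster / cell-type label, condition label).

Two on-disk dialects are supported:

``mtx+tsv``
    A MatrixMarket sparse matrix stored cells x genes (the community
    convention for single-cell exports; it is transposed on load), a gene
    sidecar ``<matrix>.genes.tsv`` (one gene id per line) and a metadata
    TSV with columns ``cell_id``, ``timepoint``, ``cluster``,
    ``condition``.

``csv``
    A dense CSV with genes as rows and cells as columns (gene ids in the
    first column, cell ids in the header) plus the same metadata TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import (
    EmptySelectionError,
    IdentityMismatchError,
    UnknownLabelError,
    ValidationError,
)

METADATA_COLUMNS = ("cell_id", "timepoint", "cluster", "condition")


@dataclass
class ExpressionDataset:
    """Genes x cells expression matrix with per-cell metadata.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_cells)`` array of finite, non-negative
        normalized expression values.
    gene_ids, cell_ids
        Unique identifiers for rows and columns respectively.
    timepoints
        Per-cell collection time in hours (absolute, not folded into the
        period; detectors fold into the period themselves).
    clusters, condition
        Per-cell cluster / cell-type and condition labels.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    timepoints: np.ndarray
    clusters: np.ndarray
    condition: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.clusters = np.asarray(self.clusters, dtype=object)
        self.condition = np.asarray(self.condition, dtype=object)
        self.validate()

    def validate(self) -> None:
        g, c = self.values.shape
        if len(self.gene_ids) != g:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {g} matrix rows"
            )
        for name, arr in (
            ("cell_ids", self.cell_ids),
            ("timepoints", self.timepoints),
            ("clusters", self.clusters),
            ("condition", self.condition),
        ):
            if len(arr) != c:
                raise ValidationError(f"{name} has {len(arr)} entries for {c} cells")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != c:
            raise ValidationError("duplicate cell ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be >= 0")
        if not np.all(np.isfinite(self.timepoints)) or np.any(self.timepoints < 0):
            raise ValidationError("timepoints must be finite and >= 0")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def distinct_timepoints(self) -> np.ndarray:
        return np.unique(self.timepoints)

    def cluster_labels(self) -> list:
        return sorted(set(self.clusters.tolist()), key=str)

    def take_cells(self, index: np.ndarray) -> "ExpressionDataset":
        """Return a copy restricted to the cells at ``index`` (in that order)."""
        index = np.asarray(index)
        return ExpressionDataset(
            values=self.values[:, index].copy(),
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in index],
            timepoints=self.timepoints[index].copy(),
            clusters=self.clusters[index].copy(),
            condition=self.condition[index].copy(),
        )

    def copy(self) -> "ExpressionDataset":
        return self.take_cells(np.arange(self.n_cells))


@dataclass
class TimepointGrouping:
    """Distinct timepoints and, per timepoint, the member cell indices.

    ``timepoints`` is strictly increasing and ``groups`` partitions the
    full cell index set.
    """

    timepoints: np.ndarray
    groups: list[np.ndarray] = field(repr=False)

    @classmethod
    def from_times(cls, times: Sequence[float]) -> "TimepointGrouping":
        times = np.asarray(times, dtype=float)
        uniq = np.unique(times)
        groups = [np.flatnonzero(times == u) for u in uniq]
        return cls(timepoints=uniq, groups=groups)

    @classmethod
    def from_dataset(cls, ds: ExpressionDataset) -> "TimepointGrouping":
        return cls.from_times(ds.timepoints)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(g) for g in self.groups])


class SubsetResult(NamedTuple):
    dataset: ExpressionDataset
    flagged_timepoints: list[float]


def _genes_sidecar(matrix_path: Path) -> Path:
    return matrix_path.with_suffix(matrix_path.suffix + ".genes.tsv")


def load_dataset(
    matrix_path: str | Path,
    metadata_path: str | Path,
    dialect: str = "mtx+tsv",
) -> ExpressionDataset:
    """Read an :class:`ExpressionDataset` from disk.

    Cells are joined to metadata by ``cell_id`` (order-insensitive) and
    reordered to the metadata order.
    """
    if dialect not in ("mtx+tsv", "csv"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    matrix_path = Path(matrix_path)
    metadata_path = Path(metadata_path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"cell_id": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValidationError(f"metadata missing columns {missing_cols}")

    if dialect == "mtx+tsv":
        mat = scipy.io.mmread(matrix_path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float).T  # disk is cells x genes
        gene_ids = _genes_sidecar(matrix_path).read_text().split()
        cells_path = matrix_path.with_suffix(matrix_path.suffix + ".cells.tsv")
        cell_ids = cells_path.read_text().split()
    elif dialect == "csv":
        frame = pd.read_csv(matrix_path, index_col=0, float_precision="round_trip")
        values = frame.to_numpy(dtype=float)
        gene_ids = [str(g) for g in frame.index]
        cell_ids = [str(c) for c in frame.columns]
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")

    if len(cell_ids) != len(set(cell_ids)):
        raise IdentityMismatchError("duplicate cell ids in matrix")
    meta_ids = meta["cell_id"].tolist()
    if len(meta_ids) != len(set(meta_ids)):
        raise IdentityMismatchError("duplicate cell ids in metadata")
    if set(meta_ids) != set(cell_ids):
        only_meta = sorted(set(meta_ids) - set(cell_ids))[:5]
        only_mat = sorted(set(cell_ids) - set(meta_ids))[:5]
        raise IdentityMismatchError(
            f"cell ids differ between matrix and metadata "
            f"(metadata-only: {only_meta}, matrix-only: {only_mat})"
        )
    order = [cell_ids.index(cid) for cid in meta_ids]
    return ExpressionDataset(
        values=values[:, order],
        gene_ids=gene_ids,
        cell_ids=meta_ids,
        timepoints=meta["timepoint"].to_numpy(dtype=float),
        clusters=meta["cluster"].to_numpy(dtype=object),
        condition=meta["condition"].to_numpy(dtype=object),
    )


def write_dataset(
    ds: ExpressionDataset,
    matrix_path: str | Path,
    metadata_path: str | Path,
    dialect: str = "mtx+tsv",
) -> None:
    """Write a dataset in the named dialect (inverse of :func:`load_dataset`)."""
    matrix_path = Path(matrix_path)
    metadata_path = Path(metadata_path)
    if dialect == "mtx+tsv":
        sparse = scipy.sparse.coo_matrix(ds.values.T)  # disk is cells x genes
        scipy.io.mmwrite(str(matrix_path), sparse)
        _genes_sidecar(matrix_path).write_text("\n".join(ds.gene_ids) + "\n")
        cells_path = matrix_path.with_suffix(matrix_path.suffix + ".cells.tsv")
        cells_path.write_text("\n".join(ds.cell_ids) + "\n")
    elif dialect == "csv":
        frame = pd.DataFrame(ds.values, index=ds.gene_ids, columns=ds.cell_ids)
        frame.to_csv(matrix_path)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    meta = pd.DataFrame(
        {
            "cell_id": ds.cell_ids,
            "timepoint": ds.timepoints,
            "cluster": ds.clusters,
            "condition": ds.condition,
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def subset(
    ds: ExpressionDataset,
    cluster=None,
    condition=None,
    min_cells_per_timepoint: int = 1,
) -> SubsetResult:
    """Restrict a dataset to one cluster and/or condition.

    Returns the filtered dataset together with the list of timepoints
    that retain fewer than ``min_cells_per_timepoint`` cells; the caller
    decides whether to drop those timepoints or treat them as an error.
    The gene set is never changed.
    """
    mask = np.ones(ds.n_cells, dtype=bool)
    if cluster is not None:
        if cluster not in set(ds.clusters.tolist()):
            raise UnknownLabelError(f"unknown cluster {cluster!r}")
        mask &= ds.clusters == cluster
    if condition is not None:
        if condition not in set(ds.condition.tolist()):
            raise UnknownLabelError(f"unknown condition {condition!r}")
        mask &= ds.condition == condition
    index = np.flatnonzero(mask)
    if index.size == 0:
        raise EmptySelectionError("subset removed every cell")
    sub = ds.take_cells(index)
    grouping = TimepointGrouping.from_dataset(sub)
    flagged = [
        float(t)
        for t, g in zip(grouping.timepoints, grouping.groups)
        if len(g) < min_cells_per_timepoint
    ]
    return SubsetResult(dataset=sub, flagged_timepoints=flagged)
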