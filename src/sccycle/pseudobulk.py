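"""Pseudo-bulk aggregation: per-cluster, per-timepoint mean expression.

The pseudo-bulk profile of gene ``g`` at time ``t`` is the arithmetic
mean of the normalized values over the cluster's cells collected at
``t``.  Summed raw-count pseudobulk is a different convention and is out
of scope; values are averaged as given.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset, TimepointGrouping, subset
from .errors import MissingTimepointError


@dataclass
class PseudobulkProfile:
    """Genes x timepoints matrix of within-cluster per-timepoint means."""

    values: np.ndarray
    timepoints: np.ndarray
    gene_ids: list[str]
    cluster: object
    n_cells_per_timepoint: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.timepoints
        )


def make_pseudobulk(ds: ExpressionDataset, cluster) -> PseudobulkProfile:
    """Average a cluster's cells within each timepoint (columns sorted by
    ascending time).

    Every distinct timepoint of the cluster must have at least one cell;
    callers wanting the stricter two-cells-per-timepoint rule apply it
    via :func:`sccycle.data_model.subset` first.
    """
    sub = subset(ds, cluster=cluster).dataset
    grouping = TimepointGrouping.from_dataset(sub)
    sizes = grouping.sizes
    if np.any(sizes < 1):  # unreachable after subset, kept as a guard
        missing = grouping.timepoints[sizes < 1].tolist()
        raise MissingTimepointError(f"timepoints without cells: {missing}")
    values = np.column_stack(
        [sub.values[:, g].mean(axis=1) for g in grouping.groups]
    )
    return PseudobulkProfile(
        values=values,
        timepoints=grouping.timepoints.copy(),
        gene_ids=list(sub.gene_ids),
        cluster=cluster,
        n_cells_per_timepoint=sizes,
    )
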