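"""Systematic single-timepoint contamination model and lambda sweeps.

A batch effect hitting one scRNA-seq collection elevates every cell of
that timepoint.  The model adds, for each targeted gene, ``lam`` times
the gene's grand mean over all of the cluster's cells (at all
timepoints) to every cell of the cluster at the target timepoint:

    X~(c, t*) = X(c, t*) + lam * <X>                   (lam >= 0)

Candidate "non-cycling" genes for contamination studies are selected as
those detectably expressed in at least half of the cluster's cells with
a cells-as-replicates harmonic-regression p-value above a threshold
(default 0.9).

Sweeps always contaminate from the pristine dataset: contamination is
not additive across rounds because the second round's grand mean would
include the first round's elevation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset, subset
from .detectors import detect_all
from .errors import ValidationError


@dataclass
class ContaminationSpec:
    """One contamination round: which cluster/timepoint/genes, how much."""

    target_timepoint: float
    lam: float
    cluster: object
    gene_set: list[str] | str = "all"

    def validate(self, ds: ExpressionDataset) -> None:
        if self.lam < 0:
            raise ValidationError("lam must be >= 0")
        sub = subset(ds, cluster=self.cluster).dataset
        times = set(np.round(sub.distinct_timepoints(), 9).tolist())
        if round(float(self.target_timepoint), 9) not in times:
            raise ValidationError(
                f"timepoint {self.target_timepoint} not present in cluster "
                f"{self.cluster!r}"
            )
        if self.gene_set != "all":
            unknown = set(self.gene_set) - set(ds.gene_ids)
            if unknown:
                raise ValidationError(f"unknown genes: {sorted(unknown)[:5]}")


def select_noncycling_genes(
    ds: ExpressionDataset,
    cluster,
    min_expressed_fraction: float = 0.5,
    p_threshold: float = 0.9,
    period: float = 24.0,
) -> list[str]:
    """Genes expressed in at least ``min_expressed_fraction`` of the
    cluster's cells whose cells-as-replicates harmonic-regression
    p-value exceeds ``p_threshold``."""
    sub = subset(ds, cluster=cluster).dataset
    expressed_frac = (sub.values > 0).mean(axis=1)
    results = detect_all(
        sub, "harmonic", mode="cells_as_replicates", period=period, compute_q=False
    )
    selected = [
        gid
        for gid, frac, res in zip(sub.gene_ids, expressed_frac, results)
        if frac >= min_expressed_fraction and res.p_value > p_threshold
    ]
    if not selected:
        warnings.warn("no genes pass the non-cycling selection", stacklevel=2)
    return selected


def contaminate(ds: ExpressionDataset, spec: ContaminationSpec) -> ExpressionDataset:
    """Return a contaminated copy of the dataset (the input is untouched).

    Exactly ``len(gene_set) * n_cells(cluster, target timepoint)``
    entries change; the per-gene offset is ``lam`` times the gene's mean
    over all of the cluster's cells at all timepoints.
    """
    spec.validate(ds)
    out = ds.copy()
    cluster_mask = ds.clusters == spec.cluster
    target_mask = cluster_mask & (
        np.round(ds.timepoints, 9) == round(float(spec.target_timepoint), 9)
    )
    genes = (
        np.arange(ds.n_genes)
        if spec.gene_set == "all"
        else np.array([ds.gene_ids.index(g) for g in spec.gene_set])
    )
    grand_mean = ds.values[np.ix_(genes, np.flatnonzero(cluster_mask))].mean(axis=1)
    cols = np.flatnonzero(target_mask)
    out.values[np.ix_(genes, cols)] += spec.lam * grand_mean[:, None]
    return out


def contamination_sweep(
    ds: ExpressionDataset,
    cluster,
    gene_set,
    lam_grid=None,
    timepoints="each",
    detector: str = "harmonic",
    mode: str = "cells_as_replicates",
    alpha: float = 0.05,
    period: float = 24.0,
    **detector_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contaminate each (timepoint, lambda) cell from the pristine data
    and record per-gene p-values and phases under the chosen detector.

    Returns ``(per_gene, summary)`` where ``per_gene`` has one row per
    (timepoint, lambda, gene) and ``summary`` counts genes with
    ``p < alpha`` per (timepoint, lambda).
    """
    if lam_grid is None:
        lam_grid = np.arange(0.0, 5.25, 0.25)
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0:
        raise ValidationError("empty lambda grid")
    sub_times = subset(ds, cluster=cluster).dataset.distinct_timepoints()
    targets = sub_times if timepoints == "each" else np.asarray(timepoints, dtype=float)
    if targets.size == 0:
        raise ValidationError("empty timepoint grid")

    rows = []
    for t_star in targets:
        for lam in lam_grid:
            spec = ContaminationSpec(
                target_timepoint=float(t_star),
                lam=float(lam),
                cluster=cluster,
                gene_set=gene_set,
            )
            contaminated = contaminate(ds, spec)
            work = subset(contaminated, cluster=cluster).dataset
            if gene_set != "all":
                keep = [work.gene_ids.index(g) for g in gene_set]
                work = ExpressionDataset(
                    values=work.values[keep],
                    gene_ids=[work.gene_ids[i] for i in keep],
                    cell_ids=work.cell_ids,
                    timepoints=work.timepoints,
                    clusters=work.clusters,
                    condition=work.condition,
                )
            results = detect_all(
                work, detector, mode=mode, period=period, compute_q=False,
                **detector_kwargs,
            )
            for r in results:
                rows.append(
                    {
                        "timepoint": float(t_star),
                        "lam": float(lam),
                        "gene_id": r.gene_id,
                        "p_value": r.p_value,
                        "phase": r.phase,
                    }
                )
    per_gene = pd.DataFrame(rows)
    summary = (
        per_gene.assign(detected=per_gene["p_value"] < alpha)
        .groupby(["timepoint", "lam"], as_index=False)["detected"]
        .sum()
        .rename(columns={"detected": "n_cyclers"})
    )
    return per_gene, summary
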