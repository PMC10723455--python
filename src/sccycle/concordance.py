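"""Subsample-concordance reliability framework and the subsample-overlap
harmonic-regression detector.

If a gene is genuinely cycling in a cell type it should still be
detected when only half of the cells at each timepoint are used.  The
framework therefore splits the cells of a cluster at random into two
"sub-experiments" (independently within each timepoint, so both halves
cover every timepoint), runs a detector on each half, and compares the
intersection of the two detected gene sets, N_cap, against the number
of cyclers detected with all cells, N_full.  The ratio N_cap / N_full
is the reliability measure; the union of the two half-detections is
typically far smaller than N_full, which is why N_full rather than the
Jaccard denominator is used (Jaccard is reported for completeness).

The same idea yields a detector: genes with harmonic-regression
p < alpha in *both* halves of a random split are unlikely to be
spurious, making the overlap set a fast, reliable alternative to more
expensive rank-based tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset, TimepointGrouping, subset
from .detectors import detect_all, results_to_frame
from .errors import SplitInfeasibleError

DEFAULT_ALPHA = 0.05


@dataclass
class HalfSplit:
    """Two disjoint cell-index sets covering every timepoint of a cluster."""

    sub1: np.ndarray
    sub2: np.ndarray
    seed: int
    cluster: object


@dataclass
class ConcordanceReport:
    """Concordance statistics for one (cluster, detector, threshold)."""

    n_full: int
    trials: list[tuple[int, int, int]]  # (N1, N2, N_cap)
    ratio_mean: float | None
    ratio_sd: float | None
    jaccard_mean: float | None
    detector: str
    mode: str
    alpha: float
    adjusted: bool
    cluster: object
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": self.cluster,
                "detector": self.detector,
                "mode": self.mode,
                "trial": i,
                "n1": n1,
                "n2": n2,
                "n_intersection": ncap,
                "n_full": self.n_full,
            }
            for i, (n1, n2, ncap) in enumerate(self.trials)
        ]
        frame = pd.DataFrame(rows)
        frame.attrs["ratio_mean"] = self.ratio_mean
        frame.attrs["ratio_sd"] = self.ratio_sd
        return frame


def _trial_seeds(seed: int, n: int) -> list[int]:
    """Per-trial seeds derived from the master seed by a counter."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def split_half(ds: ExpressionDataset, cluster, seed: int) -> HalfSplit:
    """Random halving of a cluster's cells, independently per timepoint.

    Both halves contain every distinct timepoint; for odd counts the
    extra cell goes to sub-experiment 1 (fixed tie convention for
    determinism).  Indices refer to the cells of the cluster-subset
    dataset in its own order.
    """
    sub = subset(ds, cluster=cluster).dataset
    grouping = TimepointGrouping.from_dataset(sub)
    short = grouping.timepoints[grouping.sizes < 2].tolist()
    if short:
        raise SplitInfeasibleError(
            f"timepoints with fewer than 2 cells cannot be split: {short}"
        )
    rng = np.random.default_rng(seed)
    s1, s2 = [], []
    for g in grouping.groups:
        perm = rng.permutation(g)
        half = (len(g) + 1) // 2  # sub1 gets the extra cell
        s1.append(perm[:half])
        s2.append(perm[half:])
    return HalfSplit(
        sub1=np.sort(np.concatenate(s1)),
        sub2=np.sort(np.concatenate(s2)),
        seed=seed,
        cluster=cluster,
    )


def _detected(results, alpha: float, adjusted: bool) -> set[str]:
    if adjusted:
        return {r.gene_id for r in results if r.q_value is not None and r.q_value < alpha}
    return {r.gene_id for r in results if r.p_value < alpha}


def run_concordance(
    ds: ExpressionDataset,
    cluster,
    detector: str,
    mode: str = "cells_as_replicates",
    n_trials: int = 10,
    alpha: float = DEFAULT_ALPHA,
    adjusted: bool = False,
    seed: int = 0,
    period: float = 24.0,
    **detector_kwargs,
) -> ConcordanceReport:
    """Subsample-concordance analysis for one cluster and detector.

    Runs the detector on all cells (N_full), then for each of
    ``n_trials`` random half-splits on both halves separately (in
    pseudobulk mode the halves are averaged *after* splitting), and
    reports the per-trial intersection sizes plus the mean and standard
    deviation of N_cap / N_full across trials.  The default threshold is
    the unadjusted p < alpha; BH-adjusted thresholding (q < alpha) is
    available behind the ``adjusted`` flag.
    """
    sub = subset(ds, cluster=cluster).dataset
    full_results = detect_all(
        sub, detector, mode=mode, cluster=cluster, period=period, **detector_kwargs
    )
    full_set = _detected(full_results, alpha, adjusted)
    n_full = len(full_set)

    trials: list[tuple[int, int, int]] = []
    jaccards: list[float] = []
    for trial_seed in _trial_seeds(seed, n_trials):
        split = split_half(sub, cluster, trial_seed)
        sets = []
        for half in (split.sub1, split.sub2):
            half_ds = sub.take_cells(half)
            res = detect_all(
                half_ds, detector, mode=mode, cluster=cluster, period=period,
                **detector_kwargs,
            )
            sets.append(_detected(res, alpha, adjusted))
        c1, c2 = sets
        cap = c1 & c2
        cup = c1 | c2
        trials.append((len(c1), len(c2), len(cap)))
        jaccards.append(len(cap) / len(cup) if cup else np.nan)

    flags = []
    if n_full == 0:
        ratio_mean = ratio_sd = None
        flags.append("n_full_zero")
    else:
        ratios = np.array([ncap / n_full for _, _, ncap in trials])
        ratio_mean = float(ratios.mean())
        ratio_sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
    jarr = np.asarray(jaccards, dtype=float)
    jaccard_mean = float(np.nanmean(jarr)) if np.any(np.isfinite(jarr)) else None
    return ConcordanceReport(
        n_full=n_full,
        trials=trials,
        ratio_mean=ratio_mean,
        ratio_sd=ratio_sd,
        jaccard_mean=jaccard_mean,
        detector=detector,
        mode=mode,
        alpha=alpha,
        adjusted=adjusted,
        cluster=cluster,
        flags=flags,
    )


def subsample_hr_detect(
    ds: ExpressionDataset,
    cluster,
    alpha: float = DEFAULT_ALPHA,
    n_splits: int = 1,
    seed: int = 0,
    period: float = 24.0,
) -> tuple[set[str], pd.DataFrame]:
    """Subsample-overlap harmonic-regression detector.

    With ``n_splits = 1`` (the primary procedure) the detected set is
    the genes with harmonic-regression p < alpha in *both* halves of one
    seeded random split.  With ``n_splits > 1`` a gene must satisfy that
    criterion in a strict majority of splits (an extension, flagged in
    the evidence table's ``rule`` attribute).

    Returns the detected gene set and a per-gene evidence table with
    both halves' p-values for every split.
    """
    sub = subset(ds, cluster=cluster).dataset
    votes = {g: 0 for g in sub.gene_ids}
    frames = []
    for k, trial_seed in enumerate(_trial_seeds(seed, n_splits)):
        split = split_half(sub, cluster, trial_seed)
        halves = []
        for half in (split.sub1, split.sub2):
            res = detect_all(
                sub.take_cells(half), "harmonic", mode="cells_as_replicates",
                period=period,
            )
            halves.append({r.gene_id: r.p_value for r in res})
        p1, p2 = halves
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": sub.gene_ids,
                    "split": k,
                    "p_half1": [p1[g] for g in sub.gene_ids],
                    "p_half2": [p2[g] for g in sub.gene_ids],
                }
            )
        )
        for g in sub.gene_ids:
            if p1[g] < alpha and p2[g] < alpha:
                votes[g] += 1
    needed = 1 if n_splits == 1 else n_splits // 2 + 1
    detected = {g for g, v in votes.items() if v >= needed}
    evidence = pd.concat(frames, ignore_index=True)
    evidence.attrs["rule"] = (
        "both_halves" if n_splits == 1 else f"majority_of_{n_splits}_splits"
    )
    return detected, evidence
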