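"""Scoring utilities: ROC/AUC against reference gene lists, type-I/power
grids over a simulated ensemble, upset-style overlap tables, and runtime
trend-curve fitting (linear / quadratic / exponential)."""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import DegenerateInputError, ValidationError


@dataclass
class RocResult:
    """ROC sweep over p-value thresholds plus the trapezoid AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class GridPerformance:
    """Per (mu0, dispersion) detection rates at a stated alpha."""

    table: pd.DataFrame  # columns: mu0, dispersion, tpr, fpr, n_cycling, n_noncycling
    alpha: float


def roc_auc(p_values: dict | pd.Series, reference_positive: set) -> RocResult:
    """ROC for classifying genes as reference positives by p-value.

    Smaller p-values score as more positive; tied p-values share a
    threshold, and the trapezoid AUC equals the rank-based
    (Mann-Whitney) AUC with ties counted 1/2.
    """
    series = pd.Series(p_values, dtype=float)
    labels = series.index.isin(set(reference_positive)).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("need at least one positive and one negative gene")
    # score ascending in evidence: smaller p => larger score
    fpr, tpr, thr = _sk_roc_curve(labels, -series.to_numpy())
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        thresholds=-thr, tpr=tpr, fpr=fpr, auc=auc, n_pos=n_pos, n_neg=n_neg
    )


def grid_performance(
    results: pd.DataFrame, truth: pd.DataFrame, alpha: float = 0.05
) -> GridPerformance:
    """TPR / FPR per (mu0, dispersion) grid cell at ``p < alpha``.

    ``results`` needs columns ``gene_id`` and ``p_value``; ``truth``
    needs ``gene_id``, ``label``, ``mu0``, ``dispersion``.  Every series
    in the truth table must be covered.
    """
    merged = truth.merge(results[["gene_id", "p_value"]], on="gene_id", how="left")
    if merged["p_value"].isna().any():
        missing = merged.loc[merged["p_value"].isna(), "gene_id"].tolist()[:5]
        raise ValidationError(f"results missing for series: {missing}")
    merged["detected"] = merged["p_value"] < alpha
    rows = []
    for (mu0, disp), cell in merged.groupby(["mu0", "dispersion"]):
        cyc = cell[cell["label"] == "cycling"]
        non = cell[cell["label"] == "noncycling"]
        rows.append(
            {
                "mu0": mu0,
                "dispersion": disp,
                "tpr": cyc["detected"].mean() if len(cyc) else np.nan,
                "fpr": non["detected"].mean() if len(non) else np.nan,
                "n_cycling": len(cyc),
                "n_noncycling": len(non),
            }
        )
    return GridPerformance(table=pd.DataFrame(rows), alpha=alpha)


_TREND_MODELS = ("linear", "quadratic", "exponential")


def runtime_trend_fit(sizes, times) -> dict:
    """Classify a runtime curve as linear, quadratic, or exponential.

    Fits ``t = a*m + b``, ``t = a*m^2 + b`` and ``log t = a*m + b``.
    Runtime noise is multiplicative, so the polynomial models are fit by
    least squares on the relative scale (weights ``1/t``) and all models
    are compared by relative RMS error; the arg-min model wins.
    """
    sizes = np.asarray(sizes, dtype=float)
    times = np.asarray(times, dtype=float)
    if sizes.size < 4:
        raise ValidationError("need at least 4 size/time pairs")
    if np.any(np.diff(sizes) <= 0):
        raise ValidationError("sizes must be strictly increasing")
    if np.any(times <= 0):
        raise ValidationError("times must be > 0")
    fits = {}
    for model in _TREND_MODELS:
        if model == "exponential":
            X = np.column_stack([sizes, np.ones_like(sizes)])
            coef, *_ = np.linalg.lstsq(X, np.log(times), rcond=None)
            pred = np.exp(X @ coef)
        else:
            term = sizes if model == "linear" else sizes**2
            X = np.column_stack([term, np.ones_like(sizes)])
            coef, *_ = np.linalg.lstsq(X / times[:, None], np.ones_like(times), rcond=None)
            pred = X @ coef
        fits[model] = {
            "coef": [float(c) for c in coef],
            "rel_rmse": float(np.sqrt(np.mean(((pred - times) / times) ** 2))),
        }
    best = min(_TREND_MODELS, key=lambda m: fits[m]["rel_rmse"])
    return {"best_model": best, "fits": fits}


def benchmark_runtime(
    detect_fn, sizes, make_input, repeats: int = 1
) -> pd.DataFrame:
    """Wall-clock a detector across a grid of observation counts.

    ``make_input(m)`` must return ``(y, t)`` for a problem of size
    ``m``; timings are informative only and never part of any
    acceptance surface.
    """
    rows = []
    for m in sizes:
        y, t = make_input(int(m))
        best = np.inf
        for _ in range(max(1, repeats)):
            start = time.perf_counter()
            detect_fn(y, t)
            best = min(best, time.perf_counter() - start)
        rows.append({"size": int(m), "seconds": best})
    return pd.DataFrame(rows)


def overlap_table(result_sets: dict) -> tuple[pd.DataFrame, pd.Series]:
    """Boolean membership matrix plus per-intersection counts
    (upset-style bookkeeping over named gene sets)."""
    if len(result_sets) < 2:
        raise ValidationError("need at least 2 named sets")
    names = list(result_sets)
    universe = sorted(set().union(*result_sets.values()))
    membership = pd.DataFrame(
        {name: [g in result_sets[name] for g in universe] for name in names},
        index=universe,
    )
    counts = membership.groupby(names).size()
    return membership, counts
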