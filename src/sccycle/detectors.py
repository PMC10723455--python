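"""Cycling detectors for circadian time series with uneven replicates.

Three detectors are provided, all operating on ``(value, timepoint)``
pairs with arbitrary numbers of replicates per timepoint:

harmonic regression
    Least-squares fit of ``M + b1*cos(wt) + b2*sin(wt)`` with
    ``w = 2*pi/period``; significance from the F-test of
    ``(b1, b2) = (0, 0)`` with ``(2, n-3)`` degrees of freedom.

JTK-style template test
    The observed expression is compared against cosine templates of
    different phases (and optionally asymmetric rise/fall shapes)
    discretized at the distinct fold-times.  For each template the cells
    are grouped by the template's rank ordering of timepoints and a
    two-sided Jonckheere-Terpstra (JT) p-value is computed; the reported
    p-value is the minimum over templates times the number of distinct
    templates (Bonferroni), capped at 1.

RAIN-style umbrella test
    A JT-based test for a rise-then-fall shape with a flexible peak
    position: the statistic is the JT trend statistic of the rising
    segment plus that of the reversed falling segment, with the null
    taken as the convolution of the two segment nulls (the
    "independence" construction, appropriate for cross-sectional
    cells).  The reported p-value is Bonferroni-corrected over all
    candidate peak (and interior trough) positions.

The JT null is exact (dynamic-programming convolution of Mann-Whitney
distributions) for tie-free data up to a size threshold, a tie-corrected
normal approximation otherwise, or a seeded Monte-Carlo permutation null
on request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionDataset, subset as _subset
from .errors import ValidationError

_TINY_P = 5e-324  # smallest subnormal double; degenerate-fit placeholder
_FOLD_DECIMALS = 9


# ---------------------------------------------------------------------------
# result containers


@dataclass
class CyclingResult:
    """Per-gene cycling detection record."""

    gene_id: str
    p_value: float
    method: str
    n_obs: int
    q_value: float | None = None
    phase: float | None = None
    amplitude: float | None = None
    mesor: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class HarmonicFit:
    """Cosinor fit: ``M + A*cos(2*pi*(t - phase)/period)``."""

    mesor: float
    beta_cos: float
    beta_sin: float
    amplitude: float
    phase: float
    F_statistic: float
    df: tuple[int, int]
    period: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        w = 2.0 * np.pi / self.period
        return self.mesor + self.beta_cos * np.cos(w * t) + self.beta_sin * np.sin(w * t)


@dataclass
class JTNull:
    """Null distribution of the Jonckheere-Terpstra statistic.

    ``support``/``pmf`` are populated in ``exact`` and ``monte_carlo``
    modes; the ``normal_approx`` mode carries only ``mean`` and ``var``.
    """

    mean: float
    var: float
    mode: Literal["exact", "normal_approx", "monte_carlo"]
    support: np.ndarray | None = None
    pmf: np.ndarray | None = None

    def sf(self, x: float) -> float:
        """P(JT >= x)."""
        if self.pmf is not None:
            return float(self.pmf[self.support >= x - 1e-9].sum())
        sd = math.sqrt(self.var) if self.var > 0 else 0.0
        if sd == 0.0:
            return 1.0 if x <= self.mean + 1e-9 else 0.0
        return float(scipy.stats.norm.sf((x - 0.5 - self.mean) / sd))

    def cdf(self, x: float) -> float:
        """P(JT <= x)."""
        if self.pmf is not None:
            return float(self.pmf[self.support <= x + 1e-9].sum())
        sd = math.sqrt(self.var) if self.var > 0 else 0.0
        if sd == 0.0:
            return 1.0 if x >= self.mean - 1e-9 else 0.0
        return float(scipy.stats.norm.cdf((x + 0.5 - self.mean) / sd))

    def two_sided_p(self, x: float) -> float:
        return min(1.0, 2.0 * min(self.sf(x), self.cdf(x)))


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra statistic and nulls


def jt_statistic(groups: Sequence[np.ndarray]) -> float:
    """JT trend statistic for an ordered list of value vectors.

    ``JT = sum_{i<j} #{(a in group_i, b in group_j): b > a}``, with tied
    cross-group pairs contributing 1/2.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("jt_statistic needs at least 2 groups")
    for g in groups:
        if g.size == 0:
            raise ValidationError("empty group")
    total = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a = groups[i][:, None]
            b = groups[j][None, :]
            total += float((b > a).sum()) + 0.5 * float((b == a).sum())
    return total


@lru_cache(maxsize=4096)
def _mw_counts(m: int, n: int) -> tuple[float, ...]:
    """Arrangement counts of the Mann-Whitney statistic between ``m`` old
    and ``n`` new tie-free observations (coefficients of the Gaussian
    binomial ``[m+n choose n]_q``)."""
    if m == 0 or n == 0:
        return (1.0,)
    a = _mw_counts(m, n - 1)  # [m+n-1 choose n-1]_q
    b = _mw_counts(m - 1, n)  # q^n * [m+n-1 choose n]_q
    out = np.zeros(m * n + 1)
    out[: len(a)] += a
    out[n : n + len(b)] += b
    return tuple(out)


@lru_cache(maxsize=4096)
def _exact_jt_pmf(sizes: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Exact tie-free JT null pmf by sequential Mann-Whitney convolution.

    Pooling groups left to right, the increment contributed by merging
    the next group into the pooled block is an independent Mann-Whitney
    statistic; the JT null is the convolution of those distributions.
    """
    pmf = np.array([1.0])
    cum = sizes[0]
    for ni in sizes[1:]:
        counts = np.asarray(_mw_counts(cum, ni))
        pmf = np.convolve(pmf, counts / counts.sum())
        cum += ni
    support = np.arange(pmf.size, dtype=float)
    return support, pmf


def _jt_moments(
    sizes: np.ndarray, tie_counts: np.ndarray | None = None
) -> tuple[float, float]:
    """Mean and (tie-corrected) variance of the JT null.

    ``tie_counts`` are the pooled tie-group sizes of the observations;
    omitting them assumes tie-free data.
    """
    n = np.asarray(sizes, dtype=float)
    N = n.sum()
    mean = (N * N - (n * n).sum()) / 4.0
    if tie_counts is None:
        tie_counts = np.ones(int(N))
    t = np.asarray(tie_counts, dtype=float)
    a = (
        N * (N - 1) * (2 * N + 5)
        - (n * (n - 1) * (2 * n + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    ) / 72.0
    b = 0.0
    if N > 2:
        b = ((n * (n - 1) * (n - 2)).sum() * (t * (t - 1) * (t - 2)).sum()) / (
            36.0 * N * (N - 1) * (N - 2)
        )
    c = ((n * (n - 1)).sum() * (t * (t - 1)).sum()) / (8.0 * N * (N - 1))
    return float(mean), float(max(a + b + c, 0.0))


def _mc_jt_sample(
    values: np.ndarray, sizes: Sequence[int], n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Seeded Monte-Carlo permutation sample of the JT statistic."""
    values = np.asarray(values, dtype=float)
    N = values.size
    sizes = np.asarray(sizes)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    ranks = np.repeat(np.arange(len(sizes)), sizes)
    mask = ranks[:, None] < ranks[None, :]
    chunk = max(1, int(2e6 / (N * N)))
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        order = rng.random((b, N)).argsort(axis=1)
        perm = values[order]
        gt = perm[:, None, :] > perm[:, :, None]
        eq = perm[:, None, :] == perm[:, :, None]
        contrib = (gt + 0.5 * eq) * mask
        out[done : done + b] = contrib.sum(axis=(1, 2))
        done += b
    return out


def jt_null(
    group_sizes: Sequence[int],
    mode: str = "auto",
    values: np.ndarray | None = None,
    exact_threshold: int = 50,
    n_perm: int = 100_000,
    seed: int | None = None,
) -> JTNull:
    """Null distribution of the JT statistic for the given group sizes.

    ``mode='auto'`` selects the exact DP-convolution pmf for tie-free
    data with ``N <= exact_threshold`` and the tie-corrected normal
    approximation otherwise.  ``mode='monte_carlo'`` draws a seeded
    permutation null and requires ``values``.
    """
    sizes = tuple(int(s) for s in group_sizes)
    if len(sizes) < 2 or any(s < 1 for s in sizes):
        raise ValidationError("need >= 2 non-empty groups")
    N = sum(sizes)
    has_ties = False
    tie_counts = None
    if values is not None:
        values = np.asarray(values, dtype=float)
        if values.size != N:
            raise ValidationError("values length must equal sum of group sizes")
        _, tie_counts = np.unique(values, return_counts=True)
        has_ties = bool((tie_counts > 1).any())

    if mode == "auto":
        mode = "exact" if (not has_ties and N <= exact_threshold) else "normal_approx"

    if mode == "exact":
        if has_ties:
            raise ValidationError("exact JT null is only valid for tie-free data")
        support, pmf = _exact_jt_pmf(sizes)
        mean = float((support * pmf).sum())
        var = float(((support - mean) ** 2 * pmf).sum())
        return JTNull(mean=mean, var=var, mode="exact", support=support, pmf=pmf)
    if mode == "normal_approx":
        mean, var = _jt_moments(np.asarray(sizes), tie_counts)
        return JTNull(mean=mean, var=var, mode="normal_approx")
    if mode == "monte_carlo":
        if values is None:
            raise ValidationError("monte_carlo mode requires the observed values")
        rng = np.random.default_rng(seed)
        sample = _mc_jt_sample(values, sizes, n_perm, rng)
        support, counts = np.unique(sample, return_counts=True)
        pmf = counts / counts.sum()
        mean = float(sample.mean())
        var = float(sample.var())
        return JTNull(mean=mean, var=var, mode="monte_carlo", support=support, pmf=pmf)
    raise ValidationError(f"unknown jt_null mode {mode!r}")


# ---------------------------------------------------------------------------
# harmonic regression


def _check_design(t: np.ndarray, period: float) -> np.ndarray:
    folded = np.round(np.mod(t, period), _FOLD_DECIMALS)
    uniq = np.unique(folded)
    if t.size < 4:
        raise ValidationError("need at least 4 observations")
    if uniq.size < 3:
        raise ValidationError(
            "harmonic fit is rank-deficient with fewer than 3 distinct fold-times"
        )
    return folded


def _harmonic_batch(
    Y: np.ndarray, t: np.ndarray, period: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized cosinor fit of every row of ``Y`` against shared times.

    Returns ``(p, F, amplitude, phase, mesor, degenerate_mask)``.
    """
    t = np.asarray(t, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    _check_design(t, period)
    n = t.size
    w = 2.0 * np.pi / period
    X = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (3, G)
    resid = Y.T - X @ beta
    rss = (resid**2).sum(axis=0)
    tss = ((Y.T - Y.mean(axis=1)) ** 2).sum(axis=0)
    explained = np.clip(tss - rss, 0.0, None)
    df2 = n - 3
    scale = np.maximum(tss, 1.0)
    constant = tss <= 1e-24 * scale
    degenerate = (~constant) & (rss <= 1e-18 * scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (explained / 2.0) / (rss / df2)
    F = np.where(constant, 0.0, F)
    p = np.where(
        constant,
        1.0,
        np.where(degenerate, _TINY_P, scipy.stats.f.sf(np.where(degenerate, 0.0, F), 2, df2)),
    )
    amplitude = np.hypot(beta[1], beta[2])
    amplitude = np.where(constant, 0.0, amplitude)
    phase = np.mod(np.arctan2(beta[2], beta[1]) / w, period)
    phase = np.where(phase >= period - 1e-9, 0.0, phase)  # float-mod wrap guard
    phase = np.where(constant, 0.0, phase)
    mesor = beta[0]
    return p, F, amplitude, phase, mesor, degenerate


def harmonic_regression_test(
    y: np.ndarray,
    t: np.ndarray,
    period: float = 24.0,
    gene_id: str = "",
) -> tuple[CyclingResult, HarmonicFit]:
    """Cosinor / harmonic-regression cycling test for one gene.

    Fits ``M + b1*cos(wt) + b2*sin(wt)`` by least squares and tests
    ``(b1, b2) = (0, 0)`` with an F-test on ``(2, n-3)`` degrees of
    freedom.  The phase is the peak time of the fitted curve in
    ``[0, period)``.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.shape != t.shape:
        raise ValidationError("y and t must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValidationError("y must be finite")
    p, F, amp, phase, mesor, degen = _harmonic_batch(y[None, :], t, period)
    w = 2.0 * np.pi / period
    X = np.column_stack([np.ones(t.size), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fit = HarmonicFit(
        mesor=float(mesor[0]),
        beta_cos=float(beta[1]),
        beta_sin=float(beta[2]),
        amplitude=float(amp[0]),
        phase=float(phase[0]),
        F_statistic=float(F[0]),
        df=(2, t.size - 3),
        period=period,
    )
    flags = ["degenerate_fit"] if degen[0] else []
    result = CyclingResult(
        gene_id=gene_id,
        p_value=float(p[0]),
        method="harmonic",
        n_obs=int(t.size),
        phase=float(phase[0]),
        amplitude=float(amp[0]),
        mesor=float(mesor[0]),
        flags=flags,
    )
    return result, fit


# ---------------------------------------------------------------------------
# template machinery shared by the JTK-style and RAIN-style tests


def _fold_groups(t: np.ndarray, period: float) -> tuple[np.ndarray, list[np.ndarray]]:
    folded = _check_design(np.asarray(t, dtype=float), period)
    uniq = np.unique(folded)
    groups = [np.flatnonzero(folded == u) for u in uniq]
    return uniq, groups


def _block_tables(
    y: np.ndarray, groups: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cross-group comparison tables.

    ``gt[i, j]`` counts pairs ``(a in group i, b in group j)`` with
    ``y_b > y_a``; ``eq`` counts ties.  Any template ordering's JT
    statistic is a masked sum over these tables.
    """
    sizes = np.array([len(g) for g in groups])
    idx = np.concatenate(groups)
    ys = y[idx]
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    gt_cells = (ys[None, :] > ys[:, None]).astype(float)
    eq_cells = (ys[None, :] == ys[:, None]).astype(float)
    gt = np.add.reduceat(np.add.reduceat(gt_cells, starts, axis=0), starts, axis=1)
    eq = np.add.reduceat(np.add.reduceat(eq_cells, starts, axis=0), starts, axis=1)
    return gt, eq, sizes


def _masked_stat(gt: np.ndarray, eq: np.ndarray, mask: np.ndarray) -> float:
    return float(((gt + 0.5 * eq) * mask).sum())


def _waveform(u: np.ndarray, fall_frac: float) -> np.ndarray:
    """Asymmetric cosine peaking at phase 0.

    ``u`` is the fraction of the period elapsed since the peak;
    ``fall_frac`` is the fraction of the period spent falling (0.5 gives
    the symmetric cosine).
    """
    u = np.mod(u, 1.0)
    falling = u <= fall_frac
    out = np.empty_like(u)
    out[falling] = np.cos(np.pi * u[falling] / fall_frac)
    out[~falling] = np.cos(np.pi * (u[~falling] - fall_frac) / (1.0 - fall_frac) + np.pi)
    return out


def _template_ranks(values: np.ndarray, tol: float = 1e-9) -> tuple[int, ...]:
    """Rank ordering of timepoint groups under a template, merging groups
    whose template values are tied (tied groups contribute no pairs)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=int)
    rank = 0
    prev = None
    for pos, gi in enumerate(order):
        if prev is not None and values[gi] - prev > tol:
            rank += 1
        ranks[gi] = rank
        prev = values[gi]
    return tuple(int(r) for r in ranks)


@dataclass
class _Ordering:
    phase: float
    ranks: np.ndarray
    mask: np.ndarray
    block_sizes: tuple[int, ...]


class _JTKPlan:
    """Per-design (timepoints + parameters) state reused across genes."""

    def __init__(
        self,
        t: np.ndarray,
        period: float,
        phase_grid,
        asymmetry_grid,
    ):
        self.period = period
        self.fold_times, self.groups = _fold_groups(t, period)
        self.sizes = np.array([len(g) for g in self.groups])
        if isinstance(phase_grid, str):
            if phase_grid != "auto":
                raise ValidationError(f"unknown phase grid {phase_grid!r}")
            phases = self.fold_times
        else:
            phases = np.asarray(phase_grid, dtype=float)
        if isinstance(asymmetry_grid, str):
            if asymmetry_grid != "symmetric":
                raise ValidationError(f"unknown asymmetry grid {asymmetry_grid!r}")
            falls = [0.5]
        else:
            falls = [float(a) for a in asymmetry_grid]
            if any(not 0.0 < a < 1.0 for a in falls):
                raise ValidationError("asymmetry fractions must lie in (0, 1)")
        seen: dict[tuple[int, ...], _Ordering] = {}
        for fall in falls:
            for phase in phases:
                values = _waveform((self.fold_times - phase) / period, fall)
                key = _template_ranks(values)
                if key in seen:
                    continue
                ranks = np.asarray(key)
                mask = ranks[:, None] < ranks[None, :]
                block_sizes = tuple(
                    int(self.sizes[ranks == r].sum()) for r in range(ranks.max() + 1)
                )
                seen[key] = _Ordering(float(phase), ranks, mask, block_sizes)
        self.orderings = list(seen.values())


def _template_p(
    stat: float,
    block_sizes: tuple[int, ...],
    has_ties: bool,
    tie_counts: np.ndarray | None,
    exact_threshold: int,
    null_mode: str,
    values: np.ndarray | None,
    n_perm: int,
    seed: int | None,
) -> float:
    """Two-sided JT p-value for one template ordering."""
    if len(block_sizes) < 2:
        return 1.0
    N = sum(block_sizes)
    if null_mode == "auto":
        if not has_ties and N <= exact_threshold:
            support, pmf = _exact_jt_pmf(tuple(block_sizes))
            upper = float(pmf[support >= stat - 1e-9].sum())
            lower = float(pmf[support <= stat + 1e-9].sum())
            return min(1.0, 2.0 * min(upper, lower))
        mean, var = _jt_moments(np.asarray(block_sizes), tie_counts)
        null = JTNull(mean=mean, var=var, mode="normal_approx")
        return null.two_sided_p(stat)
    null = jt_null(
        block_sizes,
        mode=null_mode,
        values=values,
        exact_threshold=exact_threshold,
        n_perm=n_perm,
        seed=seed,
    )
    return null.two_sided_p(stat)


def jtk_cycle_test(
    y: np.ndarray,
    t: np.ndarray,
    period: float = 24.0,
    phase_grid="auto",
    asymmetry_grid="symmetric",
    exact_threshold: int = 50,
    null_mode: str = "auto",
    n_perm: int = 100_000,
    seed: int | None = None,
    gene_id: str = "",
) -> CyclingResult:
    """JTK-style template test (JT / Kendall-tau against cosine templates).

    The default phase grid places one template peak at each distinct
    fold-time; the default asymmetry grid is the symmetric cosine only
    (template multiplicity costs power, so defaults minimize templates).
    The reported p-value is Bonferroni-corrected over the number of
    distinct template orderings and the phase is that of the best
    template.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    plan = _JTKPlan(t, period, phase_grid, asymmetry_grid)
    return _apply_jtk(plan, y, exact_threshold, null_mode, n_perm, seed, gene_id)


def _apply_jtk(
    plan: _JTKPlan,
    y: np.ndarray,
    exact_threshold: int,
    null_mode: str,
    n_perm: int,
    seed: int | None,
    gene_id: str,
) -> CyclingResult:
    gt, eq, _ = _block_tables(y, plan.groups)
    _, tie_counts = np.unique(y, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    best_p, best_phase = np.inf, None
    for ordering in plan.orderings:
        stat = _masked_stat(gt, eq, ordering.mask)
        values = (
            _ordered_values(y, plan.groups, ordering.ranks)
            if null_mode == "monte_carlo"
            else None
        )
        p2 = _template_p(
            stat,
            ordering.block_sizes,
            has_ties,
            tie_counts,
            exact_threshold,
            null_mode,
            values,
            n_perm,
            seed,
        )
        if p2 < best_p:
            best_p, best_phase = p2, ordering.phase
    n_templates = len(plan.orderings)
    p = min(1.0, best_p * n_templates)
    return CyclingResult(
        gene_id=gene_id,
        p_value=float(p),
        method="jtk",
        n_obs=int(y.size),
        phase=float(best_phase) if best_phase is not None else None,
        flags=[],
    )


def _ordered_values(
    y: np.ndarray, groups: list[np.ndarray], ranks: np.ndarray
) -> np.ndarray:
    """Pooled values ordered by template rank (for MC nulls)."""
    order = np.argsort(ranks, kind="stable")
    return np.concatenate([y[groups[i]] for i in order])


# ---------------------------------------------------------------------------
# umbrella / RAIN-style test


def _umbrella_cov(sizes: np.ndarray, peak: int) -> float:
    """Permutation covariance between the rising and falling JT statistics.

    The two segments share the peak timepoint's cells; for each shared
    cell, each (before-cell, after-cell) pair of comparisons covaries by
    1/12 under the tie-free permutation null (ties only shrink it, so
    using the tie-free value errs on the conservative side).
    """
    n_before = float(np.sum(sizes[:peak]))
    n_after = float(np.sum(sizes[peak + 1 :]))
    return float(sizes[peak]) * n_before * n_after / 12.0


@lru_cache(maxsize=512)
def _segment_masks(k: int, peak: int) -> np.ndarray:
    """Mask selecting the rising pairs up to ``peak`` plus the reversed
    falling pairs from ``peak`` to the last fold-time."""
    mask = np.zeros((k, k), dtype=bool)
    for i in range(peak):
        mask[i, i + 1 : peak + 1] = True  # rising: earlier < later
    for j in range(peak, k):
        mask[j + 1 :, j] = True  # falling reversed: later < earlier
    mask.setflags(write=False)
    return mask


def _umbrella_p(
    gt: np.ndarray,
    eq: np.ndarray,
    sizes: np.ndarray,
    peak: int,
    y: np.ndarray,
    groups: list[np.ndarray],
    exact_threshold: int,
    null_mode: str,
    n_perm: int,
    seed: int | None,
) -> tuple[float, float]:
    """One-sided upper p-value and statistic of the umbrella test with the
    given peak position (null = convolution of the two segment nulls)."""
    k = len(sizes)
    mask = _segment_masks(k, peak)
    stat = _masked_stat(gt, eq, mask)
    rise = tuple(int(s) for s in sizes[: peak + 1])
    fall = tuple(int(s) for s in sizes[peak:][::-1])
    segments = [seg for seg in (rise, fall) if len(seg) >= 2]
    if not segments:
        return 1.0, stat
    rise_cells = np.concatenate(groups[: peak + 1])
    fall_cells = np.concatenate(groups[peak:])
    seg_cells = [c for seg, c in ((rise, rise_cells), (fall, fall_cells)) if len(seg) >= 2]
    has_ties = any(
        (np.unique(y[c], return_counts=True)[1] > 1).any() for c in seg_cells
    )
    N = int(sizes.sum())
    if null_mode == "exact" and has_ties:
        raise ValidationError("exact umbrella null is only valid for tie-free data")
    use_exact = null_mode == "exact" or (
        null_mode == "auto" and not has_ties and N <= exact_threshold
    )
    if use_exact:
        pmf = np.array([1.0])
        for seg in segments:
            _, seg_pmf = _exact_jt_pmf(seg)
            pmf = np.convolve(pmf, seg_pmf)
        support = np.arange(pmf.size, dtype=float)
        return float(pmf[support >= stat - 1e-9].sum()), stat
    if null_mode == "monte_carlo":
        rng = np.random.default_rng(seed)
        total = np.zeros(n_perm)
        for seg, cells in zip((rise, fall), (rise_cells, fall_cells)):
            if len(seg) >= 2:
                total += _mc_jt_sample(y[cells], seg, n_perm, rng)
        p = (1.0 + float((total >= stat - 1e-9).sum())) / (n_perm + 1.0)
        return p, stat
    mean = var = 0.0
    for seg, cells in zip((rise, fall), (rise_cells, fall_cells)):
        if len(seg) >= 2:
            _, tie_counts = np.unique(y[cells], return_counts=True)
            m, v = _jt_moments(np.asarray(seg), tie_counts)
            mean += m
            var += v
    var += 2.0 * _umbrella_cov(sizes, peak)
    sd = math.sqrt(var) if var > 0 else 0.0
    if sd == 0.0:
        return 1.0 if stat <= mean + 1e-9 else 0.0, stat
    return float(scipy.stats.norm.sf((stat - 0.5 - mean) / sd)), stat


def umbrella_test(
    y: np.ndarray,
    t: np.ndarray,
    peak_index: int,
    period: float = 24.0,
    exact_threshold: int = 50,
    null_mode: str = "auto",
    n_perm: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float, list[str]]:
    """Umbrella test with a fixed peak position.

    Returns ``(p_value, statistic, flags)``; a peak at the first or last
    fold-time reduces to a monotone JT test and is flagged.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    fold_times, groups = _fold_groups(t, period)
    k = len(fold_times)
    if not 0 <= peak_index < k:
        raise ValidationError(f"peak_index {peak_index} outside 0..{k - 1}")
    gt, eq, sizes = _block_tables(y, groups)
    p, stat = _umbrella_p(
        gt, eq, sizes, peak_index, y, groups, exact_threshold, null_mode, n_perm, seed
    )
    flags = ["monotone"] if peak_index in (0, k - 1) else []
    return p, stat, flags


def rain_test(
    y: np.ndarray,
    t: np.ndarray,
    period: float = 24.0,
    exact_threshold: int = 50,
    null_mode: str = "auto",
    n_perm: int = 100_000,
    seed: int | None = None,
    gene_id: str = "",
) -> CyclingResult:
    """RAIN-style flexible-peak umbrella test.

    Takes the minimum one-sided umbrella p-value over all candidate peak
    positions plus interior trough positions (inverted umbrellas, tested
    on ``-y``) and applies a Bonferroni correction over the number of
    candidate shapes.  Troughs at the first/last fold-time duplicate the
    monotone peak shapes at the opposite end and are skipped.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    fold_times, groups = _fold_groups(t, period)
    k = len(fold_times)
    gt, eq, sizes = _block_tables(y, groups)
    shapes: list[tuple[str, int]] = [("peak", j) for j in range(k)]
    shapes += [("trough", j) for j in range(1, k - 1)]
    best_p, best_shape = np.inf, shapes[0]

    N = int(sizes.sum())
    _, tie_counts = np.unique(y, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    fast_normal = null_mode == "normal_approx" or (
        null_mode == "auto" and (has_ties or N > exact_threshold)
    )
    if fast_normal:
        # segment moments depend only on the peak position, not on the
        # peak/trough orientation: compute each prefix/suffix once
        prefix_m = {}
        suffix_m = {}
        for j in range(k):
            if j >= 1:
                cells = np.concatenate(groups[: j + 1])
                _, tc = np.unique(y[cells], return_counts=True)
                prefix_m[j] = _jt_moments(sizes[: j + 1], tc)
            else:
                prefix_m[j] = (0.0, 0.0)
            if j <= k - 2:
                cells = np.concatenate(groups[j:])
                _, tc = np.unique(y[cells], return_counts=True)
                suffix_m[j] = _jt_moments(sizes[j:][::-1], tc)
            else:
                suffix_m[j] = (0.0, 0.0)
        weights = gt + 0.5 * eq
        for kind, j in shapes:
            mask = _segment_masks(k, j)
            stat = float(((weights if kind == "peak" else weights.T) * mask).sum())
            mean = prefix_m[j][0] + suffix_m[j][0]
            var = prefix_m[j][1] + suffix_m[j][1] + 2.0 * _umbrella_cov(sizes, j)
            sd = math.sqrt(var) if var > 0 else 0.0
            if sd == 0.0:
                p = 1.0 if stat <= mean + 1e-9 else 0.0
            else:
                p = float(scipy.stats.norm.sf((stat - 0.5 - mean) / sd))
            if p < best_p:
                best_p, best_shape = p, (kind, j)
    else:
        for kind, j in shapes:
            if kind == "peak":
                p, _ = _umbrella_p(
                    gt, eq, sizes, j, y, groups, exact_threshold, null_mode, n_perm,
                    seed,
                )
            else:
                p, _ = _umbrella_p(
                    gt.T, eq, sizes, j, -y, groups, exact_threshold, null_mode, n_perm,
                    seed,
                )
            if p < best_p:
                best_p, best_shape = p, (kind, j)
    p = min(1.0, best_p * len(shapes))
    kind, j = best_shape
    if kind == "peak":
        phase = float(fold_times[j])
    else:
        # an inverted umbrella peaks at one of the ends; report the
        # endpoint with the larger observed mean
        lo = float(np.mean(y[groups[0]]))
        hi = float(np.mean(y[groups[-1]]))
        phase = float(fold_times[0] if lo >= hi else fold_times[-1])
    flags = ["monotone"] if (kind == "peak" and j in (0, k - 1)) else []
    return CyclingResult(
        gene_id=gene_id,
        p_value=float(p),
        method="rain",
        n_obs=int(y.size),
        phase=phase,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# BH adjustment and the dataset-level driver


def adjust_bh(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def detect_all(
    ds: ExpressionDataset,
    method: str,
    mode: str = "cells_as_replicates",
    cluster=None,
    period: float = 24.0,
    exact_threshold: int = 50,
    null_mode: str = "auto",
    n_perm: int = 100_000,
    seed: int | None = None,
    phase_grid="auto",
    asymmetry_grid="symmetric",
    compute_q: bool = True,
) -> list[CyclingResult]:
    """Apply one detector gene-by-gene to a dataset.

    ``mode='cells_as_replicates'`` treats each cell as an independent
    observation; ``mode='pseudobulk'`` first averages within each
    timepoint of the chosen cluster.  All-zero genes are assigned
    ``p = 1`` with an ``all_zero`` flag so gene lists stay aligned.
    """
    from .pseudobulk import make_pseudobulk

    if method not in ("harmonic", "jtk", "rain"):
        raise ValidationError(f"unknown method {method!r}")
    if mode not in ("cells_as_replicates", "pseudobulk"):
        raise ValidationError(f"unknown mode {mode!r}")

    work = ds
    if cluster is not None:
        work = _subset(ds, cluster=cluster).dataset
    if mode == "pseudobulk":
        if cluster is None:
            labels = work.cluster_labels()
            if len(labels) != 1:
                raise ValidationError("pseudobulk mode needs an explicit cluster")
            cluster = labels[0]
        profile = make_pseudobulk(work, cluster)
        Y = profile.values
        t = profile.timepoints
    else:
        Y = work.values
        t = work.timepoints

    n_obs = t.size
    results: list[CyclingResult] = []
    zero_mask = ~(Y != 0).any(axis=1)

    if method == "harmonic":
        p, F, amp, phase, mesor, degen = _harmonic_batch(Y, t, period)
        for i, gid in enumerate(work.gene_ids):
            if zero_mask[i]:
                results.append(
                    CyclingResult(gid, 1.0, "harmonic", n_obs, flags=["all_zero"])
                )
                continue
            flags = ["degenerate_fit"] if degen[i] else []
            results.append(
                CyclingResult(
                    gid,
                    float(p[i]),
                    "harmonic",
                    n_obs,
                    phase=float(phase[i]),
                    amplitude=float(amp[i]),
                    mesor=float(mesor[i]),
                    flags=flags,
                )
            )
    elif method == "jtk":
        plan = _JTKPlan(t, period, phase_grid, asymmetry_grid)
        for i, gid in enumerate(work.gene_ids):
            if zero_mask[i]:
                results.append(CyclingResult(gid, 1.0, "jtk", n_obs, flags=["all_zero"]))
                continue
            results.append(
                _apply_jtk(plan, Y[i], exact_threshold, null_mode, n_perm, seed, gid)
            )
    else:
        for i, gid in enumerate(work.gene_ids):
            if zero_mask[i]:
                results.append(CyclingResult(gid, 1.0, "rain", n_obs, flags=["all_zero"]))
                continue
            results.append(
                rain_test(
                    Y[i],
                    t,
                    period=period,
                    exact_threshold=exact_threshold,
                    null_mode=null_mode,
                    n_perm=n_perm,
                    seed=seed,
                    gene_id=gid,
                )
            )

    if compute_q:
        q = adjust_bh([r.p_value for r in results])
        for r, qi in zip(results, q):
            r.q_value = float(qi)
    return results


def results_to_frame(results: Sequence[CyclingResult], mode: str = "") -> pd.DataFrame:
    """Tabulate detection results (one row per gene)."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "method": [r.method for r in results],
            "mode": mode,
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "phase": [r.phase for r in results],
            "amplitude": [r.amplitude for r in results],
            "mesor": [r.mesor for r in results],
            "n_obs": [r.n_obs for r in results],
            "flags": [";".join(r.flags) for r in results],
        }
    )
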