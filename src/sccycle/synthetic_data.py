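"""Negative-binomial simulator for ground-truth-labeled circadian counts.

Counts at each timepoint follow a negative binomial distribution with
``Var = mu + mu^2 / r`` (``r`` is the size parameter; note that larger
``r`` means *less* noise).  Cycling signals are produced by varying the
mean with time: a per-timepoint template, normalized to span [0, 100],
plus a time-independent baseline offset ``mu0``:

    mu(t) = template(t) + mu0

The default ensemble design crosses 20 cycling + 20 non-cycling
templates with 5 baseline offsets (0.1 to 500) and 7 dispersion levels
(0.001 to 5), sampling 12 timepoints with 5 replicates each, for 1400
labeled series in total.

Templates may be extracted from a real dataset (lowest harmonic p-values
for cyclers; the expressed-and-flat rule for non-cyclers) or generated
parametrically, which is the default since it needs no download:
cycling templates are (optionally sharpened) cosines at a grid of
phases, non-cycling templates are seeded jitter with the fundamental
circadian harmonic projected out, so that they carry no 24-h component
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset, subset as _subset
from .errors import DegenerateTemplateError, ValidationError

DEFAULT_MU0_GRID = (0.1, 1.0, 10.0, 100.0, 500.0)
DEFAULT_DISPERSION_GRID = tuple(np.geomspace(0.001, 5.0, 7))


@dataclass
class Template:
    """Per-timepoint mean expression shape, normalized to span [0, 100]."""

    values: np.ndarray
    label: str  # "cycling" | "noncycling"
    source: str = "parametric"  # or "real-data-derived"
    template_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.label not in ("cycling", "noncycling"):
            raise ValidationError(f"unknown template label {self.label!r}")

    def resample(self, n_timepoints: int) -> np.ndarray:
        """Template means at ``n_timepoints`` evenly spaced phases of one
        period (periodic linear interpolation)."""
        m = self.values.size
        if m == n_timepoints:
            return self.values.copy()
        src = np.linspace(0.0, 1.0, m + 1)
        vals = np.append(self.values, self.values[0])
        dst = np.linspace(0.0, 1.0, n_timepoints, endpoint=False)
        return np.interp(dst, src, vals)


@dataclass
class SyntheticEnsembleSpec:
    """Fully determines a simulated ensemble with ground-truth labels."""

    templates: list[Template] = field(default_factory=lambda: make_parametric_templates())
    mu0_grid: tuple = DEFAULT_MU0_GRID
    dispersion_grid: tuple = DEFAULT_DISPERSION_GRID
    n_timepoints: int = 12
    reps_per_timepoint: int = 5
    timepoint_spacing: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if any(m <= 0 for m in self.mu0_grid):
            raise ValidationError("all mu0 must be > 0")
        if any(r <= 0 for r in self.dispersion_grid):
            raise ValidationError("all dispersions must be > 0")
        if self.n_timepoints < 4:
            raise ValidationError("need at least 4 timepoints")
        if self.reps_per_timepoint < 1:
            raise ValidationError("need at least 1 replicate per timepoint")

    @property
    def n_series(self) -> int:
        return len(self.templates) * len(self.mu0_grid) * len(self.dispersion_grid)

    @property
    def timepoints(self) -> np.ndarray:
        return self.timepoint_spacing * np.arange(self.n_timepoints)


@dataclass
class NBTimecourse:
    """One simulated series: replicate x timepoint counts plus truth."""

    counts: np.ndarray  # (reps, timepoints), non-negative integers
    mu_t: np.ndarray
    r: float
    truth: str  # "cycling" | "noncycling"
    template_id: str
    mu0: float


def normalize_template(
    raw,
    label: str = "cycling",
    source: str = "parametric",
    template_id: str = "",
) -> Template:
    """Affine-map per-timepoint means so they span exactly [0, 100]."""
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        raise DegenerateTemplateError("constant template cannot be normalized")
    values = np.clip(100.0 * (raw - lo) / (hi - lo), 0.0, 100.0)
    return Template(values=values, label=label, source=source, template_id=template_id)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, r: float, size) -> np.ndarray:
    # numpy parameterizes NB by (n, p); Var = mu + mu^2/r  <=>  n=r, p=r/(r+mu)
    return rng.negative_binomial(n=r, p=r / (r + mu), size=size)


def simulate_timecourse(
    template: Template,
    mu0: float,
    r: float,
    n_timepoints: int = 12,
    reps: int = 5,
    seed: int | np.random.SeedSequence = 0,
) -> NBTimecourse:
    """Draw one NB time course with ``mu(t) = template(t) + mu0``."""
    if mu0 <= 0 or r <= 0:
        raise ValidationError("mu0 and r must be > 0")
    mu_t = template.resample(n_timepoints) + mu0
    if np.any(mu_t <= 0):
        raise ValidationError("non-positive mean; check template normalization")
    rng = np.random.default_rng(seed)
    counts = _nb_draw(rng, mu_t[None, :], r, size=(reps, n_timepoints))
    return NBTimecourse(
        counts=counts,
        mu_t=mu_t,
        r=float(r),
        truth=template.label,
        template_id=template.template_id,
        mu0=float(mu0),
    )


def make_parametric_templates(
    n_cycling: int = 20,
    n_noncycling: int = 20,
    period: float = 24.0,
    phases=None,
    sharpness: float = 1.0,
    n_timepoints: int = 12,
    seed: int = 12345,
) -> list[Template]:
    """Parametric template library.

    Cycling templates are normalized cosines peaking at a grid of phases
    (``sharpness > 1`` narrows the peak).  Non-cycling templates are
    seeded jitter with the fundamental harmonic of the period projected
    out, then normalized; the jitter keeps them non-constant without
    introducing any 24-h component.
    """
    if n_cycling < 0 or n_noncycling < 0:
        raise ValidationError("template counts must be >= 0")
    t = np.linspace(0.0, period, n_timepoints, endpoint=False)
    w = 2.0 * np.pi / period
    if phases is None:
        phases = (
            np.linspace(0.0, period, n_cycling, endpoint=False) if n_cycling else []
        )
    templates: list[Template] = []
    for i, phi in enumerate(list(phases)[:n_cycling]):
        shape = (np.cos(w * (t - phi)) + 1.0) / 2.0
        if sharpness != 1.0:
            shape = shape**sharpness
        templates.append(
            normalize_template(shape, "cycling", "parametric", f"cyc{i:02d}")
        )
    rng = np.random.default_rng(seed)
    basis = np.column_stack([np.cos(w * t), np.sin(w * t)])
    proj = basis @ np.linalg.pinv(basis)
    made = 0
    while made < n_noncycling:
        jitter = rng.normal(size=n_timepoints)
        residual = jitter - proj @ jitter - np.mean(jitter - proj @ jitter)
        if residual.max() - residual.min() <= 1e-9:
            continue
        templates.append(
            normalize_template(
                residual, "noncycling", "parametric", f"non{made:02d}"
            )
        )
        made += 1
    return templates


def templates_from_dataset(
    ds: ExpressionDataset,
    cluster,
    n_cycling: int = 20,
    n_noncycling: int = 20,
    period: float = 24.0,
) -> list[Template]:
    """Real-data template extraction.

    The cycling templates are the per-timepoint pseudo-bulk means of the
    ``n_cycling`` genes with the lowest cells-as-replicates harmonic
    p-values; the non-cycling templates come from genes expressed in at
    least half of the cells with harmonic p > 0.9.
    """
    from .contamination import select_noncycling_genes
    from .detectors import detect_all
    from .pseudobulk import make_pseudobulk

    sub = _subset(ds, cluster=cluster).dataset
    results = detect_all(sub, "harmonic", period=period, compute_q=False)
    profile = make_pseudobulk(sub, cluster)
    by_p = sorted(results, key=lambda r: r.p_value)
    templates = []
    for i, r in enumerate(by_p[:n_cycling]):
        row = profile.values[profile.gene_ids.index(r.gene_id)]
        templates.append(
            normalize_template(row, "cycling", "real-data-derived", f"cyc_{r.gene_id}")
        )
    flat = select_noncycling_genes(sub, cluster, period=period)[:n_noncycling]
    for g in flat:
        row = profile.values[profile.gene_ids.index(g)]
        templates.append(
            normalize_template(row, "noncycling", "real-data-derived", f"non_{g}")
        )
    return templates


def build_ensemble(
    spec: SyntheticEnsembleSpec,
) -> tuple[list[NBTimecourse], pd.DataFrame]:
    """One time course per (template, mu0, dispersion) triple.

    Per-series seeds are derived from the master seed, so the ensemble
    is bit-reproducible and any single series can be regenerated.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_series)
    series: list[NBTimecourse] = []
    rows = []
    i = 0
    for template in spec.templates:
        for mu0 in spec.mu0_grid:
            for r in spec.dispersion_grid:
                tc = simulate_timecourse(
                    template,
                    mu0,
                    r,
                    n_timepoints=spec.n_timepoints,
                    reps=spec.reps_per_timepoint,
                    seed=seeds[i],
                )
                series.append(tc)
                rows.append(
                    {
                        "gene_id": f"g{i:05d}",
                        "label": template.label,
                        "template_id": template.template_id,
                        "mu0": float(mu0),
                        "dispersion": float(r),
                    }
                )
                i += 1
    truth = pd.DataFrame(rows)
    return series, truth


def ensemble_to_dataset(
    ensemble: list[NBTimecourse],
    timepoint_spacing: float = 2.0,
    cluster_label: str = "synthetic",
    condition_label: str = "LD",
) -> ExpressionDataset:
    """Reshape an ensemble into the universal dataset container.

    Series become genes; replicate draws become cells carrying timepoint
    metadata and a single synthetic cluster label.
    """
    if not ensemble:
        raise ValidationError("empty ensemble")
    shape = ensemble[0].counts.shape
    if any(tc.counts.shape != shape for tc in ensemble):
        raise ValidationError("all series must share the sampling design")
    reps, n_tp = shape
    # cell order: timepoint-major, replicate-minor
    values = np.stack([tc.counts.T.reshape(-1) for tc in ensemble]).astype(float)
    times = np.repeat(timepoint_spacing * np.arange(n_tp), reps)
    n_cells = reps * n_tp
    return ExpressionDataset(
        values=values,
        gene_ids=[f"g{i:05d}" for i in range(len(ensemble))],
        cell_ids=[f"cell{i:05d}" for i in range(n_cells)],
        timepoints=times,
        clusters=np.array([cluster_label] * n_cells, dtype=object),
        condition=np.array([condition_label] * n_cells, dtype=object),
    )


def simulate_flat_dataset(
    mu: float,
    r: float,
    n_genes: int,
    n_timepoints: int = 12,
    reps: int = 5,
    timepoint_spacing: float = 2.0,
    seed: int = 0,
    cluster_label: str = "synthetic",
) -> ExpressionDataset:
    """Null dataset: every gene is flat NB noise with constant mean.

    Used for type-I-error calibration; there is no cycling signal by
    construction.
    """
    if mu <= 0 or r <= 0:
        raise ValidationError("mu and r must be > 0")
    rng = np.random.default_rng(seed)
    n_cells = n_timepoints * reps
    values = _nb_draw(rng, np.full(n_cells, mu), r, size=(n_genes, n_cells)).astype(float)
    times = np.repeat(timepoint_spacing * np.arange(n_timepoints), reps)
    return ExpressionDataset(
        values=values,
        gene_ids=[f"null{i:05d}" for i in range(n_genes)],
        cell_ids=[f"cell{i:05d}" for i in range(n_cells)],
        timepoints=times,
        clusters=np.array([cluster_label] * n_cells, dtype=object),
        condition=np.array(["LD"] * n_cells, dtype=object),
    )
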