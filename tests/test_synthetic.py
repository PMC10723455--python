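import numpy as np
import pytest

from sccycle.errors import DegenerateTemplateError, ValidationError
from sccycle.synthetic_data import (
    DEFAULT_DISPERSION_GRID,
    DEFAULT_MU0_GRID,
    SyntheticEnsembleSpec,
    Template,
    build_ensemble,
    ensemble_to_dataset,
    make_parametric_templates,
    normalize_template,
    simulate_timecourse,
)


class TestNormalizeTemplate:
    def test_affine_endpoints(self):
        assert normalize_template([2, 4, 6]).values.tolist() == [0.0, 50.0, 100.0]

    def test_idempotent_on_normalized_input(self):
        tmpl = normalize_template([0.0, 25.0, 100.0])
        again = normalize_template(tmpl.values)
        np.testing.assert_allclose(again.values, tmpl.values)

    def test_affine_invariance(self):
        raw = np.array([1.0, 5.0, 2.0, 8.0])
        a = normalize_template(raw).values
        b = normalize_template(3.0 * raw + 11.0).values
        np.testing.assert_allclose(a, b)

    def test_constant_template_rejected(self):
        with pytest.raises(DegenerateTemplateError):
            normalize_template([4.0, 4.0, 4.0])


class TestSimulateTimecourse:
    def test_moments_match_nb_formula(self):
        """Empirical mean within 3 SE of mu, variance within self-calibrated
        Monte-Carlo error of mu + mu^2/r."""
        tmpl = normalize_template(
            np.cos(2 * np.pi * np.arange(12) / 12), label="cycling"
        )
        mu0, r = 10.0, 0.5
        tc = simulate_timecourse(tmpl, mu0, r, n_timepoints=12, reps=10_000, seed=3)
        for j in [0, 3, 6]:
            x = tc.counts[:, j].astype(float)
            mu = tc.mu_t[j]
            sigma2 = mu + mu * mu / r
            assert abs(x.mean() - mu) <= 3 * np.sqrt(sigma2 / x.size)
            m4 = np.mean((x - x.mean()) ** 4)
            se_var = np.sqrt(max(m4 - x.var() ** 2, 0) / x.size)
            assert abs(x.var(ddof=1) - sigma2) <= 6 * se_var

    def test_poisson_limit_at_large_dispersion(self):
        tmpl = Template(np.full(4, 50.0), label="noncycling")
        tc = simulate_timecourse(tmpl, 10.0, 1e6, n_timepoints=4, reps=20_000, seed=4)
        x = tc.counts[:, 0].astype(float)
        assert x.var(ddof=1) == pytest.approx(x.mean(), rel=0.05)

    def test_seeded_determinism(self):
        tmpl = normalize_template([0, 1, 2, 3, 2, 1], label="cycling")
        a = simulate_timecourse(tmpl, 5, 1, n_timepoints=6, reps=4, seed=9)
        b = simulate_timecourse(tmpl, 5, 1, n_timepoints=6, reps=4, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_invalid_parameters_rejected(self):
        tmpl = normalize_template([0, 1, 2], label="cycling")
        with pytest.raises(ValidationError):
            simulate_timecourse(tmpl, 0.0, 1.0)
        with pytest.raises(ValidationError):
            simulate_timecourse(tmpl, 1.0, -1.0)


class TestParametricTemplates:
    def test_counts_and_labels(self):
        templates = make_parametric_templates(6, 4)
        assert len(templates) == 10
        assert sum(t.label == "cycling" for t in templates) == 6
        assert sum(t.label == "noncycling" for t in templates) == 4

    def test_cycling_argmax_at_requested_phases(self):
        phases = [0.0, 4.0, 8.0, 12.0, 16.0, 20.0]
        templates = make_parametric_templates(6, 0, phases=phases)
        t_grid = np.linspace(0, 24, 12, endpoint=False)
        for tmpl, phi in zip(templates, phases):
            assert t_grid[np.argmax(tmpl.values)] == pytest.approx(phi)

    def test_noncycling_templates_have_no_fundamental(self):
        templates = make_parametric_templates(0, 10)
        t = np.linspace(0, 24, 12, endpoint=False)
        w = 2 * np.pi / 24
        for tmpl in templates:
            assert abs(np.dot(tmpl.values, np.cos(w * t))) < 1e-6
            assert abs(np.dot(tmpl.values, np.sin(w * t))) < 1e-6
            assert tmpl.values.min() == 0.0 and tmpl.values.max() == 100.0


class TestEnsemble:
    def test_default_design_size(self):
        spec = SyntheticEnsembleSpec(seed=0)
        assert spec.n_series == len(spec.templates) * len(DEFAULT_MU0_GRID) * len(
            DEFAULT_DISPERSION_GRID
        )
        ensemble, truth = build_ensemble(spec)
        assert len(ensemble) == spec.n_series
        assert len(truth) == spec.n_series

    def test_singleton_grid(self):
        spec = SyntheticEnsembleSpec(
            templates=[normalize_template([0, 1, 2, 3], label="cycling")],
            mu0_grid=(1.0,),
            dispersion_grid=(1.0,),
            n_timepoints=4,
        )
        ensemble, truth = build_ensemble(spec)
        assert len(ensemble) == 1

    def test_bit_identical_under_same_seed(self):
        spec = SyntheticEnsembleSpec(seed=42, mu0_grid=(1.0,), dispersion_grid=(0.5,))
        a, _ = build_ensemble(spec)
        b, _ = build_ensemble(SyntheticEnsembleSpec(seed=42, mu0_grid=(1.0,),
                                                    dispersion_grid=(0.5,)))
        assert all(np.array_equal(x.counts, y.counts) for x, y in zip(a, b))

    def test_dataset_conversion_shape_and_round_trip(self):
        spec = SyntheticEnsembleSpec(seed=1)
        ensemble, truth = build_ensemble(spec)
        ds = ensemble_to_dataset(ensemble)
        assert ds.n_genes == 1400
        assert ds.n_cells == 12 * 5
        # counts survive the reshape exactly
        i = 137
        np.testing.assert_array_equal(
            ds.values[i].reshape(12, 5).T, ensemble[i].counts
        )
        # truth table joins 1:1 with gene ids
        assert truth["gene_id"].tolist() == ds.gene_ids

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticEnsembleSpec(mu0_grid=(0.0, 1.0))
        with pytest.raises(ValidationError):
            SyntheticEnsembleSpec(n_timepoints=3)
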