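import numpy as np
import pandas as pd
import pytest

from sccycle.errors import DegenerateInputError, ValidationError
from sccycle.evaluation import (
    benchmark_runtime,
    grid_performance,
    overlap_table,
    roc_auc,
    runtime_trend_fit,
)

from _oracles import pairwise_auc


class TestRoc:
    def test_perfect_separation(self):
        p = pd.Series({"a": 0.001, "b": 0.002, "c": 0.8, "d": 0.9})
        roc = roc_auc(p, {"a", "b"})
        assert roc.auc == 1.0
        assert roc.n_pos == 2 and roc.n_neg == 2

    def test_uninformative_scores(self):
        p = pd.Series({"a": 0.5, "b": 0.5, "c": 0.5, "d": 0.5})
        assert roc_auc(p, {"a", "c"}).auc == pytest.approx(0.5)

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(6, 30))
            p = rng.choice([0.01, 0.05, 0.2, 0.5, 0.9], size=n)  # with ties
            genes = [f"g{i}" for i in range(n)]
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            positives = {g for g, l in zip(genes, labels) if l == 1}
            roc = roc_auc(pd.Series(p, index=genes), positives)
            assert roc.auc == pytest.approx(pairwise_auc(-p, labels))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        p = pd.Series(rng.random(20), index=[f"g{i}" for i in range(20)])
        pos = set(p.index[:7])
        assert roc_auc(p**3, pos).auc == pytest.approx(roc_auc(p, pos).auc)

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(2)
        p = pd.Series(rng.random(30), index=[f"g{i}" for i in range(30)])
        roc = roc_auc(p, set(p.index[:10]))
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()

    def test_single_class_is_degenerate(self):
        p = pd.Series({"a": 0.1, "b": 0.2})
        with pytest.raises(DegenerateInputError):
            roc_auc(p, {"a", "b"})


class TestGridPerformance:
    @staticmethod
    def _tables():
        truth = pd.DataFrame(
            {
                "gene_id": ["g0", "g1", "g2", "g3"],
                "label": ["cycling", "noncycling", "cycling", "noncycling"],
                "mu0": [1.0, 1.0, 10.0, 10.0],
                "dispersion": [0.5, 0.5, 0.5, 0.5],
            }
        )
        results = pd.DataFrame(
            {"gene_id": ["g0", "g1", "g2", "g3"], "p_value": [0.01, 0.2, 0.5, 0.01]}
        )
        return results, truth

    def test_rates_recompute_from_tables(self):
        results, truth = self._tables()
        perf = grid_performance(results, truth, alpha=0.05).table
        cell1 = perf[perf.mu0 == 1.0].iloc[0]
        assert cell1.tpr == 1.0 and cell1.fpr == 0.0
        cell10 = perf[perf.mu0 == 10.0].iloc[0]
        assert cell10.tpr == 0.0 and cell10.fpr == 1.0

    def test_result_order_is_irrelevant(self):
        results, truth = self._tables()
        shuffled = results.sample(frac=1.0, random_state=0)
        a = grid_performance(results, truth).table
        b = grid_performance(shuffled, truth).table
        pd.testing.assert_frame_equal(a, b)

    def test_missing_series_is_coverage_error(self):
        results, truth = self._tables()
        with pytest.raises(ValidationError):
            grid_performance(results.iloc[:2], truth)


class TestTrendFit:
    def test_planted_models_recovered_exactly(self):
        m = np.array([10.0, 20.0, 40.0, 80.0, 160.0])
        assert runtime_trend_fit(m, 3 * m**2)["best_model"] == "quadratic"
        assert runtime_trend_fit(m, 2 * m + 1)["best_model"] == "linear"
        m2 = np.array([4.0, 6.0, 8.0, 10.0, 12.0])
        assert runtime_trend_fit(m2, 0.01 * 2.0**m2)["best_model"] == "exponential"

    def test_recovery_under_multiplicative_noise(self):
        rng = np.random.default_rng(17)
        m = np.array([10.0, 20.0, 40.0, 80.0, 160.0, 320.0])
        planted = {
            "linear": 0.5 * m + 2,
            "quadratic": 0.02 * m**2 + 1,
        }
        m_exp = np.array([4.0, 8.0, 12.0, 16.0, 20.0, 24.0])
        for _ in range(10):
            for model, base in planted.items():
                noisy = base * np.exp(rng.normal(0, 0.05, size=m.size))
                assert runtime_trend_fit(m, noisy)["best_model"] == model
            noisy = 0.001 * 2.0**m_exp * np.exp(rng.normal(0, 0.05, size=m_exp.size))
            assert runtime_trend_fit(m_exp, noisy)["best_model"] == "exponential"

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            runtime_trend_fit([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValidationError):
            runtime_trend_fit([1, 2, 3, 4], [1, -2, 3, 4])


def test_benchmark_runtime_harness_reports_positive_timings():
    """The timing harness records one wall-clock row per size; the
    timings themselves are informative only and never asserted."""
    from sccycle.detectors import harmonic_regression_test

    rng = np.random.default_rng(0)

    def make_input(m):
        t = np.sort(np.tile(4.0 * np.arange(6), int(np.ceil(m / 6)))[:m])
        return rng.normal(size=m), t

    table = benchmark_runtime(
        lambda y, t: harmonic_regression_test(y, t), [12, 24, 48], make_input
    )
    assert table["size"].tolist() == [12, 24, 48]
    assert (table["seconds"] > 0).all()


class TestOverlapTable:
    def test_identical_sets_single_cell(self):
        membership, counts = overlap_table({"a": {"g1", "g2"}, "b": {"g1", "g2"}})
        assert counts.loc[(True, True)] == 2
        assert len(counts) == 1

    def test_disjoint_sets(self):
        membership, counts = overlap_table({"a": {"g1"}, "b": {"g2"}})
        assert counts.loc[(True, False)] == 1
        assert counts.loc[(False, True)] == 1

    def test_counts_sum_to_union(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(40)]
        sets = {
            name: {g for g in universe if rng.random() < 0.4}
            for name in ("hr", "jtk", "rain")
        }
        membership, counts = overlap_table(sets)
        assert counts.sum() == len(set().union(*sets.values()))
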