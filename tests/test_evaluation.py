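import numpy as np
import pandas as pd
import pytest

from nmflink.benchmark_tables import benchmark_network_stats, benchmark_precision_table
from nmflink.evaluation import (
    available_methods,
    get_scorer,
    mean_precision_ranking,
    monte_carlo_random_precision,
    precision,
    random_predictor_precision,
    relative_precision,
    run_experiment,
    stat_correlations,
)

from conftest import network_from_edges


class TestPrecision:
    def test_top10_three_hits(self):
        ranked = [(0, i) for i in range(1, 21)]
        test = {(0, 2), (0, 5), (0, 9), (0, 15)}
        # (0,15) is beyond position 10
        assert precision(ranked, test, 10) == pytest.approx(0.3)

    def test_perfect_ranking(self):
        test = {(0, 1), (0, 2)}
        ranked = [(0, 1), (0, 2), (0, 3), (0, 4)]
        assert precision(ranked, test, 2) == 1.0

    def test_all_misses(self):
        ranked = [(0, 1), (0, 2), (0, 3)]
        assert precision(ranked, {(0, 3)}, 2) == 0.0

    def test_l_validation(self):
        with pytest.raises(ValueError):
            precision([(0, 1)], set(), 0)
        with pytest.raises(ValueError):
            precision([(0, 1)], set(), 2)

    def test_orientation_insensitive(self):
        assert precision([(1, 0)], {(0, 1)}, 1) == 1.0


class TestRandomPredictor:
    def test_karate_value(self):
        p = random_predictor_precision(34, 78, 8)
        assert p == pytest.approx(8 / 491)
        assert round(p, 3) == 0.016

    def test_power_grid_value(self):
        p = random_predictor_precision(4941, 6594, 659)
        assert float(f"{p:.1e}") == pytest.approx(5.4e-5)

    def test_all_candidates_tested(self):
        # complete graph minus nothing held out except all candidates
        # n=3, m=3, l=1: candidates = 3 - 2 = 1 -> precision 1
        assert random_predictor_precision(3, 3, 1) == 1.0

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            random_predictor_precision(1, 1, 1)
        with pytest.raises(ValueError):
            random_predictor_precision(10, 5, 6)

    def test_monte_carlo_within_3se(self):
        n, m, l, reps = 34, 78, 8, 10_000
        analytic = random_predictor_precision(n, m, l)
        est = monte_carlo_random_precision(n, m, l, reps=reps, seed=0)
        # per-run hit count is hypergeometric; bound its SD by binomial
        se = np.sqrt(analytic * (1 - analytic) / l / reps)
        assert abs(est - analytic) < 3 * se


class TestRelativePrecision:
    def test_simple(self):
        assert relative_precision(0.3, 0.1) == pytest.approx(3.0)
        assert relative_precision(0.016, 0.016) == pytest.approx(1.0)

    def test_zero_random_errors(self):
        with pytest.raises(ValueError):
            relative_precision(0.3, 0.0)


class TestRunExperiment:
    def test_single_run_deterministic_method(self, karate):
        res = run_experiment(karate, ["CN"], test_fraction=0.1, runs=1, seed=3)
        assert res.mean_precision["CN"] == res.per_run_precision["CN"][0]

    def test_reproducible(self, karate):
        a = run_experiment(karate, ["CN", "RA"], runs=3, seed=5)
        b = run_experiment(karate, ["CN", "RA"], runs=3, seed=5)
        assert a.per_run_precision == b.per_run_precision

    def test_registration_order_irrelevant(self, karate):
        a = run_experiment(karate, ["CN", "AA"], runs=3, seed=5)
        b = run_experiment(karate, ["AA", "CN"], runs=3, seed=5)
        assert a.per_run_precision["CN"] == b.per_run_precision["CN"]
        assert a.per_run_precision["AA"] == b.per_run_precision["AA"]

    def test_failing_method_excluded_with_warning(self, karate):
        def broken(split, seed):
            raise RuntimeError("boom")

        scorers = {"CN": get_scorer("CN"), "bad": broken}
        with pytest.warns(UserWarning, match="bad failed"):
            res = run_experiment(karate, scorers, runs=2, seed=1)
        assert len(res.per_run_precision["CN"]) == 2
        assert len(res.per_run_precision["bad"]) == 0
        assert np.isnan(res.mean_precision["bad"])

    def test_precision_in_unit_interval(self, karate):
        res = run_experiment(karate, ["CN", "PA"], runs=5, seed=2)
        for vals in res.per_run_precision.values():
            assert all(0.0 <= v <= 1.0 for v in vals)

    def test_unknown_method(self, karate):
        with pytest.raises(ValueError):
            run_experiment(karate, ["NOPE"], runs=1, seed=0)

    def test_all_method_names_resolve(self):
        for name in available_methods():
            assert callable(get_scorer(name, rank=4))


class TestMeanPrecisionRanking:
    def test_two_by_two(self):
        table = pd.DataFrame(
            {"netA": [0.5, 0.2], "netB": [0.1, 0.3]}, index=["m1", "m2"]
        )
        ranks = mean_precision_ranking(table)
        assert ranks.loc["m1", "netA"] == 1
        assert ranks.loc["m2", "netA"] == 2
        assert ranks.loc["m1", "netB"] == 2
        assert ranks.loc["m1", "mean"] == pytest.approx(1.5)

    def test_ties_broken_by_listed_order(self):
        table = pd.DataFrame({"net": [0.5, 0.5, 0.5]}, index=["a", "b", "c"])
        ranks = mean_precision_ranking(table)
        assert list(ranks["net"]) == [1, 2, 3]
        ranks2 = mean_precision_ranking(table, tie_order=["c", "b", "a"])
        assert list(ranks2["net"]) == [3, 2, 1]

    def test_missing_cell_errors(self):
        table = pd.DataFrame({"net": [0.5, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError):
            mean_precision_ranking(table)

    def test_published_table_reproduces_mean_ranks(self):
        ranks = mean_precision_ranking(benchmark_precision_table())
        assert round(ranks.loc["AA", "mean"], 2) == 8.93
        assert round(ranks.loc["CN", "mean"], 2) == 10.07
        assert round(ranks.loc["RA", "mean"], 2) == 9.07
        assert round(ranks.loc["SPM", "mean"], 2) == 2.73


class TestStatCorrelations:
    def test_self_correlation_is_one(self):
        stats = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        prec = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"], columns=["a", "b", "c"])
        out = stat_correlations(prec, stats)
        assert out.loc["m", "s"] == pytest.approx(1.0)

    def test_antimonotone_is_minus_one(self):
        stats = pd.DataFrame({"s": [3.0, 2.0, 1.0]}, index=["a", "b", "c"])
        prec = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"], columns=["a", "b", "c"])
        assert stat_correlations(prec, stats).loc["m", "s"] == pytest.approx(-1.0)

    def test_zero_variance_is_nan(self):
        stats = pd.DataFrame({"s": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
        prec = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"], columns=["a", "b", "c"])
        assert np.isnan(stat_correlations(prec, stats).loc["m", "s"])

    def test_too_few_networks(self):
        stats = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"])
        prec = pd.DataFrame([[1.0, 2.0]], index=["m"], columns=["a", "b"])
        with pytest.raises(ValueError):
            stat_correlations(prec, stats)

    def test_published_cn_cc_correlation(self):
        out = stat_correlations(benchmark_precision_table(), benchmark_network_stats())
        assert out.loc["CN", "CC"] == pytest.approx(0.77, abs=0.02)

    def test_alignment_by_name_not_position(self):
        # the two published tables list Power and Router in different
        # orders; name-based alignment must handle that
        prec = benchmark_precision_table()
        stats = benchmark_network_stats()
        assert list(prec.columns) != list(stats.index)
        assert set(prec.columns) == set(stats.index)
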