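import numpy as np
import pytest
from scipy import stats

from pvstrat.contingency import StratumCounts
from pvstrat.disproportionality import (
    DisproportionalityResult,
    analyze_pairs,
    evaluate_pair,
    ic_credible_interval,
    ic_interval,
    ic_point,
    information_component,
    proportional_reporting_ratio,
    reporting_odds_ratio,
)
from pvstrat.errors import UndefinedStratumError
from pvstrat.icsr_model import deduplicate
from pvstrat.synthetic_data import PlantedSignal, default_config, generate


class TestInformationComponent:
    def test_reference_value(self):
        # (40 observed, 100x80/1000 = 8 expected): log2(40.5/8.5)
        c = StratumCounts("all", 40, 100, 80, 1000)
        assert information_component(c) == pytest.approx(2.252387161634285, abs=1e-12)

    def test_observed_equal_expected_is_exactly_zero(self):
        assert ic_point(8, 8.0) == 0.0

    def test_zero_observed_is_exact_power_of_two(self):
        assert ic_point(0, 7.5) == -4.0

    def test_strictly_monotone_in_observed_and_expected(self):
        grid_obs = np.array([0, 1, 5, 40, 500])
        for n_exp in (0.5, 8.0, 100.0):
            vals = ic_point(grid_obs, n_exp)
            assert np.all(np.diff(vals) > 0)
        grid_exp = np.array([0.5, 2.0, 8.0, 100.0])
        for n_obs in (0, 5, 40):
            vals = ic_point(n_obs, grid_exp)
            assert np.all(np.diff(vals) < 0)

    def test_shrinkage_limit_approaches_raw_ratio(self):
        # scaling (n_obs, n_exp) by k drives IC to log2(n_obs / n_exp)
        target = np.log2(40 / 8)
        errs = [abs(ic_point(40 * k, 8.0 * k) - target) for k in (1, 10, 1000)]
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-3

    def test_empty_stratum_raises(self):
        with pytest.raises(UndefinedStratumError):
            information_component(StratumCounts("male", 0, 0, 0, 0))


class TestCredibleInterval:
    def test_brackets_point_estimate_and_narrows_with_counts(self):
        c1 = StratumCounts("all", 40, 100, 80, 1000)
        lo1, hi1 = ic_credible_interval(c1)
        ic1 = information_component(c1)
        assert lo1 < ic1 < hi1
        c10 = StratumCounts("all", 400, 1000, 800, 10000)
        lo10, hi10 = ic_credible_interval(c10)
        assert (hi10 - lo10) < (hi1 - lo1)

    def test_concentrates_around_zero_for_huge_null_counts(self):
        lo, hi = ic_interval(10**6, 10**6)
        assert lo < 0 < hi
        assert hi - lo < 0.01

    def test_matches_monte_carlo_posterior_quantiles(self):
        # independent sampling oracle from the stated Gamma posterior; the
        # comparison allows for the oracle's own quantile noise (batch SE)
        rng = np.random.default_rng(42)
        for n_obs, n_exp in [(1, 0.5), (5, 8.0), (40, 8.0), (500, 100.0)]:
            draws = np.log2(
                rng.gamma(shape=n_obs + 0.5, scale=1.0 / (n_exp + 0.5), size=1_000_000)
            )
            mc_lo, mc_hi = np.quantile(draws, [0.025, 0.975])
            batches = draws.reshape(20, -1)
            se_lo = np.quantile(batches, 0.025, axis=1).std(ddof=1) / np.sqrt(20)
            se_hi = np.quantile(batches, 0.975, axis=1).std(ddof=1) / np.sqrt(20)
            lo, hi = ic_interval(n_obs, n_exp)
            assert lo == pytest.approx(mc_lo, abs=0.01 + 3 * se_lo)
            assert hi == pytest.approx(mc_hi, abs=0.01 + 3 * se_hi)

    def test_normal_approximation_close_to_gamma_for_large_counts(self):
        lo_g, hi_g = ic_interval(500, 400.0, method="gamma")
        lo_n, hi_n = ic_interval(500, 400.0, method="normal")
        assert lo_n == pytest.approx(lo_g, abs=0.01)
        assert hi_n == pytest.approx(hi_g, abs=0.01)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            ic_interval(5, 5.0, level=1.5)


class TestComparators:
    def test_ror_direct_arithmetic(self):
        # a=40 b=60 c=40 d=860
        c = StratumCounts("all", 40, 100, 80, 1000)
        ror = reporting_odds_ratio(c)
        assert ror.value == pytest.approx(40 * 860 / (60 * 40))
        assert ror.ci_low < ror.value < ror.ci_high
        assert not ror.corrected

    def test_ror_proportional_rows_is_one(self):
        # a=10 b=20 c=30 d=60: a/b == c/d
        c = StratumCounts("all", 10, 30, 40, 120)
        assert reporting_odds_ratio(c).value == pytest.approx(1.0)

    def test_ror_zero_cell_uses_haldane_correction(self):
        c = StratumCounts("all", 0, 61, 41, 962)  # a=0 b=61 c=41 d=860
        ror = reporting_odds_ratio(c)
        assert ror.corrected
        assert ror.value == pytest.approx(0.5 * 860.5 / (61.5 * 41.5))

    def test_prr_direct_arithmetic(self):
        c = StratumCounts("all", 40, 100, 80, 1000)
        prr = proportional_reporting_ratio(c)
        assert prr.value == pytest.approx((40 / 100) / (40 / 900))
        assert prr.ci_low < prr.value < prr.ci_high

    def test_prr_equal_proportions_is_one(self):
        c = StratumCounts("all", 10, 100, 100, 1000)  # 10/100 == 90/900
        assert proportional_reporting_ratio(c).value == pytest.approx(1.0)

    def test_prr_zero_comparator_cell_is_corrected(self):
        c = StratumCounts("all", 10, 100, 10, 1000)  # c = 0
        prr = proportional_reporting_ratio(c)
        assert prr.corrected

    def test_prr_undefined_without_comparator_population(self):
        c = StratumCounts("all", 10, 100, 10, 100)
        with pytest.raises(UndefinedStratumError):
            proportional_reporting_ratio(c)

    @pytest.mark.parametrize(
        "counts",
        [
            StratumCounts("all", 100, 10_000, 10_000, 1_000_000),
            StratumCounts("all", 200, 10_000, 10_000, 1_000_000),
            StratumCounts("all", 150, 5_000, 30_000, 1_000_000),
        ],
    )
    def test_estimators_agree_on_large_sparse_tables(self, counts):
        # with all cells large and n_drug << n_total the three measures
        # estimate the same relative reporting rate
        ror = reporting_odds_ratio(counts).value
        prr = proportional_reporting_ratio(counts).value
        two_ic = 2.0 ** information_component(counts)
        assert ror == pytest.approx(prr, rel=0.10)
        assert two_ic == pytest.approx(prr, rel=0.10)


class TestEvaluatePair:
    def test_zero_observed_pair_is_na(self, toy_dataset):
        ds = toy_dataset
        res = evaluate_pair(ds, "D", "Z", "male")
        assert res.is_na and not res.is_signal
        assert np.isnan(res.ic) and np.isnan(res.ic025)

    def test_signal_flag_tracks_lower_bound(self):
        cfg = default_config(
            n_reports=100_000,
            seed=91,
            signals=[PlantedSignal("dupilumab", "conjunctivitis", 8.0, 8.0)],
        )
        ds = generate(cfg)
        ds.reports = deduplicate(ds.reports)
        res = evaluate_pair(ds, "dupilumab", "conjunctivitis", "male")
        assert res.is_signal and res.ic025 > 0
        assert res.ic025 < res.ic < res.ic975

    def test_null_dataset_rarely_flags(self):
        ds = generate(default_config(n_reports=30_000, seed=92))
        table = analyze_pairs(ds, strata=("male", "female"))
        assert table["is_signal"].mean() <= 0.05

    def test_table_matches_scalar_path(self, toy_dataset):
        table = analyze_pairs(toy_dataset, drugs=["D"], strata=("male",))
        row = table.set_index("reaction_pt").loc["X"]
        res = evaluate_pair(toy_dataset, "D", "X", "male")
        assert row["ic"] == pytest.approx(res.ic)
        assert row["ic025"] == pytest.approx(res.ic025)
        assert row["ror"] == pytest.approx(res.ror)
        assert row["prr"] == pytest.approx(res.prr)

    def test_from_interval_signal_criterion(self):
        res = DisproportionalityResult.from_interval(2.5, 0.45, 3.69)
        assert res.is_signal and not res.is_na
        null = DisproportionalityResult.from_interval(0.3, -0.2, 0.8)
        assert not null.is_signal
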