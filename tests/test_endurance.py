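import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from _oracles import pairwise_quantile_fit
from foundorfly import endurance
from foundorfly.endurance import (
    EnduranceError,
    build_endurance_dataset,
    check_loss,
    colony_homogeneity,
    exclude_outliers,
    fit_ols_and_rank,
    fit_quantile,
    total_flight_time,
)
from foundorfly.io import FlightRecord


def make_dataset(masses, totals, colonies=None):
    n = len(masses)
    return pd.DataFrame(
        {
            "queen_id": [f"q{i}" for i in range(n)],
            "colony_id": colonies if colonies is not None else ["c0"] * n,
            "total_flight_time": totals,
            "abdomen_mass": masses,
            "log_fmr": np.log(np.linspace(0.12, 0.2, n)),
            "wing_loading": np.linspace(0.2, 0.3, n),
            "excluded": False,
            "exclusion_reason": "",
        }
    )


class TestTotalFlightTime:
    def test_single_bout(self):
        assert total_flight_time(FlightRecord("q", "c", (60.0,))) == 60.0

    def test_six_bouts_sum(self):
        rec = FlightRecord("q", "c", (10.0,) * 6)
        assert total_flight_time(rec) == 60.0

    def test_longest_flier_scale(self):
        # six bouts engineered to sum to the longest observed total
        bouts = (1000.0, 900.0, 800.0, 700.0, 750.0, 750.0)
        assert total_flight_time(FlightRecord("q", "c", bouts)) == 4900.0


class TestOutlierRule:
    def test_light_abdomen_flagged_but_not_excluded_by_default(self):
        masses = [5.2, 5.5, 5.8, 6.0, 5.6, 5.4, 5.7, 1.5]
        ds = make_dataset(masses, [100.0] * 8)
        out = exclude_outliers(ds, enabled=False, abs_threshold=2.0)
        assert out["exclusion_reason"].iloc[-1] != ""
        assert not out["excluded"].any()

    def test_exclusion_requires_assent(self):
        masses = [5.2, 5.5, 5.8, 6.0, 5.6, 5.4, 5.7, 1.5]
        ds = make_dataset(masses, [100.0] * 8)
        out = exclude_outliers(ds, enabled=True, abs_threshold=2.0)
        assert list(out["excluded"]) == [False] * 7 + [True]

    def test_k_sd_rule(self):
        # enough typical queens that the single light abdomen cannot mask
        # itself by inflating the cohort SD
        masses = [5.0 + 0.03 * i for i in range(30)] + [1.5]
        out = exclude_outliers(make_dataset(masses, [1.0] * 31), k_sd=3.0)
        assert out["exclusion_reason"].iloc[-1] != ""
        assert (out["exclusion_reason"].iloc[:-1] == "").all()

    def test_empty_dataset(self):
        ds = make_dataset([], [])
        assert exclude_outliers(ds).empty


class TestColonyHomogeneity:
    def test_homogeneous_colonies_pool(self):
        rng = np.random.default_rng(10)
        n = 60
        ds = make_dataset(
            rng.normal(5, 0.5, n),
            rng.lognormal(6, 1, n),
            colonies=[f"c{i % 3}" for i in range(n)],
        )
        table = colony_homogeneity(ds, variables=("total_flight_time", "abdomen_mass"))
        assert (table["recommendation"] == "pool").all()

    def test_disjoint_colonies_flagged(self):
        n = 30
        ds = make_dataset(
            [5.0] * n,
            [float(100 + i) for i in range(n // 2)]
            + [float(10000 + i) for i in range(n // 2)],
            colonies=["a"] * (n // 2) + ["b"] * (n // 2),
        )
        table = colony_homogeneity(ds, variables=("total_flight_time",))
        assert (table["recommendation"] == "do_not_pool").all()
        assert table["p"].iloc[0] < 1e-4

    def test_single_colony_rejected(self):
        with pytest.raises(EnduranceError):
            colony_homogeneity(make_dataset([1, 2, 3], [1, 2, 3]))


class TestQuantileFit:
    def test_collinear_points_interpolated_exactly(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = 2.0 - 3.0 * x
        for tau in (0.25, 0.5, 0.75):
            fit = fit_quantile(x, y, tau)
            assert fit.slope == pytest.approx(-3.0, abs=1e-9)
            assert fit.intercept == pytest.approx(2.0, abs=1e-9)
            assert fit.objective == pytest.approx(0.0, abs=1e-9)

    def test_six_point_heteroscedastic_set_matches_oracle(self):
        x = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        y = np.array([1.0, 5.0, 2.0, 6.0, 3.0, 7.0])
        fit = fit_quantile(x, y, 0.75)
        _, _, oracle_obj = pairwise_quantile_fit(x, y, 0.75)
        assert fit.objective == pytest.approx(oracle_obj, abs=1e-9)

    def test_median_fit_equals_lad_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 10, 7)
        y = 1 + 0.5 * x + rng.normal(0, 1, 7)
        fit = fit_quantile(x, y, 0.5)
        _, _, oracle_obj = pairwise_quantile_fit(x, y, 0.5)
        assert fit.objective == pytest.approx(oracle_obj, abs=1e-9)

    def test_never_worse_than_ols_line(self):
        rng = np.random.default_rng(7)
        for tau in (0.25, 0.5, 0.75, 0.9):
            x = rng.uniform(0, 5, 25)
            y = 3 * x + rng.standard_t(3, 25)
            fit = fit_quantile(x, y, tau)
            ols = np.polynomial.polynomial.polyfit(x, y, 1)
            assert fit.objective <= check_loss(x, y, ols[0], ols[1], tau) + 1e-9

    def test_subgradient_bracket_at_optimum(self):
        rng = np.random.default_rng(8)
        for tau in (0.25, 0.75):
            x = rng.uniform(0, 5, 40)
            y = 10 - 2 * x + rng.normal(0, 2, 40)
            fit = fit_quantile(x, y, tau)
            resid = y - fit.intercept - fit.slope * x
            below = int(np.sum(resid < -1e-8))
            below_or_on = int(np.sum(resid <= 1e-8))
            assert below <= tau * len(x) <= below_or_on

    def test_agrees_with_statsmodels_quantreg(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(3, 7, 50)
        y = 6000 - 1000 * x + rng.normal(0, 300, 50)
        fit = fit_quantile(x, y, 0.75)
        sm_fit = sm.QuantReg(y, sm.add_constant(x)).fit(q=0.75)
        sm_obj = check_loss(x, y, sm_fit.params[0], sm_fit.params[1], 0.75)
        assert fit.objective <= sm_obj + 1e-6
        assert fit.slope == pytest.approx(sm_fit.params[1], rel=1e-3)

    def test_small_n_oracle_equivalence(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            x = rng.uniform(0, 10, n)
            y = rng.uniform(0, 100, n)
            tau = float(rng.uniform(0.1, 0.9))
            fit = fit_quantile(x, y, tau)
            _, _, oracle_obj = pairwise_quantile_fit(x, y, tau)
            assert fit.objective == pytest.approx(oracle_obj, abs=1e-9)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(EnduranceError):
            fit_quantile([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_bootstrap_p_seeded_and_valid(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0, 5, 20)
        y = 10 - 3 * x + rng.normal(0, 0.5, 20)
        f1 = fit_quantile(x, y, 0.75, n_boot=99, seed=5)
        f2 = fit_quantile(x, y, 0.75, n_boot=99, seed=5)
        assert f1.p_raw == f2.p_raw
        assert 0 < f1.p_raw <= 1
        # strongly negative relationship: small p
        assert f1.p_raw < 0.1


class TestComparators:
    def test_monotone_nonlinear_ranks_beat_ols(self):
        x = np.linspace(1, 5, 20)
        ds = make_dataset(x, np.exp(x))
        tables = fit_ols_and_rank(ds, predictors=("abdomen_mass",))
        assert tables["spearman"]["r_s"].iloc[0] == pytest.approx(1.0)
        assert tables["ols"]["r_squared"].iloc[0] < 1.0

    def test_anti_monotone_line(self):
        x = np.linspace(1, 5, 20)
        ds = make_dataset(x, -2 * x + 1)
        tables = fit_ols_and_rank(ds, predictors=("abdomen_mass",))
        assert tables["spearman"]["r_s"].iloc[0] == pytest.approx(-1.0)
        assert tables["ols"]["slope"].iloc[0] < 0

    def test_holm_family_is_per_method(self):
        rng = np.random.default_rng(14)
        n = 30
        ds = make_dataset(
            rng.uniform(3, 7, n), rng.uniform(100, 5000, n)
        )
        tables = fit_ols_and_rank(ds)
        for name in ("ols", "spearman"):
            t = tables[name]
            assert len(t) == 3
            assert (t["p_corrected"] >= t["p"] - 1e-15).all()


def test_dataset_build_and_full_analysis(ic_cohort):
    from foundorfly.synthetic import FlightGenSpec, generate_flights

    flights = generate_flights(ic_cohort, FlightGenSpec(), seed=3)
    ds = build_endurance_dataset(flights)
    assert set(endurance.PREDICTORS) <= set(ds.columns)
    assert (ds["total_flight_time"] > 0).all()
    tables = endurance.endurance_analysis(ds, tau=0.75, n_boot=49, seed=6)
    q = tables["quantile"].set_index("predictor")
    # heavier abdomens and higher loading depress the envelope; more
    # flight muscle (log FMR) raises it
    assert q.loc["abdomen_mass", "slope"] < 0
    assert q.loc["wing_loading", "slope"] < 0
    assert q.loc["log_fmr", "slope"] > 0
    assert (tables["quantile"]["p_corrected"] >= tables["quantile"]["p"] - 1e-15).all()
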