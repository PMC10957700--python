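import math

import numpy as np
import pytest
import yaml

from ctp_cea import (
    InflationSeries,
    LifeTable,
    ModelParameters,
    beta_from_mean_sd,
    default_life_table,
    gamma_from_mean_sd,
    life_expectancy,
    load_parameters,
    lognormal_from_ci,
)

RNG = np.random.default_rng(20240601)


class TestLognormalFromCI:
    def test_evt_or_location_and_scale(self):
        spec = lognormal_from_ci(1.67, 1.21, 2.30)
        assert spec.family == "lognormal"
        mu, sigma = spec.params
        assert mu == pytest.approx(0.5128, abs=1e-4)
        assert sigma == pytest.approx(0.1639, abs=1e-4)

    def test_degenerate_ci_gives_zero_scale(self):
        spec = lognormal_from_ci(2.0, 2.0, 2.0)
        assert spec.params[1] == 0.0

    def test_sampled_median_recovers_input(self):
        spec = lognormal_from_ci(1.54, 1.0, 2.37)
        draws = spec.rvs(RNG, 10**6)
        assert np.median(draws) == pytest.approx(1.54, rel=0.01)

    @pytest.mark.parametrize("bad", [(-1, 1, 2), (1, 0, 2), (2, 3, 4)])
    def test_invalid_inputs_raise(self, bad):
        with pytest.raises(ValueError):
            lognormal_from_ci(*bad)


class TestGammaFromMeanSd:
    def test_shape_from_first_year_cost(self):
        spec = gamma_from_mean_sd(33402, 31930)
        assert spec.params[0] == pytest.approx(1.0943, abs=1e-4)

    def test_zero_sd_is_point_mass(self):
        spec = gamma_from_mean_sd(100, 0)
        assert spec.family == "fixed"
        assert spec.rvs(RNG) == 100

    def test_sampled_mean_recovers_input(self):
        spec = gamma_from_mean_sd(21112, 17350)
        draws = spec.rvs(RNG, 10**6)
        assert draws.mean() == pytest.approx(21112, rel=0.01)

    def test_nonpositive_mean_raises(self):
        with pytest.raises(ValueError):
            gamma_from_mean_sd(0, 10)


class TestBetaFromMeanSd:
    def test_method_of_moments_utility(self):
        spec = beta_from_mean_sd(0.94, 0.09)
        a, b = spec.params
        assert a == pytest.approx(5.605, abs=1e-3)
        assert b == pytest.approx(0.3578, abs=1e-3)

    def test_death_utility_is_point_mass_at_zero(self):
        spec = beta_from_mean_sd(0.0, 0.01)
        assert spec.family == "fixed"
        assert spec.rvs(RNG) == 0.0

    def test_infeasible_variance_warns_and_degrades(self):
        with pytest.warns(UserWarning):
            spec = beta_from_mean_sd(0.5, 0.9)
        assert spec.family == "fixed"
        assert spec.params[0] == 0.5

    def test_mean_outside_unit_interval_raises(self):
        with pytest.raises(ValueError):
            beta_from_mean_sd(1.5, 0.1)


def test_all_table_specs_recover_their_moments(params):
    """Every fitted PSA distribution reproduces its defining moments to 1%."""
    specs = [params.or_evt_spec()]
    specs += list(params.hr_mortality_specs().values())
    for table in params.cost_specs().values():
        specs += list(table.values())
    specs += list(params.utility_specs().values())
    rng = np.random.default_rng(4242)
    for spec in specs:
        draws = np.atleast_1d(spec.rvs(rng, 10**6))
        if spec.family == "lognormal":
            assert np.median(draws) == pytest.approx(spec.median(), rel=0.01)
        else:
            assert draws.mean() == pytest.approx(spec.mean(), rel=0.01, abs=1e-4)


class TestModelParameters:
    def test_defaults_match_published_values(self):
        p = ModelParameters()
        assert p.or_evt[0] == 1.67
        assert p.cost_evt == 9924.50
        assert p.wtp == 80000
        assert p.sens_diff == {"ICA": 0.08, "M1": 0.16, "M2": 0.16}

    def test_unknown_key_rejected(self):
        with pytest.raises(Exception):
            ModelParameters(not_a_parameter=1)

    def test_invalid_utility_rejected(self):
        with pytest.raises(Exception):
            ModelParameters(utilities={"mrs01": (1.5, 0.1)})

    def test_zero_wtp_accepted(self):
        assert ModelParameters(wtp=0.0).wtp == 0.0

    def test_yaml_round_trip(self, tmp_path):
        p = ModelParameters(wtp=75000, nni=4.3)
        path = tmp_path / "config.yaml"
        p.to_yaml(path)
        assert load_parameters(path) == p

    def test_empty_config_gives_defaults(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        assert load_parameters(path) == ModelParameters()

    def test_missing_fixture_named_in_error(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump({"life_table_csv": "/nope/lt.csv"}))
        with pytest.raises(FileNotFoundError, match="lt.csv"):
            load_parameters(path)

    def test_merged_levels_share_values(self, params):
        u = params.utility_by_state()
        hr = params.hr_mortality_by_state()
        assert u[0] == u[1] == 0.94
        assert hr[0] == hr[1] == 1.54
        assert u[6] == 0.0

    def test_cost_tables_inflated_to_start_year(self, params):
        raw = params.cost_tables_by_state(inflate=False)
        infl = params.cost_tables_by_state(inflate=True)
        factor = params.inflation.factor(2015, 2022)
        assert np.allclose(infl, raw * factor)
        assert raw[0, 3] == 82452

    def test_with_scaled_nested_and_flat(self, params):
        p2 = params.with_scaled("utilities.mrs2", 1.1)
        assert p2.utilities["mrs2"][0] == pytest.approx(0.88)
        assert p2.utilities["mrs2"][1] == params.utilities["mrs2"][1]
        p3 = params.with_scaled("cost_ctp", 0.9)
        assert p3.cost_ctp == pytest.approx(226.26)

    @pytest.mark.parametrize("name", ["sens_diff", "no_such", "utilities.mrs9"])
    def test_with_scaled_rejects_non_scalars(self, params, name):
        with pytest.raises(KeyError):
            params.with_scaled(name, 1.1)


class TestLifeTable:
    def test_q_monotone_in_age(self):
        lt = default_life_table()
        for sex in ("male", "female"):
            q = np.array([float(lt.q(a, sex, 2022)) for a in range(30, 106)])
            assert np.all(np.diff(q) >= 0)
            assert np.all((q >= 0) & (q <= 1))

    def test_life_expectancy_calibration(self):
        lt = default_life_table()
        assert life_expectancy(lt, 72, "female", 2022) == pytest.approx(14.0, abs=0.05)
        assert life_expectancy(lt, 72, "male", 2022) == pytest.approx(12.0, abs=0.05)

    def test_mortality_improvement_lowers_future_q(self):
        lt = default_life_table()
        assert float(lt.q(80, "male", 2030)) < float(lt.q(80, "male", 2022))

    def test_csv_round_trip(self, tmp_path):
        lt = default_life_table()
        path = tmp_path / "life.csv"
        lt.to_frame().to_csv(path, index=False)
        lt2 = LifeTable.from_csv(path)
        assert float(lt2.q(80, "female", 2022)) == pytest.approx(
            float(lt.q(80, "female", 2022))
        )

    def test_age_clamped_beyond_range(self):
        lt = default_life_table()
        assert float(lt.q(130, "male", 2022)) == float(lt.q(120, "male", 2022))


class TestInflationSeries:
    def test_same_year_factor_is_one(self):
        assert InflationSeries.default().factor(2020, 2020) == 1.0

    def test_two_years_at_two_percent(self):
        s = InflationSeries({2021: 0.02, 2022: 0.02})
        assert s.factor(2020, 2022) == pytest.approx(1.0404)

    def test_deflation_is_symmetric(self):
        s = InflationSeries({2021: -0.01, 2022: 0.03})
        assert s.factor(2020, 2022) * s.factor(2022, 2020) == pytest.approx(1.0)

    def test_uncovered_year_raises(self):
        with pytest.raises(KeyError):
            InflationSeries({2021: 0.02}).factor(2020, 2025)


class TestRecurrenceInputs:
    def test_baseline_carries_last_value_forward(self, params):
        assert params.recurrence_baseline_at(1) == 0.04
        assert params.recurrence_baseline_at(5) == 0.02
        assert params.recurrence_baseline_at(30) == 0.02
        with pytest.raises(ValueError):
            params.recurrence_baseline_at(0)

    def test_hr_recurrence_monotone_in_mrs_and_age(self, params):
        hr = params.hr_recurrence(np.array([70, 70, 70]), np.array([0, 3, 5]))
        assert hr[0] <= hr[1] <= hr[2]
        hr_age = params.hr_recurrence(np.array([50, 70, 80]), np.array([3, 3, 3]))
        assert hr_age[0] <= hr_age[1] <= hr_age[2]
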