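import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit
from scipy.stats import binom

from ctp_cea import (
    ModelParameters,
    build_arms,
    counterfactual_mrs,
    select_missed,
    shift_distribution_by_or,
    stratum_distributions,
    synthesize_cohort,
)
from ctp_cea.counterfactual import ArmAssignment

from conftest import make_cohort

RNG = np.random.default_rng(99)


def random_simplices(k, rng=RNG):
    d = rng.dirichlet(np.ones(7), size=k)
    return d


def brute_force_shift(dist, or_evt, preserve_death):
    """Independent oracle: per-cutpoint odds division on the CDF."""
    cum = np.cumsum(dist)
    cum[-1] = 1.0
    out = cum.copy()
    last = 4 if preserve_death else 5
    for k in range(last + 1):
        if 0 < cum[k] < 1:
            out[k] = expit(logit(cum[k]) - np.log(or_evt))
    return np.diff(np.concatenate(([0.0], np.maximum.accumulate(out))))


class TestShiftDistribution:
    def test_unit_or_is_identity(self):
        for dist in random_simplices(20):
            for preserve in (True, False):
                out = shift_distribution_by_or(dist, 1.0, preserve)
                np.testing.assert_allclose(out, dist, atol=1e-12)

    def test_hand_computed_cutpoint(self):
        # P(mRS <= 2) = 0.6: odds 1.5 / 1.67 = 0.8982 -> 0.4731
        dist = np.array([0, 0, 0.6, 0, 0, 0.4, 0.0])
        out = shift_distribution_by_or(dist, 1.67)
        assert np.cumsum(out)[2] == pytest.approx(0.4731, abs=1e-4)

    @pytest.mark.parametrize("preserve", [True, False])
    def test_matches_brute_force_oracle(self, preserve):
        for dist in random_simplices(50):
            for orv in (0.5, 1.3, 1.67, 3.0):
                out = shift_distribution_by_or(dist, orv, preserve)
                np.testing.assert_allclose(
                    out, brute_force_shift(dist, orv, preserve), atol=1e-12
                )
                assert out.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("preserve", [True, False])
    def test_composition_law(self, preserve):
        for dist in random_simplices(20):
            once = shift_distribution_by_or(
                shift_distribution_by_or(dist, 1.4, preserve), 1.2, preserve
            )
            combined = shift_distribution_by_or(dist, 1.4 * 1.2, preserve)
            np.testing.assert_allclose(once, combined, atol=1e-10)

    def test_removing_benefit_worsens_mean_mrs(self):
        levels = np.arange(7)
        for dist in random_simplices(50):
            out = shift_distribution_by_or(dist, 1.67)
            assert out @ levels >= dist @ levels - 1e-12

    def test_death_mass_preserved_by_default(self):
        for dist in random_simplices(20):
            out = shift_distribution_by_or(dist, 1.67, preserve_death=True)
            assert out[6] == pytest.approx(dist[6], abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            shift_distribution_by_or(np.full(7, 0.2), 1.67)
        with pytest.raises(ValueError):
            shift_distribution_by_or(np.full(7, 1 / 7), -1.0)

    @settings(max_examples=200, derandomize=True)
    @given(
        weights=st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=7, max_size=7
        ).filter(lambda w: sum(w) > 1e-6),
        or_evt=st.floats(0.1, 10.0),
        preserve=st.booleans(),
    )
    def test_shift_is_simplex_preserving_and_monotone(
        self, weights, or_evt, preserve
    ):
        dist = np.asarray(weights) / sum(weights)
        out = shift_distribution_by_or(dist, or_evt, preserve)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert (out >= -1e-12).all()
        levels = np.arange(7)
        if or_evt >= 1.0:
            assert out @ levels >= dist @ levels - 1e-9
        else:
            assert out @ levels <= dist @ levels + 1e-9


class TestCounterfactualMrs:
    def test_unit_or_is_identity_coupling(self):
        dist = np.array([0.1, 0.2, 0.25, 0.1, 0.1, 0.05, 0.2])
        mrs = RNG.integers(0, 7, 500)
        u = RNG.random(500).clip(1e-9, 1 - 1e-9)
        out = counterfactual_mrs(mrs, u, dist, 1.0)
        np.testing.assert_array_equal(out, mrs)

    def test_observed_death_stays_death(self):
        dist = np.array([0.1, 0.2, 0.25, 0.1, 0.1, 0.05, 0.2])
        out = counterfactual_mrs(np.full(50, 6), RNG.random(50), dist, 1.67)
        assert (out == 6).all()

    def test_counterfactual_never_better_than_observed(self):
        dist = np.array([0.1, 0.2, 0.25, 0.1, 0.1, 0.05, 0.2])
        mrs = RNG.integers(0, 7, 2000)
        u = RNG.random(2000).clip(1e-9, 1 - 1e-9)
        out = counterfactual_mrs(mrs, u, dist, 1.67)
        assert (out >= mrs).all()

    def test_survivors_stay_alive_when_death_preserved(self):
        dist = np.array([0.1, 0.2, 0.25, 0.1, 0.1, 0.05, 0.2])
        mrs = RNG.integers(0, 6, 2000)
        u = RNG.random(2000).clip(1e-9, 1 - 1e-9)
        out = counterfactual_mrs(mrs, u, dist, 1.67, preserve_death=True)
        assert (out <= 5).all()

    def test_marginal_matches_closed_form(self):
        """Coupled counterfactuals of a stratum reproduce the shifted
        distribution (total-variation distance < 0.01 at n = 1e5)."""
        dist = np.array([0.07, 0.18, 0.24, 0.11, 0.12, 0.06, 0.22])
        n = 100_000
        rng = np.random.default_rng(5)
        mrs = rng.choice(7, size=n, p=dist)
        u = rng.random(n).clip(1e-9, 1 - 1e-9)
        out = counterfactual_mrs(mrs, u, dist, 1.67)
        emp = np.bincount(out, minlength=7) / n
        target = shift_distribution_by_or(dist, 1.67)
        assert 0.5 * np.abs(emp - target).sum() < 0.01


class TestSelectMissed:
    def test_degenerate_probabilities(self, cohort701):
        zero = {"ICA": 0.0, "M1": 0.0, "M2": 0.0}
        one = {"ICA": 1.0, "M1": 1.0, "M2": 1.0}
        assert select_missed(cohort701, zero, seed=1) == set()
        assert select_missed(cohort701, one, seed=1) == set(cohort701.frame["id"])

    def test_binomial_band_for_m1(self):
        coh = make_cohort(np.zeros(367, dtype=int), occlusion="M1")
        missed = select_missed(coh, {"ICA": 0.08, "M1": 0.16, "M2": 0.16}, seed=2)
        lo = binom.ppf(0.005, 367, 0.16)
        hi = binom.ppf(0.995, 367, 0.16)
        assert lo <= len(missed) <= hi

    def test_invalid_probability_raises(self, cohort701):
        with pytest.raises(ValueError):
            select_missed(cohort701, {"ICA": 1.5, "M1": 0.1, "M2": 0.1}, seed=0)


class TestBuildArms:
    def test_zero_sensitivity_gain_keeps_arms_identical(self, cohort701):
        p = ModelParameters(sens_diff={"ICA": 0.0, "M1": 0.0, "M2": 0.0})
        arms = build_arms(cohort701, p, seed=3)
        assert not arms["missed"].any()
        np.testing.assert_array_equal(
            arms["mrs90_control"], arms["mrs90_treated"]
        )

    def test_unit_or_keeps_outcomes_identical(self, cohort701):
        p = ModelParameters(or_evt=(1.0, 1.0, 1.0))
        arms = build_arms(cohort701, p, seed=3)
        assert arms["missed"].any()
        np.testing.assert_array_equal(
            arms["mrs90_control"], arms["mrs90_treated"]
        )

    def test_control_arm_weakly_worse(self, cohort701, params):
        arms = build_arms(cohort701, params, seed=3)
        assert (arms["mrs90_control"] >= arms["mrs90_treated"]).all()
        assert arms["mrs90_control"].mean() >= arms["mrs90_treated"].mean()

    def test_detected_patients_unchanged(self, cohort701, params):
        arms = build_arms(cohort701, params, seed=3)
        kept = arms[~arms["missed"]]
        np.testing.assert_array_equal(
            kept["mrs90_control"], kept["mrs90_treated"]
        )

    def test_reproducible_from_seed(self, cohort701, params):
        a = build_arms(cohort701, params, seed=4)
        b = build_arms(cohort701, params, seed=4)
        assert a.equals(b)


def test_stratum_distributions_are_simplices(cohort701):
    dists = stratum_distributions(cohort701)
    for occ, d in dists.items():
        assert d.shape == (7,)
        assert d.sum() == pytest.approx(1.0)


def test_arm_assignment_invariant():
    with pytest.raises(ValueError):
        ArmAssignment(patient_id=1, missed=False, mrs90_treated=2, mrs90_control=4)
    ok = ArmAssignment(patient_id=1, missed=True, mrs90_treated=2, mrs90_control=4)
    assert ok.mrs90_control == 4
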