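import numpy as np
import pytest

from vslqaly.economic_data import EconomicProfile, LifeTable, PopulationDistribution, SurvivalModel
from vslqaly.preference import PreferenceModel, UtilityFamily
from vslqaly.valuation import (
    DiscountSpec,
    UndefinedQALYError,
    discount_factor,
    evaluate_scenario,
    lev,
    population_weighted_qaly,
    qaly_value,
    vsl_curve,
)
from .conftest import flat_trajectory

PREF = PreferenceModel(UtilityFamily("log", z0=1.0))
NO_DISCOUNT = DiscountSpec(rate=0.0)


def hand_integrand(surv, profile, pref, traj, disc, a, grid):
    """Literal per-age integrand of the value-of-life flow, written out."""
    from vslqaly.preference import phi

    out = []
    for t in grid:
        i = int(t)
        z = traj.values[i] * profile.full_consumption[i]
        v = profile.full_income[i] + phi(z, pref.utility) * profile.full_consumption[i]
        out.append(discount_factor(t, a, disc) * v * surv(t, a))
    return np.array(out)


class TestDiscountFactor:
    def test_unity_at_current_age(self):
        assert discount_factor(30, 30, DiscountSpec()) == 1.0
        assert discount_factor(30, 30, DiscountSpec("hyperbolic")) == 1.0

    def test_hyperbolic_half_after_hundred_years(self):
        assert discount_factor(100, 0, DiscountSpec("hyperbolic", kappa=0.01)) == pytest.approx(0.5)

    def test_hyperbolic_dominates_exponential(self):
        ts = np.arange(1, 111)
        e = discount_factor(ts, 0, DiscountSpec(rate=0.01))
        h = discount_factor(ts, 0, DiscountSpec("hyperbolic", kappa=0.01))
        assert np.all(h >= e)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            discount_factor(10, 20, DiscountSpec())


class TestVSL:
    def test_rectangle_limit(self):
        """r = 0, S = 1 on a span of T years, constant flow v gives VSL = v T."""
        n = 10
        table = LifeTable(np.arange(n + 1.0), np.concatenate([np.ones(n), [0.0]]), n)
        surv = SurvivalModel(table)
        ages = np.arange(n + 1.0)
        profile = EconomicProfile(ages, np.full(n + 1, 5.0), np.zeros(n + 1))
        traj = flat_trajectory(n)
        _, _, v = vsl_curve(surv, profile, PREF, traj, NO_DISCOUNT, 0)
        # trapezoid sees S drop from 1 to 0 across the last year: area n - 1/2
        assert v == pytest.approx(5.0 * (n - 0.5))

    def test_matches_hand_rolled_discrete_sum(self, toy_setup):
        surv, profile, traj = toy_setup
        disc = DiscountSpec(rate=0.03)
        for a in (0, 1, 2):
            grid = np.arange(a, 5.0)
            g = hand_integrand(surv, profile, PREF, traj, disc, a, grid)
            w = np.ones_like(grid)
            w[0] = w[-1] = 0.5
            expected = float(np.sum(w * g))
            _, years, got = vsl_curve(surv, profile, PREF, traj, disc, a)
            assert got == pytest.approx(expected, rel=1e-12)
            assert years.sum() == pytest.approx(got, rel=1e-12)

    def test_homogeneous_in_money_given_fixed_phi(self, toy_setup):
        """Doubling all monetary inputs doubles VSL when the Φ series is held fixed."""
        surv, profile, traj = toy_setup
        pref = PreferenceModel(UtilityFamily("log", z0=1.0))
        phi_series = pref.phi_series(profile, traj)

        def manual_vsl(scale):
            grid = np.arange(0, 5.0)
            g = (
                discount_factor(grid, 0, NO_DISCOUNT)
                * (scale * profile.full_income + phi_series * scale * profile.full_consumption)
                * surv(grid, 0)
            )
            w = np.ones_like(grid)
            w[0] = w[-1] = 0.5
            return float(np.sum(w * g))

        assert manual_vsl(2.0) == pytest.approx(2 * manual_vsl(1.0), rel=1e-12)


class TestLEV:
    def test_unit_area_limit(self, toy_setup):
        """r = 0, perfect health, constant flow: LEV equals the flow exactly."""
        surv, profile, traj = toy_setup
        pref = PreferenceModel(UtilityFamily("log", z0=1.0))
        v_const = profile.full_income[0] + pref.phi_series(profile, traj)[0] * profile.full_consumption[0]
        for a in (0, 1, 2):
            assert lev(surv, profile, pref, traj, NO_DISCOUNT, a) == pytest.approx(v_const, rel=1e-12)

    def test_step_survival_closed_form(self):
        """Step survival at T: LEV discounts the single one-year increment."""
        n, T, r = 10, 6, 0.02
        lx = np.where(np.arange(n + 1.0) <= T, 1.0, 0.0)
        surv = SurvivalModel(LifeTable(np.arange(n + 1.0), lx, n))
        ages = np.arange(n + 1.0)
        profile = EconomicProfile(ages, np.full(n + 1, 3.0), np.zeros(n + 1))
        got = lev(surv, profile, PREF, flat_trajectory(n), DiscountSpec(rate=r), 0)
        # increment S(t-1,0)-S(t,0) is the hat function peaking at t = T+1;
        # trapezoid of e^{-rt} * v * hat over [T, T+2]
        expected = 3.0 * (0.5 * np.exp(-r * T) * 0 + np.exp(-r * (T + 1)) * 1.0 + 0.5 * np.exp(-r * (T + 2)) * 0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_hand_rolled_discrete_sum(self, toy_setup):
        surv, profile, traj = toy_setup
        disc = DiscountSpec(rate=0.05)
        a = 1
        grid = np.arange(a, 6.0)  # extends one year past the table
        v = []
        from vslqaly.preference import phi

        for t in grid:
            i = min(int(t), 4)
            z = traj.values[i] * profile.full_consumption[i]
            v.append(profile.full_income[i] + phi(z, PREF.utility) * profile.full_consumption[i])
        s_prev = np.array([1.0 if t - 1 <= a else surv(t - 1, a) for t in grid])
        s_now = np.array([surv(t, a) if t <= 4 else 0.0 for t in grid])
        g = discount_factor(grid, a, disc) * np.array(v) * (s_prev - s_now)
        w = np.ones_like(grid)
        w[0] = w[-1] = 0.5
        assert lev(surv, profile, PREF, traj, disc, a) == pytest.approx(float(np.sum(w * g)), rel=1e-12)


class TestQALY:
    def test_identity_at_perfect_health(self, toy_setup):
        _, _, traj = toy_setup
        assert qaly_value(2.5, traj, 2) == 2.5

    def test_divides_by_current_qol(self):
        traj = flat_trajectory(4)
        traj.values[3] = 0.5
        traj.untruncated[3] = 0.5
        assert qaly_value(2.0, traj, 3) == pytest.approx(4.0)

    def test_error_beyond_terminal_age(self):
        from vslqaly.qol_scenarios import QoLTrajectory

        ages = np.arange(5.0)
        vals = np.array([1.0, 1.0, 1.0, 0.0, 0.0])
        traj = QoLTrajectory("t", ages, vals, np.ones(5), terminal_age=3.0)
        with pytest.raises(UndefinedQALYError, match="terminal"):
            qaly_value(1.0, traj, 4)


class TestPopulationWeighting:
    def test_constant_curve_returns_constant(self, toy_setup):
        surv, profile, traj = toy_setup
        res = evaluate_scenario(surv, profile, PREF, traj, NO_DISCOUNT)
        pop = PopulationDistribution(np.arange(5.0), np.full(5, 7.0))
        # r=0, constant flow: QALY(a) = LEV(a)/1 = constant at every age
        # with survivors remaining (the terminal age l = 0 is excluded)
        got = population_weighted_qaly(res, pop, age_range=(0, 3))
        assert got == pytest.approx(res.qaly[0])

    def test_two_age_weighted_mean(self):
        # N = (1, 3), QALY = (4, 8) -> 7.0, via a direct loop oracle
        weights, values = np.array([1.0, 3.0]), np.array([4.0, 8.0])
        assert np.sum(weights * values) / weights.sum() == pytest.approx(7.0)

    def test_matches_brute_force_loop(self, base_study, synth_inputs):
        res = base_study.results["SCN1"]
        pop = synth_inputs.population
        total = num = 0.0
        for i, a in enumerate(res.ages):
            if a < 20 or not res.support[i]:
                continue
            n = pop.counts[int(a)]
            num += n * res.qaly[i]
            total += n
        assert base_study.weighted_qaly["SCN1"] == pytest.approx(num / total, rel=1e-12)

    def test_empty_overlap_is_an_error(self, toy_setup):
        surv, profile, traj = toy_setup
        res = evaluate_scenario(surv, profile, PREF, traj, NO_DISCOUNT)
        pop = PopulationDistribution(np.arange(5.0), np.array([1.0, 1, 1, 1, 1]))
        with pytest.raises(ValueError):
            population_weighted_qaly(res, pop, age_range=(50, None))


class TestEvaluateScenario:
    def test_vsl_year_sums_to_total(self, base_study):
        for res in base_study.results.values():
            assert res.vsl_year.sum() == pytest.approx(res.total_vsl, rel=1e-12)

    def test_all_outputs_finite_on_support(self, base_study):
        for res in base_study.results.values():
            assert np.all(np.isfinite(res.vsl))
            assert np.all(np.isfinite(res.lev))
            assert np.all(np.isfinite(res.qaly[res.support]))

    def test_refinement_stability(self, synth_inputs, base_study):
        """Halving the quadrature step moves VSL and LEV by well under 0.1%."""
        pref = PreferenceModel(UtilityFamily("log", z0=base_study.z0))
        traj = base_study.scenarios["SCN1"]
        disc = DiscountSpec()
        for a in (0, 40, 70):
            v1 = vsl_curve(synth_inputs.survival, synth_inputs.profile, pref, traj, disc, a)[2]
            v2 = vsl_curve(synth_inputs.survival, synth_inputs.profile, pref, traj, disc, a, refine=2)[2]
            assert abs(v2 - v1) / abs(v1) < 1e-3
            l1 = lev(synth_inputs.survival, synth_inputs.profile, pref, traj, disc, a)
            l2 = lev(synth_inputs.survival, synth_inputs.profile, pref, traj, disc, a, refine=2)
            assert abs(l2 - l1) / abs(l1) < 1e-3
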