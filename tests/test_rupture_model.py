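"""Bell kinetics, piecewise-exponential survival, sweeps, parameter recovery."""

import math

import numpy as np
import pytest
from scipy import stats

from depforce import ramp_control as rc
from depforce import rupture_model as rm


def make_schedule(rate=4.0, f_max=16.0, n_steps=100):
    return rc.design_ramp(rate, 1.0, math.sqrt(f_max), n_steps)


class TestBellRate:
    def test_zero_force_gives_k0(self, bond):
        assert rm.bell_rate(0.0, bond) == pytest.approx(bond.k0)

    def test_zero_barrier_distance_is_force_independent(self):
        p = rm.BellParameters(k0=2.0, x_dagger=0.0)
        f = np.array([0.0, 10.0, 1000.0])
        np.testing.assert_allclose(rm.bell_rate(f, p), 2.0)

    def test_doubling_at_kbt_ln2(self):
        p = rm.BellParameters(k0=1.0, x_dagger=1.0)
        f = p.kbt * math.log(2.0) / p.x_dagger
        assert rm.bell_rate(f, p) == pytest.approx(2.0, rel=1e-12)

    def test_overflow_guard_warns(self):
        p = rm.BellParameters(k0=1.0, x_dagger=1.0)
        with pytest.warns(RuntimeWarning, match="capped"):
            out = rm.bell_rate(1e7, p)
        assert np.isfinite(out)

    def test_negative_force_rejected(self, bond):
        with pytest.raises(ValueError):
            rm.bell_rate(-1.0, bond)


class TestSurvival:
    def test_constant_hazard_is_exact_exponential(self):
        p = rm.BellParameters(k0=0.5, x_dagger=0.0)
        sched = make_schedule()
        curve = rm.survival_under_schedule(sched, p, n_points=200)
        np.testing.assert_allclose(curve.survival, np.exp(-0.5 * curve.times),
                                   rtol=1e-12)

    def test_single_step_schedule_is_single_exponential(self, bond):
        sched = make_schedule(n_steps=1)
        curve = rm.survival_under_schedule(sched, bond, n_points=50)
        # before the jump the bond feels zero force: hazard k0
        np.testing.assert_allclose(curve.survival, np.exp(-bond.k0 * curve.times),
                                   rtol=1e-12)

    def test_monotone_and_bounded(self, bond):
        curve = rm.survival_under_schedule(make_schedule(), bond, n_points=500)
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 0)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_staircase_mode_converges_to_evans_ritchie(self, bond):
        # n_steps -> inf: the most probable rupture force approaches
        # F* = (kBT/x) ln(r x / (k0 kBT)) of the continuous ramp
        rate = 4.0
        f_star = rm.evans_ritchie_force(rate, bond)
        f_max = rm.required_f_max(rate, bond, survival_tail=1e-8)
        sched = make_schedule(rate, f_max, n_steps=4000)
        curve = rm.survival_under_schedule(sched, bond)
        # density over the staircase: mass per hold / force step
        pdf = -np.diff(curve.survival)
        forces = sched.step_forces[:-1]
        mode = forces[np.argmax(pdf)]
        assert mode == pytest.approx(f_star, rel=0.02)


class TestSampling:
    def test_same_seed_identical(self, bond):
        sched = make_schedule()
        a = rm.sample_rupture_forces(sched, bond, 500, 42)
        b = rm.sample_rupture_forces(sched, bond, 500, 42)
        np.testing.assert_array_equal(a.rupture_forces, b.rupture_forces)
        np.testing.assert_array_equal(a.rupture_times, b.rupture_times)

    def test_monte_carlo_matches_closed_form_ks(self, bond):
        sched = make_schedule(4.0, f_max=rm.required_f_max(4.0, bond))
        samples = rm.sample_rupture_forces(sched, bond, 10_000, 3)
        curve = rm.survival_under_schedule(sched, bond)
        s_end = curve.survival[-1]
        cdf = lambda t: (1.0 - curve.at(t)) / (1.0 - s_end)
        d = stats.kstest(samples.uncensored_times, cdf).statistic
        crit_1pct = 1.63 / math.sqrt(samples.uncensored_times.size)
        assert d < crit_1pct

    def test_vanishing_off_rate_censors_everything(self):
        p = rm.BellParameters(k0=1e-15, x_dagger=0.1)
        sched = make_schedule()
        samples = rm.sample_rupture_forces(sched, p, 50, 0)
        assert samples.n_censored == 50
        np.testing.assert_allclose(samples.rupture_forces, sched.f_max)

    def test_forces_within_schedule_range(self, bond):
        sched = make_schedule()
        s = rm.sample_rupture_forces(sched, bond, 1000, 5)
        assert np.all(s.rupture_forces >= 0)
        assert np.all(s.rupture_forces <= sched.f_max)

    def test_csv_records_seed(self, tmp_path, bond):
        s = rm.sample_rupture_forces(make_schedule(), bond, 10, 9)
        path = tmp_path / "samples.csv"
        s.to_csv(path)
        text = path.read_text()
        assert "# seed=9" in text
        assert "censored" in text


class TestClosedFormMean:
    def test_matches_monte_carlo(self, bond):
        sched = make_schedule(4.0, f_max=rm.required_f_max(4.0, bond))
        mean_cf, _ = rm.mean_rupture_force(sched, bond)
        samples = rm.sample_rupture_forces(sched, bond, 20_000, 17)
        se = samples.uncensored_forces.std() / math.sqrt(20_000)
        assert mean_cf == pytest.approx(samples.uncensored_forces.mean(), abs=4 * se)

    def test_staircase_error_decreases_with_steps(self, bond):
        rate = 4.0
        f_max = rm.required_f_max(rate, bond)
        cont = rm.continuous_mean_force(rate, bond, f_max)
        errs = []
        for n in (5, 50, 500):
            sched = make_schedule(rate, f_max, n)
            errs.append(abs(rm.mean_rupture_force(sched, bond)[0] - cont))
        assert errs[0] > errs[1] > errs[2]


class TestLoadingRateSweep:
    def test_mean_force_monotone_over_instrument_range(self, bond):
        rates = np.geomspace(4e-2, 3e3, 6)
        df = rm.loading_rate_sweep(rates, bond, n_beads=400, seed=2)
        means = df["closed_form_mean_pN"].to_numpy()
        assert np.all(np.diff(means) > 0)

    def test_high_rate_slope_approaches_kbt_over_x(self, bond):
        # closed-form means vs ln(rate) at high rates: slope -> kBT / x_dagger
        rates = np.geomspace(1e2, 1e4, 5)
        means = []
        for r in rates:
            sched = rm.schedule_for_rate(r, bond, n_steps=400)
            means.append(rm.mean_rupture_force(sched, bond)[0])
        slope = stats.linregress(np.log(rates), means).slope
        assert slope == pytest.approx(bond.kbt / bond.x_dagger, rel=0.05)

    def test_zero_barrier_distance_gives_rate_independent_times(self):
        # with x_dagger = 0 the rupture *time* law is Exp(k0) whatever the
        # ramp; forces then simply scale with the rate
        p = rm.BellParameters(k0=0.5, x_dagger=0.0)
        t_means = []
        for rate in (0.1, 10.0, 1000.0):
            sched = rm.schedule_for_rate(rate, p, n_steps=100)
            samples = rm.sample_rupture_forces(sched, p, 4000, 8)
            t_means.append(samples.uncensored_times.mean())
        t_means = np.array(t_means)
        np.testing.assert_allclose(t_means, 1 / 0.5, rtol=0.1)

    def test_all_censored_rate_flagged(self):
        # force ceiling far below where this stiff bond ever ruptures
        p = rm.BellParameters(k0=1e-12, x_dagger=0.01)
        df = rm.loading_rate_sweep([1.0], p, n_beads=20, seed=0, f_max=5.0)
        assert bool(df["all_censored"].iloc[0])
        assert math.isnan(df["mean_force_pN"].iloc[0])


class TestStepCountSensitivity:
    def test_instrument_step_range_is_stable(self, bond):
        df = rm.step_count_sensitivity(4.0, [400, 200, 100, 20], bond)
        assert df.attrs["relative_spread"] < 0.02

    def test_single_step_deviates_most_from_continuous(self, bond):
        rate = 4.0
        f_max = rm.required_f_max(rate, bond)
        cont = rm.continuous_mean_force(rate, bond, f_max)
        df = rm.step_count_sensitivity(rate, [1, 20, 400], bond, f_max=f_max)
        dev = (df["closed_form_mean_pN"] - cont).abs().to_numpy()
        assert dev[0] == dev.max()
        assert dev[0] > 5 * dev[2]

    def test_same_step_count_same_seed_reproduces(self, bond):
        a = rm.step_count_sensitivity(4.0, [100, 100], bond, n_beads=200, seed=4)
        sampled = a["sampled_mean_pN"].to_numpy()
        # identical N but independent sub-streams: closed form identical
        cf = a["closed_form_mean_pN"].to_numpy()
        assert cf[0] == cf[1]
        b = rm.step_count_sensitivity(4.0, [100, 100], bond, n_beads=200, seed=4)
        np.testing.assert_array_equal(sampled, b["sampled_mean_pN"].to_numpy())


class TestFitBellParameters:
    def test_recovers_barrier_distance_within_ten_percent(self, bond):
        rates = np.geomspace(4e-2, 3e3, 6)
        sweep = rm.loading_rate_sweep(rates, bond, n_steps=100, n_beads=1000, seed=7)
        fit = rm.fit_bell_parameters(sweep)
        assert not fit.degenerate
        assert fit.params.x_dagger == pytest.approx(bond.x_dagger, rel=0.10)

    def test_noiseless_closed_form_input_recovers_exactly(self, bond):
        # feed Evans-Ritchie forces directly: regression must return the
        # generating parameters to numerical precision
        import pandas as pd

        rates = np.geomspace(1.0, 1e4, 8)
        table = pd.DataFrame({
            "loading_rate_pN_per_s": rates,
            "mode_force_pN": [rm.evans_ritchie_force(r, bond) for r in rates],
        })
        fit = rm.fit_bell_parameters(table)
        assert fit.params.x_dagger == pytest.approx(bond.x_dagger, rel=1e-9)
        assert fit.params.k0 == pytest.approx(bond.k0, rel=1e-6)

    def test_force_insensitive_kinetics_flagged_degenerate(self):
        # x_dagger = 0 data: characteristic force scales linearly with the
        # rate itself, which the fitter must flag instead of inverting
        import pandas as pd

        rates = np.geomspace(1.0, 1e4, 6)
        table = pd.DataFrame({
            "loading_rate_pN_per_s": rates,
            "mode_force_pN": rates / 0.5,  # F = r * E[t], t ~ Exp(k0=0.5)
        })
        fit = rm.fit_bell_parameters(table)
        assert fit.degenerate
        assert fit.params.x_dagger == 0.0

    def test_non_monotone_table_rejected(self):
        import pandas as pd

        table = pd.DataFrame({
            "loading_rate_pN_per_s": [1.0, 100.0, 10000.0],
            "mode_force_pN": [10.0, 5.0, 20.0],
        })
        with pytest.raises(ValueError, match="non-decreasing"):
            rm.fit_bell_parameters(table)

    def test_narrow_rate_span_rejected(self, bond):
        import pandas as pd

        table = pd.DataFrame({
            "loading_rate_pN_per_s": [1.0, 2.0, 4.0],
            "mode_force_pN": [1.0, 2.0, 3.0],
        })
        with pytest.raises(ValueError, match="decades"):
            rm.fit_bell_parameters(table)
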