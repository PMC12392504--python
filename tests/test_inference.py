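"""Tests of the drift-field estimation and phase-portrait machinery.

The analytic oracles are classical planar systems: a damped linear
oscillator (globally stable spiral), the van der Pol oscillator (limit
cycle), a damped double-well (bistable), and pure linear friction
(stationary line of equilibria).
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from phasecell import (StreamlineSettings, classify_phase_portrait,
                       drift_field_from_function, estimate_drift_field,
                       finite_difference_kinematics,
                       implied_friction_coefficient, integrate_streamlines,
                       kinematics_from_runs)
from phasecell.inference import (KinematicsSamples, bootstrap_inference,
                                 increment_autocorrelation)
from phasecell.synthetic_sde import SDEModelSpec, simulate_sde


def make_samples(rng, n, drift, x_range=(-30, 30), v_range=(-2, 2),
                 noise=0.3):
    """Direct (x, v, a) draws with a = F*(x, v) + independent noise."""
    x = rng.uniform(*x_range, n)
    v = rng.uniform(*v_range, n)
    a = drift(x, v) + noise * rng.standard_normal(n)
    return KinematicsSamples(x=x, v=v, a=a, run_id=np.zeros(n, int),
                             dt_sample=1.0)


class TestFiniteDifferences:
    def test_constant_linear_quadratic(self):
        t = np.arange(0.0, 60.0, 1.0)
        const = finite_difference_kinematics(t, np.full_like(t, 7.0), 10.0)
        assert np.allclose(const.v, 0.0) and np.allclose(const.a, 0.0)
        lin = finite_difference_kinematics(t, 0.8 * t, 10.0)
        assert np.allclose(lin.v, 0.8) and np.allclose(lin.a, 0.0)
        g = 0.04
        quad = finite_difference_kinematics(t, 0.5 * g * t ** 2, 10.0)
        assert np.allclose(quad.a, g)   # second difference exact

    def test_index_pairing_is_leading(self):
        t = np.arange(0.0, 50.0, 10.0)
        x = np.array([0.0, 1.0, 3.0, 6.0, 10.0])
        s = finite_difference_kinematics(t, x, 10.0)
        assert np.allclose(s.x, x[:-2])
        assert np.allclose(s.v, np.diff(x)[:-1] / 10.0)

    def test_dt_sample_must_divide(self):
        t = np.arange(0.0, 60.0, 1.0)
        with pytest.raises(ValueError):
            finite_difference_kinematics(t, t, 2.5)
        with pytest.raises(ValueError):
            finite_difference_kinematics(t[:2], t[:2], 1.0)


class TestDriftField:
    def test_zero_acceleration_gives_zero_field(self):
        rng = np.random.default_rng(0)
        s = make_samples(rng, 5000, lambda x, v: 0.0 * x, noise=0.0)
        f = estimate_drift_field(s, np.linspace(-30, 30, 7),
                                 np.linspace(-2, 2, 7), min_count=5)
        assert np.allclose(f.F[f.mask], 0.0)

    def test_conditional_mean_and_noise_split(self):
        """Interleaved a=±1 samples in one bin: F=0 there, σ-estimate=1."""
        n = 400
        x = np.zeros(n)
        v = np.zeros(n)
        a = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        s = KinematicsSamples(x=x, v=v, a=a, run_id=np.zeros(n, int),
                              dt_sample=1.0)
        f = estimate_drift_field(s, np.array([-1.0, 1.0]),
                                 np.array([-1.0, 1.0]), min_count=10)
        assert f.F[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert f.noise[0, 0] == pytest.approx(1.0, rel=1e-6)

    def test_ou_slope_recovery_from_direct_samples(self):
        rng = np.random.default_rng(1)
        xi = 0.2
        s = make_samples(rng, 100_000, lambda x, v: -xi * v)
        f = estimate_drift_field(s, np.linspace(-30, 30, 13),
                                 np.linspace(-2, 2, 31), min_count=20)
        # slope of F(0, v) against v
        mid = len(f.x_centers) // 2
        col = f.F[mid]
        good = np.isfinite(col)
        slope = np.polyfit(f.v_centers[good], col[good], 1)[0]
        assert slope == pytest.approx(-xi, rel=0.1)

    def test_rms_error_decreases_with_samples(self):
        xi = 0.2
        errs = []
        for n, seed in ((4000, 3), (32000, 4)):
            rng = np.random.default_rng(seed)
            s = make_samples(rng, n, lambda x, v: -xi * v)
            f = estimate_drift_field(s, np.linspace(-30, 30, 7),
                                     np.linspace(-2, 2, 13), min_count=10)
            ref = -xi * f.v_centers[None, :]
            err = np.sqrt(np.nanmean(
                np.where(f.mask, (f.F - ref) ** 2, np.nan)))
            errs.append(err)
        assert errs[1] < errs[0]

    def test_undersampled_field_raises(self):
        rng = np.random.default_rng(0)
        s = make_samples(rng, 10, lambda x, v: 0 * x)
        with pytest.raises(ValueError):
            estimate_drift_field(s, np.linspace(-30, 30, 7),
                                 np.linspace(-2, 2, 7), min_count=50)


class TestStreamlines:
    def damped_field(self):
        return drift_field_from_function(
            lambda x, v: -x - 0.5 * v,
            np.linspace(-3, 3, 31), np.linspace(-3, 3, 31))

    def test_damped_oscillator_all_terminate_at_origin(self):
        field = self.damped_field()
        portrait = integrate_streamlines(
            field, StreamlineSettings(dt=0.01, max_steps=50_000))
        # corner seeds spiral out of the finite lattice; the rest reach 0
        assert len(portrait.terminal_points) >= 0.75 * len(
            portrait.streamlines)
        assert np.all(np.hypot(portrait.terminal_points[:, 0],
                               portrait.terminal_points[:, 1]) < 0.3)
        # oracle: brute-force ODE integration reaches the same fixed point
        sol = solve_ivp(lambda t, y: [y[1], -y[0] - 0.5 * y[1]],
                        (0, 100), [2.0, 1.5], rtol=1e-8)
        assert np.hypot(*sol.y[:, -1]) < 1e-3

    def test_pure_growth_leaves_domain(self):
        field = drift_field_from_function(
            lambda x, v: v, np.linspace(-3, 3, 21), np.linspace(-3, 3, 21))
        portrait = integrate_streamlines(
            field, StreamlineSettings(dt=0.01, max_steps=10_000))
        i = np.argmin(np.hypot(
            portrait.diagnostics["seeds"][:, 0] - 0.0,
            portrait.diagnostics["seeds"][:, 1] - 2.0))
        assert portrait.diagnostics["terminals_per_seed"][i] is None
        assert not portrait.cycling[i]

    def test_van_der_pol_streamlines_cycle_bounded(self):
        field = drift_field_from_function(
            lambda x, v: 1.0 * (1 - x ** 2) * v - x,
            np.linspace(-4, 4, 41), np.linspace(-4, 4, 41))
        portrait = integrate_streamlines(
            field, StreamlineSettings(dt=0.01, max_steps=20_000))
        assert portrait.cycling.mean() > 0.5
        for line, cyc in zip(portrait.streamlines, portrait.cycling):
            if cyc:
                tail = line[-1000:]
                assert np.all(np.abs(tail) < 4.0)

    def test_masked_bins_are_never_read(self):
        """A hole in the field's support stops streamlines rather than
        being interpolated across."""
        xe = np.linspace(-3, 3, 31)
        ve = np.linspace(-3, 3, 31)
        field = drift_field_from_function(lambda x, v: -x - 0.5 * v, xe, ve)
        # mask a vertical band: counts below threshold
        field.counts[12:18, :] = 0
        field.min_count = 1
        portrait = integrate_streamlines(
            field, StreamlineSettings(dt=0.01, max_steps=20_000))
        band = (field.x_centers[12] - 0.2, field.x_centers[17] + 0.2)
        for line in portrait.streamlines:
            inside = (line[:, 0] > band[0] + 0.25) & (
                line[:, 0] < band[1] - 0.25)
            assert not inside.any()


class TestClassifier:
    def classify(self, func, x_span, v_span, hints=None, dt=0.01,
                 max_steps=30_000):
        field = drift_field_from_function(
            func, np.linspace(*x_span, 37), np.linspace(*v_span, 31))
        portrait = integrate_streamlines(
            field, StreamlineSettings(dt=dt, max_steps=max_steps))
        return classify_phase_portrait(portrait, field, hints)

    def test_van_der_pol_is_limit_cycle(self):
        p = self.classify(lambda x, v: (1 - x ** 2) * v - x,
                          (-4, 4), (-4, 4))
        assert p.label == "limit_cycle"

    def test_damped_double_well_is_bistable(self):
        x0, k, xi = 20.0, 1e-4, 0.2
        p = self.classify(
            lambda x, v: -4 * k * x * (x ** 2 - x0 ** 2) - xi * v,
            (-30, 30), (-3, 3))
        assert p.label == "bistable"
        fp = np.array(p.diagnostics["fixed_points"])
        assert sorted(np.round(fp[:, 0] / 10).astype(int) * 10) == [-20, 20]

    def test_pure_linear_friction_is_stationary(self):
        p = self.classify(lambda x, v: -0.2 * v + 0 * x, (-40, 40), (-2, 2))
        assert p.label == "stationary"

    def test_bistable_separatrix_between_groups(self):
        x0, k, xi = 20.0, 1e-4, 0.2
        p = self.classify(
            lambda x, v: -4 * k * x * (x ** 2 - x0 ** 2) - xi * v,
            (-30, 30), (-3, 3))
        assert len(p.separatrices) >= 1


class TestDiscretizationCorrection:
    def test_increment_autocorrelation_limits(self):
        assert increment_autocorrelation(1e-8) == pytest.approx(1.0,
                                                                abs=1e-6)
        assert increment_autocorrelation(50.0) < 0.02
        # small-u expansion 1 - 2u/3
        assert increment_autocorrelation(0.01) == pytest.approx(
            1 - 2 * 0.01 / 3, abs=1e-4)

    def test_round_trip_slope_to_friction(self):
        xi, dt = 0.2, 10.0
        rho = increment_autocorrelation(xi * dt)
        slope = (rho - 1.0) / dt
        assert implied_friction_coefficient(slope, dt) == pytest.approx(
            xi, rel=1e-6)

    def test_out_of_range_slope_rejected(self):
        with pytest.raises(ValueError):
            implied_friction_coefficient(0.01, 10.0)
        with pytest.raises(ValueError):
            implied_friction_coefficient(-0.11, 10.0)


class TestBootstrap:
    def test_identical_trajectories_give_identical_portrait(self):
        spec = SDEModelSpec(name="ou")
        tset = simulate_sde(spec, 1, 600.0, 0.05, seed=5)
        runs = [tset.runs[0]] * 8
        out = bootstrap_inference(runs, B=5, base_seed=0, dt_sample=10.0,
                                  n_x=8, n_v=8, min_count=5)
        assert len(out["labels"]) == 1

    def test_zero_resamples_empty_summary(self):
        spec = SDEModelSpec(name="ou")
        tset = simulate_sde(spec, 2, 300.0, 0.05, seed=5)
        out = bootstrap_inference(tset.runs, B=0, base_seed=0)
        assert out["labels"] == {} and out["B"] == 0

    def test_ou_set_classified_stationary_in_most_resamples(self):
        spec = SDEModelSpec(name="ou", noise=0.4)
        tset = simulate_sde(spec, 200, 2880.0, 0.05, seed=11)
        out = bootstrap_inference(tset.runs, B=50, base_seed=3,
                                  dt_sample=10.0, n_x=24, n_v=24,
                                  min_count=10)
        freq = out["label_frequency"]
        assert freq.get("stationary", 0.0) >= 0.9
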