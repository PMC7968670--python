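"""The model family: critical density, endemic fraction, detection ratios, ODE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cultepi import (
    ModelParams,
    critical_density,
    detection_ratio_epidemiological,
    detection_ratio_null,
    detection_ratio_proportional,
    endemic_fraction,
    simulate_sir,
)


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(gamma=0, zeta=1e-5),
            dict(gamma=-1, zeta=1e-5),
            dict(gamma=3, zeta=0),
            dict(gamma=3, zeta=1e-5, epsilon=1.0),
            dict(gamma=3, zeta=1e-5, epsilon=-0.1),
            dict(gamma=3, zeta=1e-5, phi=0),
        ],
    )
    def test_invariants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)


class TestCriticalDensity:
    @pytest.mark.parametrize(
        "gamma, phi, expected",
        [(3.0, 2.0, 9.0), (1.0, 2.0, 1.0), (1.0, 5.5, 1.0), (2.0, 3.0, 8.0)],
    )
    def test_power_law(self, gamma, phi, expected):
        params = ModelParams(gamma=gamma, zeta=1.0, phi=phi)
        assert critical_density(params) == pytest.approx(expected)

    def test_published_full_data_threshold(self):
        """gamma chosen as sqrt(12.27) yields the 12.27 /100km^2 threshold."""
        params = ModelParams(gamma=3.5029, zeta=1e-5, phi=2.0)
        assert critical_density(params) == pytest.approx(12.27, abs=0.01)


class TestEndemicFraction:
    def test_zero_at_and_below_threshold(self, default_params):
        assert endemic_fraction(9.0, default_params) == 0.0
        assert endemic_fraction(4.0, default_params) == 0.0
        assert endemic_fraction(0.0, default_params) == 0.0

    def test_closed_form_above_threshold(self, default_params):
        assert endemic_fraction(36.0, default_params) == pytest.approx(0.5)

    @given(
        rho=st.floats(0, 1e4),
        gamma=st.floats(0.1, 6),
        phi=st.floats(0.5, 6),
    )
    @settings(max_examples=200, deadline=None)
    def test_range_and_continuity(self, rho, gamma, phi):
        params = ModelParams(gamma=gamma, zeta=1.0, phi=phi)
        val = endemic_fraction(rho, params)
        assert 0.0 <= val < 1.0
        # continuity at the threshold: value just above rho* is near 0
        rho_star = critical_density(params)
        assert endemic_fraction(rho_star * (1 + 1e-9), params) < 1e-6

    def test_monotone_in_density(self, default_params):
        rho = np.linspace(0, 200, 2001)
        vals = endemic_fraction(rho, default_params)
        assert np.all(np.diff(vals) >= 0)


class TestDetectionRatios:
    def test_subthreshold_floor_is_epsilon(self):
        params = ModelParams(gamma=3.0, zeta=0.5, epsilon=0.001)
        for rho in (0.0, 4.0, 9.0):
            assert detection_ratio_epidemiological(rho, params) == pytest.approx(0.001)

    def test_epidemiological_value(self):
        params = ModelParams(gamma=3.0, zeta=1e-5, epsilon=0.0)
        assert detection_ratio_epidemiological(36.0, params) == pytest.approx(1.8e-4)

    def test_clipped_to_unit_interval(self):
        params = ModelParams(gamma=3.0, zeta=1.0, epsilon=0.0)
        # raw value 1.0 * 0.5 * 36 = 18 exceeds 1: clip engages
        assert detection_ratio_epidemiological(36.0, params) == 1.0

    @given(
        rho=st.floats(0, 1e4),
        gamma=st.floats(0.5, 5),
        zeta=st.floats(1e-8, 1e-2),
        epsilon=st.floats(0, 0.01),
    )
    @settings(max_examples=200, deadline=None)
    def test_never_below_epsilon(self, rho, gamma, zeta, epsilon):
        params = ModelParams(gamma=gamma, zeta=zeta, epsilon=epsilon)
        assert detection_ratio_epidemiological(rho, params) >= epsilon - 1e-15

    @pytest.mark.parametrize(
        "rho, zeta, epsilon, expected",
        [(0.0, 1e-4, 0.0, 0.0), (10.0, 1e-4, 0.0, 1e-3), (20000.0, 1e-4, 0.0, 1.0)],
    )
    def test_proportional(self, rho, zeta, epsilon, expected):
        assert detection_ratio_proportional(rho, zeta, epsilon) == pytest.approx(expected)

    @pytest.mark.parametrize("k, rho", [(0.01, 5.0), (0.0, 123.0), (1.0, 0.0)])
    def test_null_ignores_density(self, k, rho):
        assert detection_ratio_null(k, rho) == k


class TestSimulateSIR:
    def test_extinction_below_threshold(self, default_params):
        traj = simulate_sir(4.0, default_params, i0=0.5, t_max=40.0)
        assert traj.infected_fraction[-1] < 0.5 * 1e-3

    @pytest.mark.parametrize("rho", [10.0, 16.0, 36.0, 100.0])
    def test_equilibrium_matches_closed_form(self, rho, default_params):
        """The ODE's fixed point solves rho^(1/phi)(1-I) = gamma, i.e. I*."""
        traj = simulate_sir(rho, default_params, i0=0.01, t_max=80.0)
        assert traj.infected_fraction[-1] == pytest.approx(
            endemic_fraction(rho, default_params), abs=1e-3
        )

    def test_trajectory_stays_in_unit_interval(self, default_params):
        traj = simulate_sir(400.0, default_params, i0=1.0, t_max=20.0)
        assert np.all(traj.infected_fraction >= 0)
        assert np.all(traj.infected_fraction <= 1)

    def test_rejects_bad_inputs(self, default_params):
        with pytest.raises(ValueError):
            simulate_sir(10.0, default_params, i0=0.0)
        with pytest.raises(ValueError):
            simulate_sir(10.0, default_params, i0=1.5)
        with pytest.raises(ValueError):
            simulate_sir(10.0, default_params, dt=-0.1)

    def test_csv_export(self, tmp_path, default_params):
        traj = simulate_sir(36.0, default_params, t_max=1.0)
        out = tmp_path / "traj.csv"
        traj.to_csv(out)
        data = np.loadtxt(out, delimiter=",", skiprows=1)
        assert data.shape[1] == 2
        np.testing.assert_allclose(data[:, 1], traj.infected_fraction, atol=1e-12)
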