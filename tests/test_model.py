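"""Analytic properties and frozen examples of the point-source diffusion model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from spimdiff.model import (
    DiffusionParams,
    FCorrection,
    SingularTimeError,
    concentration,
    f_of_D,
    half_time,
    peak_time,
    solve_Dv,
    wave_speed,
)

from conftest import brute_force_half_time


class TestConcentration:
    def test_value_at_origin_of_observation(self):
        p = DiffusionParams(D=12, t0=320, B=1)
        assert concentration(p, 0, 0) == pytest.approx(
            1.0 / np.sqrt(np.pi * 12 * 320), rel=1e-12
        )
        assert concentration(p, 0, 0) == pytest.approx(9.105e-3, rel=1e-3)

    def test_prefactor_normalisation_at_x0(self):
        # at x = 0 the exponential term is 1 for any time
        p = DiffusionParams(D=3.7, t0=11.0, B=42.0)
        for t in (0.0, 5.0, 900.0):
            u = t + p.t0
            assert concentration(p, 0, t) * np.sqrt(np.pi * p.D * u) / p.B == pytest.approx(1.0)

    def test_peak_of_time_course_at_x2_over_2D(self):
        p = DiffusionParams(D=12, t0=0, B=1)
        t = np.linspace(1, 600, 120000)
        c = concentration(p, 60.0, t)
        assert t[np.argmax(c)] == pytest.approx(60**2 / (2 * 12), abs=0.05)

    def test_singular_and_domain_errors(self):
        p = DiffusionParams(D=1, t0=0, B=1)
        with pytest.raises(SingularTimeError):
            concentration(p, 10, 0)
        with pytest.raises(ValueError):
            concentration(p, -1, 10)
        with pytest.raises(ValueError):
            concentration(p, 1, -10)

    def test_strictly_positive(self):
        p = DiffusionParams(D=2, t0=100, B=5)
        x = np.linspace(0, 300, 50)
        assert np.all(concentration(p, x, 10.0) > 0)

    def test_satisfies_diffusion_pde(self):
        # dC/dt = D * d2C/dx2, checked with 4th-order finite differences
        p = DiffusionParams(D=7.3, t0=0.0, B=2.0)
        hx = 0.05
        worst = 0.0
        scale = 0.0
        for t in np.geomspace(1.0, 3000.0, 10):
            ht = 1e-3 * t
            for x in np.linspace(0.0, 200.0, 21):
                xs = np.abs([x - 2 * hx, x - hx, x, x + hx, x + 2 * hx])  # C even in x
                cx = concentration(p, xs, t)
                cxx = (-cx[0] + 16 * cx[1] - 30 * cx[2] + 16 * cx[3] - cx[4]) / (12 * hx**2)
                ts = np.array([t - 2 * ht, t - ht, t + ht, t + 2 * ht])
                ct_ = concentration(p, x, ts)
                ct = (ct_[0] - 8 * ct_[1] + 8 * ct_[2] - ct_[3]) / (12 * ht)
                worst = max(worst, abs(ct - p.D * cxx))
                scale = max(scale, abs(ct))
        assert worst < 1e-6 * scale

    def test_half_line_mass_equals_B(self):
        p = DiffusionParams(D=4.2, t0=77.0, B=13.5)
        for t in (0.0, 50.0, 2000.0):
            mass, err = quad(lambda x: concentration(p, x, t), 0, np.inf)
            assert mass == pytest.approx(p.B, abs=1e-8 * p.B)

    def test_depends_on_D_t_product_only(self):
        x = np.linspace(0, 100, 11)
        a = concentration(DiffusionParams(D=3.0, t0=0, B=1), x, 400.0)
        b = concentration(DiffusionParams(D=6.0, t0=0, B=1), x, 200.0)
        np.testing.assert_allclose(a, b, rtol=1e-14)


class TestPeakTime:
    @pytest.mark.parametrize(
        "x, D, t0, observed, expected",
        [
            (60, 12, 0, False, 150.0),
            (0, 5, 0, False, 0.0),
            (60, 12, 320, True, 0.0),  # peak passed during the delay: trace decays
            (60, 12, 100, True, 50.0),
        ],
    )
    def test_examples(self, x, D, t0, observed, expected):
        assert peak_time(DiffusionParams(D=D, t0=t0), x, observed=observed) == pytest.approx(expected)


class TestHalfTime:
    def test_at_x0_equals_three_t0_exactly(self):
        for D, t0 in [(1.0, 10.0), (12.0, 320.0), (20.0, 1800.0)]:
            assert half_time(DiffusionParams(D=D, t0=t0), 0.0) == pytest.approx(3 * t0, rel=1e-9)

    @pytest.mark.parametrize("x, expected", [(30, 1.081e3), (60, 1.569e3)])
    def test_control_condition_values(self, x, expected):
        # frozen from the dense-grid first-crossing oracle
        p = DiffusionParams(D=12, t0=320)
        assert half_time(p, x) == pytest.approx(expected, rel=1e-3)

    def test_agrees_with_brute_force_oracle(self):
        for D in (2.0, 5.0, 10.0, 15.0, 20.0):
            for t0 in (200.0, 320.0, 600.0, 900.0, 1200.0):
                for x in (0.0, 10.0, 20.0, 30.0, 40.0):
                    p = DiffusionParams(D=D, t0=t0)
                    assert half_time(p, x) == pytest.approx(
                        brute_force_half_time(p, x), abs=0.05
                    )

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        D=st.floats(1.0, 20.0),
        t0=st.floats(50.0, 1500.0),
        x=st.floats(0.0, 80.0),
        dx=st.floats(1.0, 40.0),
        dt0=st.floats(10.0, 500.0),
    )
    def test_monotone_in_distance_and_delay(self, D, t0, x, dx, dt0):
        # tau_1/2 always grows with distance; it grows with the delay only in
        # the decaying-trace regime (peak before observation, x**2 < 2*D*t0)
        base = half_time(DiffusionParams(D=D, t0=t0), x)
        assert half_time(DiffusionParams(D=D, t0=t0), x + dx) > base
        if x * x < 2.0 * D * t0:
            assert half_time(DiffusionParams(D=D, t0=t0 + dt0), x) > base

    def test_requires_positive_t0(self):
        with pytest.raises(ValueError):
            half_time(DiffusionParams(D=1.0, t0=0.0), 10.0)


class TestFCorrection:
    @pytest.mark.parametrize("D, expected", [(12, 3.892), (1, 7.643), (10, 4.34)])
    def test_polynomial_values(self, D, expected):
        assert f_of_D(FCorrection(), D) == pytest.approx(expected, abs=1e-9)

    def test_positive_and_near_4_on_supported_range(self):
        fc = FCorrection()
        vals = [f_of_D(fc, D) for D in np.linspace(1, 20, 50)]
        assert all(v > 0 for v in vals)
        assert min(vals) > 2 and max(vals) < 8

    def test_warns_outside_range(self):
        with pytest.warns(UserWarning):
            f_of_D(FCorrection(), 25.0)


class TestWaveSpeedAndDv:
    @pytest.mark.parametrize("R0, tau, v", [(70, 700, 0.10), (0, 700, 0.0), (50, 500, 0.10)])
    def test_wave_speed(self, R0, tau, v):
        assert wave_speed(R0, tau) == pytest.approx(v)

    def test_wave_speed_domain(self):
        with pytest.raises(ValueError):
            wave_speed(10, 0)

    def test_solve_Dv_control_wave(self):
        # R0 = 70 um at tau = 700 s -> ~8.4 um^2/s under the MSD/f(D) relation
        assert solve_Dv(70, 700) == pytest.approx(8.4, rel=0.02)

    def test_solve_Dv_limits_and_monotonicity(self):
        assert solve_Dv(0, 700) == 0.0
        d1 = solve_Dv(40, 700)
        d2 = solve_Dv(80, 700)
        assert d2 > d1

    def test_product_reading_differs(self):
        assert solve_Dv(70, 700, reading="product") < 1.0

    def test_out_of_bracket_is_error(self):
        with pytest.raises(ValueError):
            solve_Dv(5000, 700)


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [dict(D=0), dict(D=-1), dict(D=1, t0=-5), dict(D=1, B=0)])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DiffusionParams(**{"B": 1.0, "t0": 0.0, **kwargs})
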