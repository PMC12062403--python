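import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from finprop import metrics as mx


class TestAverageAcceleration:
    def test_closed_fin_printed_case(self):
        # u_e = 0.73 BL/s reached after 11.4 cycles at 10 Hz
        assert mx.average_acceleration(0.73, 11.4 / 10.0) == pytest.approx(0.64, abs=0.005)

    def test_full_open_printed_case(self):
        assert mx.average_acceleration(0.73, 14.9 / 10.0) == pytest.approx(0.49, abs=0.005)

    def test_zero_speed_gives_zero(self):
        assert mx.average_acceleration(0.0, 2.0) == 0.0

    def test_nonpositive_time_rejected(self):
        with pytest.raises(mx.InvalidInputError):
            mx.average_acceleration(1.0, 0.0)


class TestReynolds:
    def test_zero_speed(self):
        assert mx.reynolds(0.0, 0.057, 9.5818e-7) == 0.0

    def test_direct_evaluation(self):
        assert mx.reynolds(0.1, 0.057, 9.5818e-7) == pytest.approx(5948.78, abs=0.01)

    def test_linear_in_speed(self):
        assert mx.reynolds(0.2, 0.057, 9.5818e-7) == pytest.approx(
            2 * mx.reynolds(0.1, 0.057, 9.5818e-7))

    def test_nonpositive_viscosity_rejected(self):
        with pytest.raises(mx.InvalidInputError):
            mx.reynolds(1.0, 0.057, 0.0)


class TestPowerExpenditure:
    def test_zero_velocities_zero_power(self):
        t = np.linspace(0, 1, 11)
        f = np.ones((11, 3, 2))
        v = np.zeros_like(f)
        total, mean = mx.power_expenditure(f, v, t)
        assert total == 0.0 and mean == 0.0

    def test_constant_integrand(self):
        t = np.linspace(0, 2, 21)
        f = np.zeros((21, 1, 2))
        v = np.zeros_like(f)
        f[:, 0, 0] = 1.0
        v[:, 0, 0] = 1.0
        total, mean = mx.power_expenditure(f, v, t)
        assert total == pytest.approx(2.0)
        assert mean == pytest.approx(1.0)

    def test_in_phase_sinusoids_average_half_product(self):
        t = np.linspace(0, 1, 2001)
        A, B = 1.7, 0.4
        f = np.zeros((len(t), 1, 2))
        v = np.zeros_like(f)
        f[:, 0, 1] = A * np.sin(2 * np.pi * 5 * t)
        v[:, 0, 1] = B * np.sin(2 * np.pi * 5 * t)
        _, mean = mx.power_expenditure(f, v, t)
        assert mean == pytest.approx(A * B / 2, rel=1e-4)

    def test_misaligned_series_rejected(self):
        with pytest.raises(mx.InvalidInputError):
            mx.power_expenditure(np.zeros((5, 2, 2)), np.zeros((5, 3, 2)),
                                 np.linspace(0, 1, 5))


class TestEfficiencyAndCost:
    def test_zero_thrust_zero_efficiency(self):
        assert mx.froude_efficiency(0.0, 0.5, 1.0) == 0.0

    def test_unity_when_power_equals_thrust_times_speed(self):
        assert mx.froude_efficiency(0.3, 0.2, 0.06) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert mx.froude_efficiency(0.01, 0.1, 0.002) == pytest.approx(0.5)

    def test_nonpositive_power_rejected(self):
        with pytest.raises(mx.InvalidInputError):
            mx.froude_efficiency(1.0, 1.0, 0.0)

    def test_cost_of_transport_unity(self):
        assert mx.cost_of_transport(1.0, 1.0, 1.0) == 1.0

    def test_cost_of_transport_with_model_mass(self):
        assert mx.cost_of_transport(0.002, 0.1, 0.0026) == pytest.approx(7.6923, abs=1e-4)

    def test_cost_halves_when_speed_doubles(self):
        assert mx.cost_of_transport(1.0, 2.0, 1.0) == pytest.approx(
            0.5 * mx.cost_of_transport(1.0, 1.0, 1.0))

    def test_zero_speed_rejected(self):
        with pytest.raises(mx.InvalidInputError):
            mx.cost_of_transport(1.0, 0.0, 1.0)


class TestDragCoefficient:
    def test_standard_unity_case(self):
        assert mx.drag_coefficient(1.0, 2.0, 1.0, 1.0, "standard") == pytest.approx(1.0)

    def test_zero_drag(self):
        assert mx.drag_coefficient(0.0, 2.0, 1.0, 1.0, "standard") == 0.0

    def test_conventions_differ_by_exactly_speed_factor(self):
        for U in (0.3, 1.7, 4.0):
            printed = mx.drag_coefficient(2.0, 1000.0, U, 0.01, "as_printed")
            standard = mx.drag_coefficient(2.0, 1000.0, U, 0.01, "standard")
            assert printed == pytest.approx(standard * U, rel=1e-14)

    def test_zero_speed_rejected(self):
        with pytest.raises(mx.InvalidInputError):
            mx.drag_coefficient(1.0, 1.0, 0.0, 1.0)


class TestThrustDragSplit:
    def test_mixed_elements(self):
        T, D, F = mx.thrust_drag_split([2.0, -0.5])
        assert (T, D, F) == (2.0, 0.5, 1.5)

    def test_all_opposing(self):
        T, D, F = mx.thrust_drag_split([-1.0, -2.0])
        assert T == 0.0 and F == -D == -3.0

    @settings(max_examples=100, derandomize=True)
    @given(fx=st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=40),
           sign=st.sampled_from([-1.0, 1.0]))
    def test_split_identity_property(self, fx, sign):
        T, D, F = mx.thrust_drag_split(fx, swim_sign=sign)
        assert F == T - D
        assert T >= 0 and D >= 0

    def test_identity_holds_on_random_records(self, rng):
        for _ in range(20):
            fx = rng.normal(size=50)
            T, D, F = mx.thrust_drag_split(fx, swim_sign=-1.0)
            assert F == T - D
            assert T >= 0 and D >= 0
            assert F == pytest.approx(-fx.sum(), rel=1e-12, abs=1e-12)


class TestSummarize:
    def make_series(self, n=400, cycles=4.0):
        t = np.linspace(0, cycles, n, endpoint=False) + cycles / n
        return t

    def test_constant_series_reproduces_constants(self):
        t = self.make_series()
        n = len(t)
        s = mx.summarize(t, np.full(n, 0.2), np.full(n, 3.0), np.full(n, 1.0),
                         np.full(n, 0.5), u_e_target=0.1, body_length=1.0,
                         mass=2.0, rho=1.0, nu=1e-3, area=1.0, cycle=1.0,
                         n_cycles=4.0)
        assert s.thrust_avg == pytest.approx(3.0)
        assert s.drag_avg == pytest.approx(1.0)
        assert s.net_force_avg == pytest.approx(2.0)
        assert s.froude_efficiency == pytest.approx(3.0 * 0.2 / 0.5)
        assert s.cost_of_transport == pytest.approx(0.5 / (0.2 * 2.0))
        assert s.alpha * s.t_0 == pytest.approx(s.u_e, rel=1e-12)

    def test_determinism(self):
        t = self.make_series()
        n = len(t)
        args = (t, np.linspace(0, 0.5, n), np.full(n, 1.0), np.full(n, 0.6),
                np.full(n, 0.2))
        kw = dict(u_e_target=0.3, body_length=1.0, mass=1.0, rho=1.0,
                  nu=1e-3, cycle=1.0, n_cycles=4.0)
        s1 = mx.summarize(*args, **kw)
        s2 = mx.summarize(*args, **kw)
        assert s1 == s2

    def test_analytic_linear_speed_series(self):
        # u(t) = 0.1 t: target 0.25 crossed at t = 2.5
        t = self.make_series(800, 8.0)
        u = 0.1 * t
        n = len(t)
        s = mx.summarize(t, u, np.full(n, 1.0), np.full(n, 1.0),
                         np.full(n, 1.0), u_e_target=0.25, body_length=1.0,
                         mass=1.0, rho=1.0, nu=1e-3, cycle=1.0, n_cycles=8.0)
        assert s.t_0 == pytest.approx(2.5, rel=1e-3)
        assert s.alpha == pytest.approx(0.1, rel=1e-3)

    def test_window_truncated_with_warning(self):
        t = self.make_series(100, 2.0)
        n = len(t)
        with pytest.warns(UserWarning, match="truncat"):
            mx.summarize(t, np.full(n, 0.1), np.full(n, 1.0), np.full(n, 1.0),
                         np.full(n, 1.0), u_e_target=0.05, body_length=1.0,
                         mass=1.0, cycle=1.0, n_cycles=20.0)


class TestTimeToSpeed:
    def test_linear_series(self):
        t = np.linspace(0, 1, 101)
        assert mx.time_to_speed(t, t, 0.5) == pytest.approx(0.5)

    def test_never_reached_returns_none(self):
        t = np.linspace(0, 1, 11)
        assert mx.time_to_speed(t, 0.1 * t, 5.0) is None

    def test_exponential_approach(self):
        t = np.linspace(0, 3, 301)
        u = 1.0 - np.exp(-t)
        assert mx.time_to_speed(t, u, 0.6321) == pytest.approx(1.0, abs=5e-3)
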