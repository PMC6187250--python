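"""Rate laws, simulators, closed-form and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rre import (
    ReactionSpec,
    SystemState,
    Trajectory,
    effective_kprime,
    finite_difference_rates,
    rate_full,
    rate_reduced,
    read_trajectory,
    simulate_closed,
    simulate_full,
    trajectory_rates,
    write_trajectory,
)


def euler_closed(kprime, x, a, m, bp1_0, bp2_0, times, dt=1e-4):
    """Independent fixed-step oracle for the closed two-species system."""
    out1, out2 = [bp1_0], [bp2_0]
    b1, b2, t = bp1_0, bp2_0, times[0]
    for t_next in times[1:]:
        n = max(1, int(round((t_next - t) / dt)))
        h = (t_next - t) / n
        for _ in range(n):
            r = kprime * max(b1, 0.0) ** x
            b1, b2 = max(b1 - a * r * h, 0.0), b2 + m * r * h
        out1.append(b1)
        out2.append(b2)
        t = t_next
    return np.array(out1), np.array(out2)


class TestRateLaws:
    @pytest.mark.parametrize(
        "bp1,kprime,x,expected",
        [(0.0, 0.05, 2.0, 0.0), (1.0, 0.05, 2.0, 0.05), (2.0, 0.05, 2.0, 0.2)],
    )
    def test_reduced_law_values(self, bp1, kprime, x, expected):
        spec = ReactionSpec(kprime=kprime, x=x)
        assert rate_reduced(bp1, spec) == pytest.approx(expected, abs=1e-15)

    def test_reduced_law_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            rate_reduced(-0.1, ReactionSpec())

    @pytest.mark.parametrize(
        "bp1,bath,k,y,x,expected",
        [
            (2.0, (1.0, 1.0), 0.05, (1.0, 2.0), 2.0, 0.2),
            (0.0, (5.0,), 0.05, (1.0,), 1.0, 0.0),
            (3.0, (5.0,), 0.01, (1.0,), 1.0, 0.15),
        ],
    )
    def test_full_law_values(self, bp1, bath, k, y, x, expected):
        spec = ReactionSpec(kprime=k, k=k, x=x, y=y)
        assert rate_full(SystemState(bp1, 0.0, bath), spec) == pytest.approx(expected)

    def test_full_law_bath_order_mismatch(self):
        spec = ReactionSpec(k=0.05, y=(1.0,))
        with pytest.raises(ValueError, match="mismatch"):
            rate_full(SystemState(1.0, 0.0, (1.0, 2.0)), spec)

    def test_full_law_matches_reduced_at_frozen_bath(self):
        spec = ReactionSpec(k=0.02, kprime=0.02, x=1.7, y=(0.5, 2.0))
        bath = (4.0, 1.5)
        kp = effective_kprime(spec, bath)
        reduced = ReactionSpec(kprime=kp, x=1.7)
        for bp1 in (0.2, 1.0, 3.1):
            assert rate_full(SystemState(bp1, 0.0, bath), spec) == pytest.approx(
                rate_reduced(bp1, reduced), rel=1e-12
            )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        bp1=st.floats(0.01, 50.0),
        c=st.floats(0.1, 10.0),
        x=st.floats(0.2, 3.0),
        kprime=st.floats(1e-4, 1.0),
    )
    def test_reduced_law_power_scaling(self, bp1, c, x, kprime):
        spec = ReactionSpec(kprime=kprime, x=x)
        assert math.isclose(
            rate_reduced(c * bp1, spec), c**x * rate_reduced(bp1, spec), rel_tol=1e-9
        )


class TestClosedSimulation:
    def test_first_order_matches_exponential(self):
        t = np.linspace(0, 20, 81)
        traj = simulate_closed(ReactionSpec(kprime=0.1, x=1.0), SystemState(1.0, 0.0), t)
        ref1, ref2 = np.exp(-0.1 * t), 1 - np.exp(-0.1 * t)
        assert np.max(np.abs(traj.bp1 - ref1) / np.maximum(ref1, 1e-12)) < 1e-6
        assert np.max(np.abs(traj.bp2 - ref2)) < 1e-6

    def test_second_order_matches_rational_solution(self):
        t = np.linspace(0, 20, 81)
        traj = simulate_closed(ReactionSpec(kprime=0.1, x=2.0), SystemState(1.0, 0.0), t)
        ref = 1.0 / (1.0 + 0.1 * t)
        assert np.max(np.abs(traj.bp1 - ref) / ref) < 1e-6
        # spot value: bp1(5) = 1/(1 + 0.5)
        i5 = np.searchsorted(t, 5.0)
        assert traj.bp1[i5] == pytest.approx(1 / 1.5, rel=1e-6)

    def test_zero_rate_constant_keeps_state(self):
        t = np.linspace(0, 10, 11)
        traj = simulate_closed(ReactionSpec(kprime=0.0, x=1.0), SystemState(0.7, 0.2), t)
        assert np.allclose(traj.bp1, 0.7) and np.allclose(traj.bp2, 0.2)

    def test_conservation_and_rate_antisymmetry(self):
        t = np.arange(0, 10.0 + 1e-9, 0.01)
        traj = simulate_closed(ReactionSpec(kprime=0.2, x=1.5), SystemState(1.0, 0.3), t)
        total = traj.bp1 + traj.bp2
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-6
        r1 = finite_difference_rates(traj.times, traj.bp1)
        r2 = finite_difference_rates(traj.times, traj.bp2)
        assert np.max(np.abs(r1 + r2)) < 1e-3

    def test_monotonicity_of_species(self):
        t = np.linspace(0, 30, 61)
        traj = simulate_closed(ReactionSpec(kprime=0.1, x=0.7), SystemState(1.0, 0.0), t)
        assert np.all(np.diff(traj.bp1) <= 1e-12)
        assert np.all(np.diff(traj.bp2) >= -1e-12)

    @pytest.mark.parametrize("x", [0.5, 1.0, 2.0])
    def test_adaptive_integrator_matches_euler_oracle(self, x):
        t = np.linspace(0, 10, 21)
        traj = simulate_closed(ReactionSpec(kprime=0.1, x=x), SystemState(1.0, 0.0), t)
        e1, e2 = euler_closed(0.1, x, 1.0, 1.0, 1.0, 0.0, t)
        assert np.max(np.abs(traj.bp1 - e1) / np.maximum(e1, 1e-6)) < 1e-4
        assert np.max(np.abs(traj.bp2 - e2)) < 1e-4

    def test_stoichiometry_alone_reverses_final_ordering(self):
        # upstream-consumed faster than downstream-produced (a > m) leaves
        # BP1 above BP2 at t=5; the opposite stoichiometry reverses it
        t = np.linspace(0, 5, 11)
        init = SystemState(1.0, 0.1)
        fast_consume = simulate_closed(ReactionSpec(kprime=0.05, x=1.0, a=5, m=1), init, t)
        fast_produce = simulate_closed(ReactionSpec(kprime=0.05, x=1.0, a=1, m=5), init, t)
        assert fast_consume.bp2[-1] < fast_consume.bp1[-1]
        assert fast_produce.bp2[-1] > fast_produce.bp1[-1]

    def test_rejects_non_monotone_grid(self):
        with pytest.raises(ValueError, match="increasing"):
            simulate_closed(ReactionSpec(), SystemState(1.0, 0.0), [0.0, 2.0, 1.0])


class TestFullSimulation:
    def test_large_bath_converges_to_reduced_model(self):
        t = np.linspace(0, 10, 51)
        ratio = 1e6
        spec = ReactionSpec(kprime=0.05, k=0.05 / ratio, x=1.0, y=(1.0,))
        init = SystemState(1.0, 0.0, (ratio,))
        full = simulate_full(spec, init, t)
        red = simulate_closed(
            ReactionSpec(kprime=effective_kprime(spec, init.bath), x=1.0),
            SystemState(1.0, 0.0), t,
        )
        assert np.max(np.abs(full.bp1 - red.bp1)) < 1e-4 * init.bp1
        assert np.max(np.abs(full.bp2 - red.bp2)) < 1e-4 * init.bp1

    def test_zero_bath_orders_equal_closed_simulation(self):
        t = np.linspace(0, 10, 21)
        spec = ReactionSpec(kprime=0.08, k=0.08, x=1.3, y=(0.0,))
        full = simulate_full(spec, SystemState(1.0, 0.1, (5.0,)), t)
        red = simulate_closed(ReactionSpec(kprime=0.08, x=1.3), SystemState(1.0, 0.1), t)
        assert np.allclose(full.bp1, red.bp1, rtol=1e-7)
        assert np.allclose(full.bp2, red.bp2, rtol=1e-7, atol=1e-9)

    def test_reduced_model_overshoots_when_bath_comparable(self):
        # pseudo-first-order assumption violated at bath ~ upstream level
        t = np.linspace(0, 10, 51)
        spec = ReactionSpec(kprime=0.05, k=0.05, x=1.0, y=(1.0,))
        init = SystemState(1.0, 0.0, (1.0,))
        full = simulate_full(spec, init, t)
        red = simulate_closed(ReactionSpec(kprime=0.05, x=1.0), SystemState(1.0, 0.0), t)
        assert red.bp2[-1] > full.bp2[-1]
        assert (red.bp2[-1] - full.bp2[-1]) / full.bp2[-1] > 0.05
        # bath is actually consumed
        assert full.bath[-1, 0] < init.bath[0]


class TestRates:
    def test_exact_on_linear_series(self):
        assert np.allclose(finite_difference_rates([0, 1, 2], [0, 1, 2]), [1, 1, 1])

    def test_zero_on_constant_series(self):
        assert np.allclose(finite_difference_rates([0, 1, 2, 3], [4, 4, 4, 4]), 0.0)

    def test_central_difference_exact_on_quadratic(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        rates = finite_difference_rates(t, t**2)
        assert rates[1] == pytest.approx(2.0) and rates[2] == pytest.approx(4.0)

    def test_requires_three_points(self):
        with pytest.raises(ValueError, match="3 grid points"):
            finite_difference_rates([0, 1], [0, 1])

    def test_trajectory_rates_delegates(self):
        t = np.linspace(0, 10, 21)
        traj = simulate_closed(ReactionSpec(kprime=0.1), SystemState(1.0, 0.0), t)
        assert np.allclose(trajectory_rates(traj),
                           finite_difference_rates(t, traj.bp2))


class TestTrajectoryContainer:
    def test_roundtrip_is_bit_exact(self, tmp_path):
        t = np.linspace(0, 10, 21)
        spec = ReactionSpec(kprime=0.05, k=0.05, x=1.0, y=(1.0,))
        traj = simulate_full(spec, SystemState(1.0, 0.0, (3.0,)), t)
        path = tmp_path / "traj.csv"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        assert np.array_equal(traj.times, back.times)
        assert np.array_equal(traj.bp1, back.bp1)
        assert np.array_equal(traj.bp2, back.bp2)
        assert np.array_equal(traj.bath, back.bath)

    def test_validation(self):
        with pytest.raises(ValueError, match="equal length"):
            Trajectory(np.array([0.0, 1.0]), np.array([1.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="increasing"):
            Trajectory(np.array([0.0, 0.0]), np.array([1.0, 1.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError, match="nonnegative"):
            SystemState(-1.0, 0.0)
        with pytest.raises(ValueError, match="order"):
            ReactionSpec(x=0.0)
        with pytest.raises(ValueError, match="stoichiometric"):
            ReactionSpec(a=0.5)
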