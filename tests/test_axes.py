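import math

import numpy as np
import pytest

from treesway.axes import (
    ExtremaSequence,
    estimate_alpha,
    estimate_lambda,
    estimate_t1,
    find_extrema,
    frequency_gap,
    pair_differences,
)
from treesway.core import OscillatorParameters, damped_frequency
from treesway.errors import CoincidenceError, ExtremaError, GeometryError
from treesway.simulate import SimulationSpec, generate_trajectory


def _extrema_from_times(times, coordinate="x"):
    times = np.asarray(times, dtype=float)
    kinds = np.array(["+", "-"] * times.size)[: times.size]
    return ExtremaSequence(
        coordinate=coordinate,
        times=times,
        values=np.ones_like(times),
        kinds=kinds,
    )


class TestFindExtrema:
    def test_cosine_extrema_located_to_sub_sample_accuracy(self):
        t = np.arange(0.0, 2.0, 1.0 / 200.0)
        ex = find_extrema(t, np.cos(20.0 * t), 0.05, "x")
        expected = np.arange(1, 13) * math.pi / 20.0
        got = ex.times[(ex.times > 0.05) & (ex.times < 1.95)]
        assert got.size == expected[expected < 1.95].size
        assert np.max(np.abs(got - expected[: got.size])) < 1e-4
        assert all(a != b for a, b in zip(ex.kinds, ex.kinds[1:]))

    def test_constant_signal_rejected(self):
        t = np.linspace(0.0, 1.0, 100)
        with pytest.raises(ExtremaError):
            find_extrema(t, np.zeros_like(t), 0.05)
        with pytest.raises(ExtremaError):
            find_extrema(t, np.full_like(t, 2.0), 0.05)

    def test_damped_signal_spacing_matches_quasi_half_period(self):
        omega, delta = 21.56, 0.52
        wbar = damped_frequency(omega, delta)
        t = np.arange(0.0, 20.0, 1.0 / 200.0)
        sig = np.exp(-delta * t) * (np.cos(wbar * t) + delta / wbar * np.sin(wbar * t))
        ex = find_extrema(t, sig, 1e-6, "x")
        spacing = np.diff(ex.times)
        assert np.max(np.abs(spacing - math.pi / wbar)) < 1e-3 * (math.pi / wbar)


class TestPairDifferences:
    def test_identical_times_give_zero_deltas(self):
        ex = _extrema_from_times([0.5, 1.0, 1.5, 2.0])
        d = pair_differences(ex, _extrema_from_times([0.5, 1.0, 1.5, 2.0], "y"))
        np.testing.assert_allclose(d.deltas, 0.0)

    def test_hand_paired_example(self):
        ex_x = _extrema_from_times([1.0, 2.0, 3.0])
        ex_y = _extrema_from_times([0.9, 2.2, 2.9], "y")
        d = pair_differences(ex_x, ex_y)
        np.testing.assert_allclose(d.deltas, [0.1, -0.2, 0.1], atol=1e-12)
        np.testing.assert_allclose(d.ref_times, [0.95, 2.1, 2.95], atol=1e-12)

    def test_deltas_shrink_towards_coincidence(self):
        # undamped corner start: drift between the oscillations accumulates,
        # so |delta t| decreases towards t1 on the branch containing the zero
        p = OscillatorParameters(20.0, 20.8, 0.0, 0.0, 0.3, X0=10.0, Y0=5.0)
        traj = generate_trajectory(SimulationSpec(p, duration=15.0, sample_rate=200.0))
        ex_x = find_extrema(traj.times, traj.x, 1e-6, "x")
        ex_y = find_extrema(traj.times, traj.y, 1e-6, "y")
        d = pair_differences(ex_x, ex_y)
        est = estimate_t1(d, y_extrema_times=ex_y.times)
        before = np.abs(d.deltas[(d.ref_times < est.t1) & (d.ref_times > est.t1 - 1.0)])
        assert before.size >= 3
        assert before[-1] <= before[0]


class TestEstimateT1:
    def test_undamped_closed_form(self):
        p = OscillatorParameters(20.0, 20.2, 0.0, 0.0, 0.4, X0=10.0, Y0=5.0)
        traj = generate_trajectory(SimulationSpec(p, duration=20.0, sample_rate=100.0))
        ex_x = find_extrema(traj.times, traj.x, 1e-6, "x")
        ex_y = find_extrema(traj.times, traj.y, 1e-6, "y")
        est = estimate_t1(pair_differences(ex_x, ex_y), y_extrema_times=ex_y.times)
        assert est.t1 == pytest.approx(math.pi / 0.2, abs=1.0 / 100.0)
        assert est.quality == "strict"

    def test_equal_frequencies_raise(self):
        p = OscillatorParameters(20.0, 20.0, 0.1, 0.1, 0.4, X0=10.0, Y0=5.0)
        traj = generate_trajectory(SimulationSpec(p, duration=20.0, sample_rate=100.0))
        ex_x = find_extrema(traj.times, traj.x, 1e-6, "x")
        ex_y = find_extrema(traj.times, traj.y, 1e-6, "y")
        with pytest.raises(CoincidenceError):
            estimate_t1(pair_differences(ex_x, ex_y))

    def test_damped_matches_damped_frequency_difference(self):
        p = OscillatorParameters(21.56, 21.86, 0.52, 0.64, 0.9163, X0=10.0, Y0=5.0)
        traj = generate_trajectory(SimulationSpec(p, duration=30.0, sample_rate=100.0))
        ex_x = find_extrema(traj.times, traj.x, 1e-9, "x")
        ex_y = find_extrema(traj.times, traj.y, 1e-9, "y")
        est = estimate_t1(pair_differences(ex_x, ex_y), y_extrema_times=ex_y.times)
        t1_expected = math.pi / (p.omega_bar2 - p.omega_bar1)
        assert est.t1 == pytest.approx(t1_expected, rel=0.02)


class TestFrequencyGap:
    def test_inverse_of_coincidence_time(self):
        assert frequency_gap(15.708) == pytest.approx(0.2, abs=1e-4)
        assert frequency_gap(1e6) == pytest.approx(0.0, abs=1e-5)
        assert frequency_gap(7.126) == pytest.approx(math.pi / 7.126, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(Exception):
            frequency_gap(0.0)


class TestLambdaAndAlpha:
    def test_lambda_345(self):
        assert estimate_lambda(3.0, 4.0, 0.6, 0.8) == pytest.approx(5.0)

    def test_lambda_degenerate(self):
        with pytest.raises(GeometryError):
            estimate_lambda(3.0, 4.0, 0.0, 0.0)

    def test_lambda_one_for_undamped_corner_arrival(self):
        # undamped: position at t1 is back on the rectangle, equal diagonal
        assert estimate_lambda(1.0, 1.0, -1.0, 1.0) == pytest.approx(1.0, abs=1e-6)

    def test_lambda_exceeds_one_when_damped(self):
        p = OscillatorParameters(21.56, 21.86, 0.52, 0.64, 0.9163, X0=10.0, Y0=5.0)
        traj = generate_trajectory(SimulationSpec(p, duration=30.0, sample_rate=100.0))
        t1 = math.pi / (p.omega_bar2 - p.omega_bar1)
        xt1 = float(np.interp(t1, traj.times, traj.x))
        yt1 = float(np.interp(t1, traj.times, traj.y))
        assert estimate_lambda(traj.x[0], traj.y[0], xt1, yt1) > 1.0

    @pytest.mark.parametrize(
        "a, c, parity, expected_deg",
        [
            ((1.0, 1.0), (-1.0, 1.0), "even", 0.0),
            ((1.0, 1.0), (1.0, -1.0), "odd", 0.0),
        ],
    )
    def test_corner_examples(self, a, c, parity, expected_deg):
        # C is already on the unit diagonal so lambda = 1 and CA = A - C
        alpha = estimate_alpha(a[0], a[1], c[0], c[1], parity)
        assert math.degrees(alpha) == pytest.approx(expected_deg, abs=1e-9)

    def test_scaling_invariance(self):
        a = estimate_alpha(3.0, 1.0, -2.0, 0.8, "even")
        b = estimate_alpha(30.0, 10.0, -20.0, 8.0, "even")
        assert a == pytest.approx(b, abs=1e-12)

    def test_indeterminate_chord(self):
        # A coincides with C: chord degenerates
        with pytest.raises(GeometryError):
            estimate_alpha(1.0, 1.0, 1.0, 1.0, "even")
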