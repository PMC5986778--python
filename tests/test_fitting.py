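import math

import numpy as np
import pytest

from treesway.config import SYNTHETIC_CONFIG, AnalysisConfig
from treesway.core import OscillatorParameters, damped_frequency, free_decay
from treesway.fitting import analyze, consistency_check, fit_axis, initial_guess
from treesway.simulate import SimulationSpec, generate_trajectory

from conftest import TABLE_PARAMS


def _angle_diff_deg(a, b):
    """Smallest difference between two axis angles in degrees (mod 180)."""
    return abs((a - b + 90.0) % 180.0 - 90.0)


class TestInitialGuess:
    def test_recovers_damped_cosine_parameters(self):
        t = np.arange(0.0, 20.0, 1.0 / 100.0)
        sig = np.exp(-0.5 * t) * np.cos(21.5 * t)
        delta0, wbar0, a0 = initial_guess(sig, 100.0)
        assert wbar0 == pytest.approx(21.5, rel=0.01)
        assert delta0 == pytest.approx(0.5, rel=0.05)
        assert a0 == pytest.approx(sig[0])

    def test_undamped_cosine_gives_near_zero_decay(self):
        t = np.arange(0.0, 20.0, 1.0 / 100.0)
        delta0, _, _ = initial_guess(np.cos(21.5 * t), 100.0)
        assert abs(delta0) <= 0.01


class TestFitAxis:
    def test_noiseless_parameter_recovery(self):
        wbar = damped_frequency(21.564, 0.518)
        t = np.arange(0.0, 30.0, 1.0 / 100.0)
        sig = free_decay(t, 10.0, 0.518, wbar)
        fit = fit_axis(t, sig)
        assert fit.amplitude0 == pytest.approx(10.0, rel=1e-3)
        assert fit.delta == pytest.approx(0.518, rel=1e-3)
        assert fit.omega_bar == pytest.approx(wbar, rel=1e-3)
        assert fit.omega == pytest.approx(21.564, rel=1e-3)
        assert fit.residual_rms < 1e-8

    def test_undamped_data_fits_zero_decay(self):
        t = np.arange(0.0, 30.0, 1.0 / 100.0)
        fit = fit_axis(t, 5.0 * np.cos(20.0 * t))
        assert fit.delta <= 1e-6

    def test_zeta_consistency(self):
        t = np.arange(0.0, 30.0, 1.0 / 100.0)
        fit = fit_axis(t, free_decay(t, 4.0, 0.4, 20.0))
        assert fit.zeta == pytest.approx(fit.delta / fit.omega, abs=1e-12)

    def test_noisy_monte_carlo_recovery(self):
        # 1% amplitude Gaussian noise: frequency within 0.5%, decay within 10%
        wbar = damped_frequency(21.56, 0.52)
        t = np.arange(0.0, 30.0, 1.0 / 100.0)
        clean = free_decay(t, 10.0, 0.52, wbar)
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            fit = fit_axis(t, clean + rng.normal(0.0, 0.1, t.size))
            assert fit.omega_bar == pytest.approx(wbar, rel=0.005)
            assert fit.delta == pytest.approx(0.52, rel=0.10)


class TestAnalyze:
    def test_table_like_parameters_recovered(self, table_result):
        res = table_result
        p = TABLE_PARAMS
        assert _angle_diff_deg(res.alpha, math.degrees(p.alpha)) < 1.0
        assert res.fit_X.omega == pytest.approx(p.omega1, rel=0.005)
        assert res.fit_Y.omega == pytest.approx(p.omega2, rel=0.005)
        assert res.fit_X.delta == pytest.approx(p.delta1, rel=0.05)
        assert res.fit_Y.delta == pytest.approx(p.delta2, rel=0.05)
        assert res.fit_X.omega <= res.fit_Y.omega
        assert 0.0 <= res.alpha < 180.0

    def test_t1_matches_damped_gap(self, table_result):
        p = TABLE_PARAMS
        t1_expected = math.pi / (p.omega_bar2 - p.omega_bar1)
        assert table_result.t1 == pytest.approx(t1_expected, rel=0.02)

    def test_alpha_zero_case(self):
        p = OscillatorParameters(21.56, 21.86, 0.52, 0.64, 0.0, X0=10.0, Y0=5.0)
        traj = generate_trajectory(SimulationSpec(p, duration=30.0, sample_rate=100.0))
        res = analyze(traj, SYNTHETIC_CONFIG)
        assert _angle_diff_deg(res.alpha, 0.0) < 1.0

    def test_frame_equivariance(self, table_result):
        # rotating the measurement frame shifts alpha and nothing else
        theta = 25.0
        p = TABLE_PARAMS
        rotated = OscillatorParameters(
            p.omega1, p.omega2, p.delta1, p.delta2,
            p.alpha + math.radians(theta), p.X0, p.Y0,
        )
        traj = generate_trajectory(SimulationSpec(rotated, duration=30.0, sample_rate=100.0))
        res = analyze(traj, SYNTHETIC_CONFIG)
        assert _angle_diff_deg(res.alpha, table_result.alpha + theta) < 0.1
        assert res.fit_X.omega == pytest.approx(table_result.fit_X.omega, rel=1e-3)
        assert res.fit_Y.omega == pytest.approx(table_result.fit_Y.omega, rel=1e-3)
        assert res.fit_X.delta == pytest.approx(table_result.fit_X.delta, rel=1e-3)

    def test_reanalysis_is_a_fixed_point(self, table_result):
        # regenerate a trajectory from the reported parameters and re-analyse
        r = table_result
        p = OscillatorParameters(
            r.fit_X.omega, r.fit_Y.omega, r.fit_X.delta, r.fit_Y.delta,
            math.radians(r.alpha), abs(r.fit_X.amplitude0), abs(r.fit_Y.amplitude0),
        )
        traj = generate_trajectory(SimulationSpec(p, duration=30.0, sample_rate=100.0))
        res2 = analyze(traj, SYNTHETIC_CONFIG)
        assert _angle_diff_deg(res2.alpha, r.alpha) < 1.0
        assert res2.fit_X.omega == pytest.approx(r.fit_X.omega, rel=0.005)
        assert res2.fit_Y.omega == pytest.approx(r.fit_Y.omega, rel=0.005)
        assert res2.fit_X.delta == pytest.approx(r.fit_X.delta, rel=0.05)

    def test_report_serialisation(self, table_result):
        d = table_result.to_dict()
        assert d["alpha_deg"] == pytest.approx(table_result.alpha)
        assert d["frequency_X_hz"] == pytest.approx(table_result.fit_X.omega / (2 * math.pi))
        row = table_result.table_row()
        assert set(row) == {
            "marker", "t1_s", "alpha_deg", "omega1_rad_per_s", "omega2_rad_per_s",
            "delta1_per_s", "delta2_per_s",
        }


class TestConsistencyCheck:
    def test_clean_synthetic_within_two_percent(self, table_result):
        rep = consistency_check(table_result, tolerance=0.02)
        assert rep.applicable and rep.passed
        assert rep.relative_discrepancy < 0.02

    def test_degenerate_gap_flagged_not_applicable(self, table_result):
        from dataclasses import replace

        degenerate = replace(table_result, fitted_gap=0.0)
        rep = consistency_check(degenerate)
        assert not rep.applicable
        assert "not applicable" in str(rep)
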