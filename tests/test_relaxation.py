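"""Relaxation-window extraction and the tau estimators.

The simplex fit is checked against two independent routes: a closed-form
log-linear regression and an exhaustive grid search over tau.
"""

import numpy as np
import pytest

from lvdiastole.relaxation import (
    RelaxationWindow,
    extract_relaxation_window,
    fit_tau_grid,
    fit_tau_loglinear,
    fit_tau_simplex,
)

from conftest import make_window


class TestWindowExtraction:
    def test_first_beat_has_no_previous_lvedp(self, noiseless_sim, noiseless_analysis):
        with pytest.raises(ValueError, match="previous LVEDP"):
            extract_relaxation_window(noiseless_sim.traces["lv"], noiseless_analysis.beats, 0)

    def test_noiseless_length_matches_analytic_crossing_time(
        self, noiseless_sim, noiseless_analysis
    ):
        lv = noiseless_sim.traces["lv"]
        beats = noiseless_analysis.beats
        for i in range(1, len(beats)):
            w = extract_relaxation_window(lv, beats, i)
            assert w.usable
            tau_s = noiseless_sim.ground_truth["tau_ms"][i] / 1000.0
            expected = tau_s * np.log(w.p0 / beats[i - 1].lvedp) * lv.sampling_rate
            assert abs(w.n_samples - 1 - expected) <= 2

    def test_window_time_axis_starts_at_zero(self, noiseless_sim, noiseless_analysis):
        w = extract_relaxation_window(noiseless_sim.traces["lv"], noiseless_analysis.beats, 3)
        assert w.t[0] == 0.0
        assert w.start == noiseless_analysis.beats[3].dpdt_min_index

    def test_decay_plateauing_above_previous_lvedp_is_unusable(
        self, noiseless_sim, noiseless_analysis
    ):
        import copy

        beats = [copy.copy(b) for b in noiseless_analysis.beats]
        beats[2].lvedp = 0.5  # below the simulated diastolic floor: never crossed
        w = extract_relaxation_window(noiseless_sim.traces["lv"], beats, 3)
        assert not w.usable
        assert "never drops below" in w.reason


class TestSimplexFit:
    def test_exact_exponential_recovered_to_microsecond(self):
        fit = fit_tau_simplex(make_window(tau_ms=25.0, p0=50.0, duration_ms=40.0))
        assert abs(fit.tau - 25.0) < 1e-3
        assert fit.sse < 1e-12
        assert fit.converged and fit.method == "simplex"

    def test_agrees_with_grid_oracle_on_noisy_windows(self):
        for seed in range(20):
            w = make_window(tau_ms=20.0, p0=50.0, duration_ms=35.0, noise_sd=0.5, seed=seed)
            tau_s = fit_tau_simplex(w).tau
            tau_g = fit_tau_grid(w, 1.0, 100.0, 0.01).tau
            assert abs(tau_s - tau_g) < 0.02

    def test_monotone_in_true_tau(self):
        fits = [fit_tau_simplex(make_window(tau_ms=tau)).tau for tau in (15.0, 20.0, 30.0)]
        assert fits[0] < fits[1] < fits[2]

    def test_scale_equivariance(self):
        w = make_window(tau_ms=22.0, noise_sd=0.3, seed=9)
        c = 3.7
        scaled = RelaxationWindow(w.start, w.end, w.t, c * w.pressure)
        f, fc = fit_tau_simplex(w), fit_tau_simplex(scaled)
        assert abs(f.tau - fc.tau) < 1e-4
        assert fc.sse == pytest.approx(c**2 * f.sse, rel=1e-4, abs=1e-12)

    def test_boundary_solution_is_flagged(self):
        # non-decaying data pushes tau to its ceiling; that must be flagged
        t = np.arange(30) / 1000.0
        w = RelaxationWindow(0, 29, t, np.full(30, 40.0) + 0.001 * np.arange(30))
        fit = fit_tau_simplex(w, tau_max=500.0)
        assert fit.at_bound

    def test_unusable_window_rejected(self):
        w = RelaxationWindow(5, 5, np.array([]), np.array([]), usable=False, reason="x")
        with pytest.raises(ValueError, match="unusable"):
            fit_tau_simplex(w)


class TestLogLinear:
    def test_matches_simplex_on_exact_data(self):
        w = make_window(tau_ms=25.0)
        assert abs(fit_tau_loglinear(w).tau - fit_tau_simplex(w).tau) < 1e-6

    def test_constant_window_is_degenerate(self):
        t = np.arange(20) / 1000.0
        w = RelaxationWindow(0, 19, t, np.full(20, 30.0))
        with pytest.raises(ValueError, match="non-decaying"):
            fit_tau_loglinear(w)

    def test_nonpositive_pressure_rejected(self):
        t = np.arange(20) / 1000.0
        p = 10.0 * np.exp(-t / 0.02) - 5.0
        w = RelaxationWindow(0, 19, t, p)
        with pytest.raises(ValueError, match="positive"):
            fit_tau_loglinear(w)

    def test_within_15_percent_of_simplex_under_noise(self):
        for seed in range(10):
            w = make_window(tau_ms=25.0, noise_sd=0.5, seed=100 + seed)
            tau_ll = fit_tau_loglinear(w).tau
            tau_sx = fit_tau_simplex(w).tau
            assert abs(tau_ll - tau_sx) / tau_sx < 0.15


class TestGrid:
    def test_exact_data_minimizer_at_truth(self):
        fit = fit_tau_grid(make_window(tau_ms=25.0), 1.0, 100.0, 0.01)
        assert abs(fit.tau - 25.0) <= 0.01 + 1e-9

    def test_grid_sse_bounds_simplex_sse(self):
        for seed in (0, 1, 2):
            w = make_window(tau_ms=18.0, noise_sd=0.4, seed=seed)
            g = fit_tau_grid(w, 1.0, 100.0, 0.01)
            s = fit_tau_simplex(w)
            # exhaustive search cannot beat the continuous optimum by more
            # than the grid-resolution slack
            assert s.sse <= g.sse + 1e-6

    def test_bad_grid_bounds_rejected(self):
        w = make_window()
        with pytest.raises(ValueError):
            fit_tau_grid(w, 10.0, 5.0, 0.01)


def test_time_unit_rescaling_scales_tau():
    # expressing the time axis in units 1000x coarser scales tau by exactly 1000
    w = make_window(tau_ms=25.0, noise_sd=0.2, seed=4)
    w_scaled = RelaxationWindow(w.start, w.end, w.t * 1000.0, w.pressure)
    f = fit_tau_simplex(w)
    f_scaled = fit_tau_simplex(w_scaled, tau_max=500_000.0)
    assert f_scaled.tau == pytest.approx(1000.0 * f.tau, rel=1e-4)


def test_pipeline_tau_recovery_on_simulated_record(noisy_sim, noisy_analysis):
    """Over 60 s at tau 25 ms / noise 0.5 mmHg the fitted taus must centre on
    the programmed value with modest spread."""
    taus = noisy_analysis.tau_table.query("usable")["tau_ms"]
    assert abs(taus.mean() - 25.0) / 25.0 < 0.05
    assert taus.std() < 2.0
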