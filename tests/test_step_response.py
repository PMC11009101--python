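"""Step-response analysis: trimming, windowing, filtering, overlay fits."""

import math

import numpy as np
import pytest

from minsted_track import (
    EmitterTrajectory,
    StepWindow,
    Trace,
    filter_steps,
    filter_traces,
    segment_and_interpolate,
    simulate_step_response_ensemble,
    simulate_trace,
    trim_warmup,
    zero_overlay_fit,
    zoh_interpolate,
)
from minsted_track.theory import solve_step_ode


def make_trace(scan, epsf, t, x=None, y=None, radius=None, warmup=0, duration=None, meta=None):
    t = np.asarray(t, dtype=float)
    n = t.size
    warm = np.zeros(n, dtype=bool)
    warm[:warmup] = True
    return Trace(
        t=t,
        beta=np.zeros(n),
        x=np.zeros(n) if x is None else np.asarray(x, float),
        y=np.zeros(n) if y is None else np.asarray(y, float),
        radius=np.full(n, scan.radius) if radius is None else np.asarray(radius, float),
        is_background=np.zeros(n, dtype=bool),
        is_warmup=warm,
        scan=scan,
        epsf=epsf,
        duration=float(t[-1] if duration is None else duration),
        meta=meta or {},
    )


class TestTrimWarmup:
    def test_flagged_events_removed(self, scan, epsf):
        tr = make_trace(scan, epsf, np.linspace(0.001, 1, 500), warmup=100)
        out = trim_warmup(tr)
        assert out.n == 400 and out.warmup_count == 0

    def test_constant_radius_unchanged(self, scan, epsf):
        tr = make_trace(scan, epsf, np.linspace(0.001, 1, 200))
        assert trim_warmup(tr).n == 200

    def test_radius_ramp_trimmed_at_convergence(self, scan, epsf):
        radius = np.concatenate([np.linspace(40, 13.5, 57), np.full(143, 13.0)])
        tr = make_trace(scan, epsf, np.linspace(0.001, 1, 200), radius=radius)
        out = trim_warmup(tr)
        assert out.n == 143 and np.all(out.radius == 13.0)

    def test_all_warmup_is_error(self, scan, epsf):
        tr = make_trace(scan, epsf, [0.1, 0.2], warmup=2)
        with pytest.raises(ValueError):
            trim_warmup(tr)


class TestFilterTraces:
    @pytest.mark.parametrize(
        "duration, n, kept",
        [
            (0.030, 2000, False),  # too short despite many photons
            (0.040, 99, False),    # too few photons
            (0.040, 100, True),    # boundaries are strict "less than"
            (0.031, 100, True),
        ],
    )
    def test_strict_boundaries(self, scan, epsf, duration, n, kept):
        tr = make_trace(scan, epsf, np.linspace(0.0, duration, n))
        out, reasons = filter_traces([tr])
        assert (len(out) == 1) is kept
        assert (0 in reasons) is not kept


class TestZeroOrderHold:
    def test_single_event_held_everywhere(self):
        grid = np.linspace(-0.015, 0.015, 11)
        assert zoh_interpolate([-0.015], [3.3], grid) == pytest.approx(np.full(11, 3.3))

    def test_event_exactly_on_grid_point_is_taken(self):
        got = zoh_interpolate([0.0, 0.002], [1.0, 5.0], [0.0, 0.002, 0.003])
        assert got == pytest.approx([1.0, 5.0, 5.0])

    def test_piecewise_hold(self):
        grid = np.array([-0.001, 0.0, 0.0019, 0.002, 0.004])
        got = zoh_interpolate([-0.001, 0.002], [0.0, 5.0], grid)
        assert got == pytest.approx([0.0, 0.0, 0.0, 5.0, 5.0])

    def test_idempotent_on_gridded_series(self, rng):
        grid = np.linspace(0, 1, 101)
        vals = rng.normal(size=101)
        assert zoh_interpolate(grid, vals, grid) == pytest.approx(vals)

    def test_grid_before_first_event_rejected(self):
        with pytest.raises(ValueError):
            zoh_interpolate([0.5], [1.0], [0.0, 0.5])


class TestSegmentation:
    def test_grid_spacing_and_edge_windows(self, scan, epsf, rng):
        T = 0.015
        traces = simulate_step_response_ensemble(1, 16.0, T, scan, epsf, rng,
                                                 steps_per_trace=5)
        wins = segment_and_interpolate(traces[0], T=T, s=16.0)
        # first step at t=T has no photon at or before the window start
        assert len(wins) == 4
        for w in wins:
            assert np.diff(w.grid) == pytest.approx(np.full(10000, T / 5000))
            assert w.grid[0] == -T and w.grid[-1] == T and w.grid.size == 10001

    def test_requires_step_metadata(self, scan, epsf):
        tr = make_trace(scan, epsf, np.linspace(0.001, 1, 100))
        with pytest.raises(ValueError):
            segment_and_interpolate(tr)

    def test_beam_frame_signal_settles_at_zero(self, scan, epsf, rng):
        traces = simulate_step_response_ensemble(1, 16.0, 0.015, scan, epsf, rng)
        w = segment_and_interpolate(traces[0], T=0.015, s=16.0)[1]
        # converged portions (well before and well after the step) sit near 0
        assert abs(np.mean(w.x[w.t < -0.005])) < 3.0
        assert abs(np.mean(w.x[w.t > 0.010])) < 3.0


def _noise_window(grid, t_events, x, y, rate):
    return StepWindow(step_time=0.0, t=t_events, x=x, y=y, grid=grid,
                      x_grid=zoh_interpolate(t_events, x, grid), rate=rate)


class TestFilterSteps:
    def _windows(self, rates, peaks, rng, T=0.015, s=16.0):
        grid = np.linspace(-T, T, 10001)
        wins = []
        for rate, peak in zip(rates, peaks):
            t = np.linspace(-T, T, 200)
            x = np.zeros(200)
            x[100:110] = peak  # brief excursion after the step
            y = rng.normal(0, 1.0, 200)
            wins.append(_noise_window(grid, t, x, y, rate))
        return wins

    def test_rate_threshold_is_strict(self, rng):
        wins = self._windows([1000, 1000, 1000, 690, 700], [0] * 5, rng)
        kept, reasons = filter_steps(wins, s=16.0)
        assert len(kept) == 4 and len(reasons) == 1  # 0.69*median out, 0.70 in

    def test_displacement_threshold_is_strict(self, rng):
        grid = np.linspace(-0.015, 0.015, 10001)
        t = np.linspace(-0.015, 0.015, 200)
        y = np.concatenate([np.full(100, -1.0), np.full(100, 1.0)])  # std(Y) known
        sd = np.std(y, ddof=1)
        exact = np.zeros(200)
        exact[150] = 16.0 + 2 * sd  # displacement == limit: retained
        over = np.zeros(200)
        over[150] = 16.0 + 2 * sd + 0.01
        wins = [_noise_window(grid, t, exact, y, 1000.0),
                _noise_window(grid, t, over, y, 1000.0)]
        kept, reasons = filter_steps(wins, s=16.0, median_rate=1000.0)
        assert len(kept) == 1 and 1 in reasons

    def test_clean_simulated_windows_mostly_retained(self, scan, epsf, rng):
        traces = simulate_step_response_ensemble(25, 16.0, 0.015, scan, epsf, rng)
        wins = []
        for tr in traces:
            wins += segment_and_interpolate(tr, T=0.015, s=16.0)
        kept, _ = filter_steps(wins, s=16.0)
        assert len(kept) >= 0.95 * len(wins)


class TestZeroOverlayFit:
    def _exp_windows(self, n, tau, T=0.015, s=16.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        grid = np.linspace(-T, T, 10001)
        wins = []
        for _ in range(n):
            t = np.sort(rng.uniform(-T, T, 600))
            t[0] = -T  # anchor so the hold is defined from the window start
            x = np.where(t >= 0, s * np.exp(-t / tau), 0.0)
            x += rng.normal(0, noise, t.size)
            y = rng.normal(0, noise, t.size)
            wins.append(_noise_window(grid, t, x, y, 600 / (2 * T)))
        return wins

    def test_noiseless_exponential_recovered(self):
        # recovery is limited by the zero-order-hold discretization of the
        # ~50 us event spacing, not by the solver
        res = zero_overlay_fit(self._exp_windows(4, tau=0.001), T=0.015, s=16.0)
        assert res.converged
        assert res.tau == pytest.approx(0.001, rel=0.01)
        assert res.sigma == pytest.approx(0.0, abs=0.01)
        assert res.sigma_bar == pytest.approx(0.0, abs=0.01)

    def test_translation_invariance_of_tau(self):
        wins = self._exp_windows(6, tau=0.0012, noise=0.5, seed=4)
        res = zero_overlay_fit(wins, T=0.015, s=16.0)
        for w in wins:
            w.x = w.x + 250.0
            w.x_grid = w.x_grid + 250.0
        res_shifted = zero_overlay_fit(wins, T=0.015, s=16.0)
        assert res_shifted.tau == pytest.approx(res.tau, rel=1e-9)

    def test_pure_noise_sigma_bar_matches_direct_formula(self):
        rng = np.random.default_rng(10)
        T, sn = 0.015, 2.0
        grid = np.linspace(-T, T, 10001)
        wins = []
        for _ in range(400):
            t = np.sort(rng.uniform(-T, T, 400))
            t[0] = -T
            x = rng.normal(0, sn, 400)
            wins.append(_noise_window(grid, t, x, rng.normal(0, sn, 400), 400 / (2 * T)))
        res = zero_overlay_fit(wins, T=T, s=0.0)
        (lo, _), (z_lo, _) = res.sigma_interval, res.zero_interval
        direct = np.std(
            [np.mean(w.x[(w.t > lo) & (w.t < T)]) - np.mean(w.x[(w.t > z_lo) & (w.t < 0)])
             for w in wins],
            ddof=1,
        ) / math.sqrt(2)
        assert res.sigma_bar == pytest.approx(direct, rel=1e-9)
        # i.i.d. closed form: difference of two independent sample means
        n2 = 400 * (T - lo) / (2 * T)
        n1 = 400 * (-z_lo) / (2 * T)
        assert direct == pytest.approx(sn * math.sqrt(1 / n1 + 1 / n2) / math.sqrt(2), rel=0.25)

    def test_simulated_ensemble_matches_ode_and_sigma_ordering(self, scan, epsf):
        rng = np.random.default_rng(77)
        traces = simulate_step_response_ensemble(50, 16.0, 0.015, scan, epsf, rng)
        wins = []
        for tr in traces:
            wins += segment_and_interpolate(tr, T=0.015, s=16.0)
        wins, _ = filter_steps(wins, s=16.0)
        res = zero_overlay_fit(wins, T=0.015, s=16.0)
        ode = solve_step_ode(16.0, scan.rate, scan.alpha, scan.radius, epsf.sigma_e)
        assert res.tau == pytest.approx(ode.tau_fit, rel=0.15)
        assert res.sigma_bar < res.sigma

    def test_needs_two_windows(self):
        with pytest.raises(ValueError):
            zero_overlay_fit(self._exp_windows(1, tau=0.001))
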