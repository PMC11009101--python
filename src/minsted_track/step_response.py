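"""Step-temporal-response analysis: from planted-step traces to tau, sigma, sigma-bar.

The protocol plants an instantaneous displacement of size ``s`` every ``T``
seconds and characterizes the tracker by overlaying the responses:

1. warm-up trimming and trace quality filters;
2. segmentation of a ``[-T, T]`` window around each planted step and
   zero-order-hold interpolation onto a regular grid of spacing ``T/5000``;
3. window filters on detection rate and on outlier displacements;
4. per-window zeroing on a pre-step interval Z, ensemble averaging, and an
   exponential fit of the mean response, performed twice (Z = (-10 ms, 0)
   for an initial tau0, then Z = (-T + 5*tau0, 0));
5. the single-photon precision ``sigma`` (across-window std of the gridded
   response, averaged over converged times 5*tau < t < T) and the
   step-localization precision ``sigma_bar`` (across-window std of the
   per-window time-mean position, divided by sqrt(2) to remove the zeroing
   uncertainty, which is of equal size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulate import Trace
from .theory import fit_exponential_decay

__all__ = [
    "trim_warmup",
    "filter_traces",
    "StepWindow",
    "segment_and_interpolate",
    "filter_steps",
    "StepResponseResult",
    "zero_overlay_fit",
    "zoh_interpolate",
]

GRID_DIVISIONS = 5000  # grid spacing is T / 5000


def trim_warmup(trace: Trace) -> Trace:
    """Drop leading events recorded before the sampling radius converged.

    Uses the warm-up flags when present, otherwise the radius column:
    leading events whose radius differs from the final value are removed.
    """
    if trace.n == 0:
        raise ValueError("cannot trim an empty trace")
    if np.any(trace.is_warmup):
        keep_from = int(np.max(np.nonzero(trace.is_warmup)[0])) + 1
    else:
        final_r = trace.radius[-1]
        not_final = np.nonzero(trace.radius != final_r)[0]
        keep_from = int(not_final[-1]) + 1 if not_final.size else 0
    if keep_from >= trace.n:
        raise ValueError("all events flagged as warm-up; nothing left to analyze")
    return trace.select(slice(keep_from, None))


def filter_traces(traces, min_duration: float = 0.031, min_photons: int = 100):
    """Discard traces shorter than 31 ms or with fewer than 100 photons.

    Both thresholds are strict ("less than" is discarded; equality is
    retained).  Returns ``(kept, reasons)`` where ``reasons`` maps the
    index of each discarded trace to the failed criterion.
    """
    kept, reasons = [], {}
    for i, tr in enumerate(traces):
        duration = tr.t[-1] - tr.t[0] if tr.n else 0.0
        if duration < min_duration:
            reasons[i] = f"duration {duration * 1e3:.1f} ms < {min_duration * 1e3:.0f} ms"
        elif tr.n < min_photons:
            reasons[i] = f"photons {tr.n} < {min_photons}"
        else:
            kept.append(tr)
    return kept, reasons


def zoh_interpolate(t_events, values, t_grid):
    """Zero-order-hold ("most recent value") interpolation.

    A grid point exactly on an event time takes that event's value.  Every
    grid point must have at least one event at or before it.
    """
    t_events = np.asarray(t_events, dtype=float)
    values = np.asarray(values, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    idx = np.searchsorted(t_events, t_grid, side="right") - 1
    if np.any(idx < 0):
        raise ValueError("grid extends before the first event; cannot hold a value")
    return values[idx]


@dataclass
class StepWindow:
    """Photon data around one planted step, with the gridded x coordinate.

    Times are relative to the step; the grid spans ``[-T, T]`` with spacing
    exactly ``T / 5000``.  ``x`` is the beam-frame response coordinate
    (planted reference staircase minus the recorded center), which sits
    near 0 on converged plateaus and jumps toward ``s`` at each step
    before relaxing back — the shape the instrument records when the
    co-aligned beams, not the fluorophore, are dislocated.
    """

    step_time: float
    t: np.ndarray  # event times relative to the step, within [-T, T]
    x: np.ndarray
    y: np.ndarray
    grid: np.ndarray
    x_grid: np.ndarray
    rate: float  # detections per second within the window


def segment_and_interpolate(trace: Trace, T: float = 0.015, s: float = 16.0):
    """Cut ``[-T, T]`` windows around each planted step and grid them.

    Step times come from the planted-step protocol recorded in the trace
    metadata.  The emitter-frame staircase is converted to the beam-frame
    response ``s * (steps at or before t) - x_center(t)`` sampled at the
    photon times (a photon coinciding exactly with a step counts as
    pre-step, matching the simulator tie-break), then zero-order-hold
    interpolated.  Windows are kept only "if possible": the interval must
    lie within the recorded duration and at least one photon must exist at
    or before the window start, so the hold is defined everywhere.
    """
    step_times = trace.meta.get("step_times")
    if step_times is None:
        raise ValueError("trace metadata lacks planted step times")
    step_times = np.asarray(step_times, dtype=float)
    # linspace keeps the endpoints exactly at +-T (an event exactly at the
    # window start must not precede the first grid point)
    grid = np.linspace(-T, T, 2 * GRID_DIVISIONS + 1)
    windows = []
    t = trace.t
    m = np.searchsorted(step_times, t, side="left")  # steps strictly before each photon
    w_sig = s * m - trace.x
    for ts in step_times:
        if t.size == 0 or t[0] > ts - T or ts + T > trace.duration:
            continue  # incomplete coverage at a trace edge
        in_win = (t >= ts - T) & (t <= ts + T)
        rel = t - ts
        x_grid = zoh_interpolate(rel, w_sig, grid)
        windows.append(
            StepWindow(
                step_time=float(ts),
                t=rel[in_win],
                x=w_sig[in_win],
                y=trace.y[in_win],
                grid=grid,
                x_grid=x_grid,
                rate=float(np.sum(in_win)) / (2.0 * T),
            )
        )
    return windows


def filter_steps(windows, s: float = 16.0, median_rate: float | None = None):
    """Apply the per-window rate and outlier-displacement filters.

    A window is discarded when its detection rate is below 70% of the
    median rate (strict), or when any gridded displacement from the
    pre-step baseline exceeds ``s + 2*std(Y)`` (strict; sample std of the
    window's y coordinates).
    """
    if not windows:
        return [], {}
    if median_rate is None:
        median_rate = float(np.median([w.rate for w in windows]))
    kept, reasons = [], {}
    for i, w in enumerate(windows):
        if w.rate < 0.7 * median_rate:
            reasons[i] = f"rate {w.rate:.0f}/s below 70% of median {median_rate:.0f}/s"
            continue
        baseline = float(np.mean(w.x_grid[w.grid < 0]))
        limit = s + 2.0 * float(np.std(w.y, ddof=1)) if w.y.size > 1 else s
        if np.max(np.abs(w.x_grid - baseline)) > limit:
            reasons[i] = f"displacement exceeds s + 2 std(Y) = {limit:.2f} nm"
            continue
        kept.append(w)
    return kept, reasons


@dataclass
class StepResponseResult:
    """Temporal and spatial precision extracted from overlaid step windows."""

    tau: float
    tau0: float
    sigma: float
    sigma_bar: float
    n_steps: int
    zero_interval: tuple
    sigma_interval: tuple
    converged: bool
    mean_response_t: np.ndarray
    mean_response: np.ndarray


def zero_overlay_fit(windows, T: float = 0.015, s: float = 16.0) -> StepResponseResult:
    """Overlay zeroed step windows and extract tau, sigma and sigma-bar.

    Two passes: the first zeroes each window on Z = (-10 ms, 0) (clipped to
    the window) and fits an exponential to the ensemble-mean response for
    an initial tau0; the second re-zeroes on Z = (-T + 5*tau0, 0) and
    refits.  Grid points at t >= 0 that precede the first post-step photon
    still hold the pre-step level although the planted displacement has
    already happened, so the step size ``s`` is added to them; the overlaid
    response then jumps to ``s`` at t = 0 and decays to 0.
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows to overlay")

    def corrected(w):
        """x_grid with s added at t >= 0 before the first post-step photon."""
        post = w.t[w.t > 0]
        t_first = post[0] if post.size else np.inf
        out = w.x_grid.copy()
        out[(w.grid >= 0) & (w.grid < t_first)] += s
        return out

    def one_pass(z_lo: float):
        z_lo = max(z_lo, -T)
        x0s, used = [], []
        for w in windows:
            in_z = (w.t > z_lo) & (w.t < 0)
            if not np.any(in_z):
                continue
            x0s.append(float(np.mean(w.x[in_z])))
            used.append(w)
        if len(used) < 2:
            raise ValueError("fewer than 2 windows have photons in the zeroing interval")
        grid = used[0].grid
        pos = grid >= 0
        overlay = np.array([corrected(w)[pos] - x0 for w, x0 in zip(used, x0s)])
        mean_resp = overlay.mean(axis=0)
        fit = fit_exponential_decay(grid[pos], mean_resp, model="decay")
        return fit, used, x0s, grid, mean_resp

    # intervals built from 5*tau are capped at 5*(T/8) so that a degenerate
    # fit (pure-noise input, non-convergence) cannot empty them
    cap = T / 8.0

    fit0, _, _, _, _ = one_pass(-0.010)
    tau0 = fit0.tau if fit0.converged else cap
    z_lo = -T + 5.0 * min(tau0, cap)
    fit, used, x0s, grid, mean_resp = one_pass(z_lo)
    tau = fit.tau if fit.converged else tau0

    # sigma: across-window std of the zeroed gridded response for 5*tau < t < T
    conv_lo = 5.0 * min(tau, cap)
    conv = (grid > conv_lo) & (grid < T)
    zeroed = np.array([w.x_grid - x0 for w, x0 in zip(used, x0s)])
    sigma = float(np.mean(np.std(zeroed[:, conv], axis=0, ddof=1)))

    # sigma_bar: std over windows of the per-window time-mean of the raw
    # photon positions in (5*tau, T), divided by sqrt(2) for the zeroing error
    means = []
    for w, x0 in zip(used, x0s):
        in_conv = (w.t > conv_lo) & (w.t < T)
        if np.any(in_conv):
            means.append(float(np.mean(w.x[in_conv])) - x0)
    sigma_bar = float(np.std(means, ddof=1) / math.sqrt(2.0)) if len(means) > 1 else float("nan")

    pos = grid >= 0
    return StepResponseResult(
        tau=float(tau),
        tau0=float(tau0),
        sigma=sigma,
        sigma_bar=sigma_bar,
        n_steps=len(used),
        zero_interval=(float(z_lo), 0.0),
        sigma_interval=(float(conv_lo), float(T)),
        converged=bool(fit.converged),
        mean_response_t=grid[pos],
        mean_response=mean_resp,
    )
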