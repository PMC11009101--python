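"""Monte-Carlo simulator of MINSTED single-fluorophore tracking.

Photon detections are drawn as a homogeneous Poisson process at the
configured mean rate k (plus an optional independent background process).
Each signal photon's emission angle is sampled from the von Mises angular
law given the current circle center and the emitter position at that time;
the center is then shifted by ``alpha * r`` toward the detection point.
Background photons carry a uniform angle but update the center exactly like
signal photons — the instrument cannot distinguish them.

The emitter follows a piecewise-constant ground-truth trajectory
(:class:`EmitterTrajectory`).  Steps occur instantaneously between photon
arrivals; a photon coinciding exactly with a step time sees the pre-step
position (a measure-zero tie-break).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .epsf import EPSF, ScanConfig, vonmises_params

__all__ = [
    "EmitterTrajectory",
    "PhotonEvent",
    "Trace",
    "update_center",
    "simulate_trace",
    "apply_termination",
    "simulate_step_response_ensemble",
]


@dataclass(frozen=True)
class EmitterTrajectory:
    """Piecewise-constant ground-truth emitter path.

    ``times`` are strictly increasing segment start times with
    ``times[0] == 0``; ``positions`` is the matching ``(n, 2)`` array of
    positions in nm.
    """

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        if times.ndim != 1 or times.size == 0 or times[0] != 0.0:
            raise ValueError("times must be 1-D and start at 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("segment start times must be strictly increasing")
        if positions.shape != (times.size, 2):
            raise ValueError("positions must have shape (len(times), 2)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)

    @classmethod
    def stationary(cls, position=(0.0, 0.0)) -> "EmitterTrajectory":
        return cls(times=np.array([0.0]), positions=np.array([position], dtype=float))

    @classmethod
    def stepping(cls, s: float, period: float, n_steps: int, start=(0.0, 0.0)) -> "EmitterTrajectory":
        """Steps of size ``s`` along +x at t = period, 2*period, ..."""
        times = np.concatenate([[0.0], period * np.arange(1, n_steps + 1)])
        x0, y0 = start
        xs = x0 + s * np.arange(n_steps + 1)
        return cls(times=times, positions=np.column_stack([xs, np.full(n_steps + 1, y0)]))

    def position_at(self, t) -> np.ndarray:
        """Emitter position at time(s) t; exact step times map to pre-step."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left") - 1
        idx = np.clip(idx, 0, self.times.size - 1)
        return self.positions[idx]


class PhotonEvent(NamedTuple):
    """Single detection: time, angle, point on circle, center after update."""

    t: float
    beta: float
    detection_point: tuple
    center_after: tuple
    is_background: bool


@dataclass
class Trace:
    """Ordered photon events of one MINSTED localization.

    Primary storage is columnar (numpy arrays); :meth:`events` provides
    per-photon named tuples for convenience.  ``radius`` is recorded per
    event so that analyses can trim any non-converged warm-up portion.
    """

    t: np.ndarray
    beta: np.ndarray
    x: np.ndarray  # center after update, nm
    y: np.ndarray
    radius: np.ndarray
    is_background: np.ndarray
    is_warmup: np.ndarray
    scan: ScanConfig
    epsf: EPSF
    duration: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.t.size)

    @property
    def warmup_count(self) -> int:
        return int(np.sum(self.is_warmup))

    def select(self, index) -> "Trace":
        """Copy of the trace restricted to a boolean mask or slice."""
        return replace(
            self,
            t=self.t[index],
            beta=self.beta[index],
            x=self.x[index],
            y=self.y[index],
            radius=self.radius[index],
            is_background=self.is_background[index],
            is_warmup=self.is_warmup[index],
            meta=dict(self.meta),
        )

    def events(self) -> list:
        out = []
        ar = self.scan.alpha * self.scan.radius
        for i in range(self.n):
            cb = (self.x[i] - ar * math.cos(self.beta[i]), self.y[i] - ar * math.sin(self.beta[i]))
            det = (cb[0] + self.radius[i] * math.cos(self.beta[i]),
                   cb[1] + self.radius[i] * math.sin(self.beta[i]))
            out.append(PhotonEvent(float(self.t[i]), float(self.beta[i]), det,
                                   (float(self.x[i]), float(self.y[i])),
                                   bool(self.is_background[i])))
        return out


def update_center(center, beta: float, scan: ScanConfig) -> np.ndarray:
    """Shift the circle center by ``alpha * r`` toward the detection angle."""
    center = np.asarray(center, dtype=float)
    ar = scan.alpha * scan.radius
    return center + ar * np.array([math.cos(beta), math.sin(beta)])


def simulate_trace(
    trajectory: EmitterTrajectory,
    scan: ScanConfig,
    epsf: EPSF,
    duration: float,
    rng: np.random.Generator,
    background_rate: float = 0.0,
    bleach_time: float | None = None,
    start_center=None,
    warmup_events: int = 0,
    meta: dict | None = None,
) -> Trace:
    """Simulate one MINSTED localization trace.

    Signal photons arrive as homogeneous Poisson at ``scan.rate`` until
    ``bleach_time`` (if given); background photons arrive at
    ``background_rate`` for the whole duration with uniform angles.  Every
    detection, background included, moves the center by ``alpha * r``.

    ``start_center`` defaults to the emitter's initial position; set it to
    an offset (with ``warmup_events`` > 0) to emulate the pre-convergence
    phase of a real acquisition, whose events analyses then trim.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if background_rate < 0 or not np.isfinite(background_rate):
        raise ValueError("background_rate must be finite and >= 0")

    signal_end = duration if bleach_time is None else min(duration, bleach_time)
    n_sig = rng.poisson(scan.rate * signal_end) if signal_end > 0 else 0
    t_sig = np.sort(rng.uniform(0.0, signal_end, size=n_sig))
    n_bg = rng.poisson(background_rate * duration)
    t_bg = np.sort(rng.uniform(0.0, duration, size=n_bg))

    t_all = np.concatenate([t_sig, t_bg])
    is_bg = np.concatenate([np.zeros(n_sig, dtype=bool), np.ones(n_bg, dtype=bool)])
    order = np.argsort(t_all, kind="stable")
    t_all = t_all[order]
    is_bg = is_bg[order]
    # detection times live on a 1-ns grid (detector timing resolution, and
    # the precision of the trace file format); coincident photons are dropped
    t_all = np.round(t_all, 9)
    keep = np.concatenate([[True], np.diff(t_all) > 0]) if t_all.size else np.ones(0, bool)
    t_all = t_all[keep]
    is_bg = is_bg[keep]
    n = t_all.size

    emitter = trajectory.position_at(t_all)  # (n, 2); background rows unused
    center = np.array(trajectory.position_at(0.0) if start_center is None else start_center,
                      dtype=float)

    ar = scan.alpha * scan.radius
    inv_sig2 = 1.0 / epsf.sigma_e**2
    r = scan.radius
    two_pi = 2.0 * math.pi

    beta_out = np.empty(n)
    x_out = np.empty(n)
    y_out = np.empty(n)
    cx, cy = float(center[0]), float(center[1])
    for i in range(n):
        if is_bg[i]:
            beta = rng.uniform(0.0, two_pi)
        else:
            dx = emitter[i, 0] - cx
            dy = emitter[i, 1] - cy
            d = math.hypot(dx, dy)
            if d > 0:
                beta = rng.vonmises(math.atan2(dy, dx), r * d * inv_sig2)
            else:
                beta = rng.uniform(-math.pi, math.pi)
            beta %= two_pi
        cx += ar * math.cos(beta)
        cy += ar * math.sin(beta)
        beta_out[i] = beta
        x_out[i] = cx
        y_out[i] = cy

    warm = np.zeros(n, dtype=bool)
    warm[: min(warmup_events, n)] = True
    full_meta = {"trajectory_times": trajectory.times.tolist(),
                 "trajectory_positions": trajectory.positions.tolist()}
    if bleach_time is not None:
        full_meta["bleach_time"] = float(bleach_time)
    if meta:
        full_meta.update(meta)
    return Trace(
        t=t_all, beta=beta_out, x=x_out, y=y_out,
        radius=np.full(n, scan.radius),
        is_background=is_bg, is_warmup=warm,
        scan=scan, epsf=epsf, duration=float(duration), meta=full_meta,
    )


def apply_termination(trace: Trace, min_photons: int = 16, window: float | None = None) -> Trace:
    """Truncate a trace per the instrument's low-rate termination rule.

    The localization stops at the first time a trailing window of length
    ``window`` (default: the scan's termination window T_t) contains fewer
    than ``min_photons`` events.  The count only decreases when a window
    expires (a photon leaves the trailing window), so it suffices to check,
    for each event at t_j, the count in (t_j, t_j + window]; checks whose
    window extends past the recorded duration are not evaluated.
    """
    w = trace.scan.termination_window if window is None else window
    if w <= 0:
        raise ValueError("window must be positive")
    t = trace.t
    if t.size == 0:
        return trace
    expiry = t + w
    # events strictly inside (t_j, t_j + w]
    counts = np.searchsorted(t, expiry, side="right") - (np.arange(t.size) + 1)
    candidates = np.nonzero((counts < min_photons) & (expiry <= trace.duration))[0]
    if candidates.size == 0:
        return trace
    u = float(expiry[candidates[0]])
    out = trace.select(t <= u)
    out.duration = u
    out.meta = dict(trace.meta)
    out.meta["termination_time"] = u
    out.meta["termination_window"] = w
    return out


def simulate_step_response_ensemble(
    n_traces: int,
    s: float,
    period: float,
    scan: ScanConfig,
    epsf: EPSF,
    rng: np.random.Generator,
    steps_per_trace: int = 5,
) -> list:
    """Simulate an ensemble of periodic planted-step traces.

    Emitter-frame equivalent of the instrument protocol that dislocates the
    co-aligned beams from a stationary fluorophore: in each trace the
    emitter jumps by ``s`` along +x every ``period`` seconds, starting at
    t = period.  Ground-truth step times are exact multiples of the period
    and are recorded in the trace metadata.

    The step-response analysis keeps only windows with a full
    ``[-period, +period]`` interval preceded by at least one photon, so a
    trace with ``steps_per_trace`` steps typically yields
    ``steps_per_trace - 1`` usable windows.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    traces = []
    duration = (steps_per_trace + 1) * period
    for _ in range(n_traces):
        traj = EmitterTrajectory.stepping(s, period, steps_per_trace)
        step_times = (period * np.arange(1, steps_per_trace + 1)).tolist()
        tr = simulate_trace(
            traj, scan, epsf, duration, rng,
            meta={"step_times": step_times, "step_size": float(s), "step_period": float(period)},
        )
        traces.append(tr)
    return traces
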