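"""Synthetic kinesin-1 walker: ground-truth trajectories for pipeline testing.

Emulates the stepping phenomenology of a single-fluorophore-labeled
kinesin-1 head on a microtubule: 16-nm on-axis advances (twice the tubulin
dimer spacing, since only one head is labeled), an occasional unpaired
8-nm step, memoryless dwells parameterized by their median, and rare
protofilament switches that displace the motor laterally by 6-26 nm with a
random sign — in half of the cases also shifting the on-axis binding
register by 8 nm.  Switches are modeled as instantaneous relocations;
diffusion during detachment is not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .epsf import EPSF, ScanConfig
from .simulate import EmitterTrajectory, Trace, apply_termination, simulate_trace

__all__ = ["WalkerConfig", "generate_walk", "generate_dataset"]


@dataclass(frozen=True)
class WalkerConfig:
    """Parameters of the synthetic kinesin-1 walk.

    ``dwell_median`` parameterizes exponential dwells via the median
    (rate = ln 2 / median), matching how dwell times are reported;
    ``p_switch`` is the per-step probability that the event is a
    protofilament switch instead of a regular step.
    """

    step_on_axis: float = 16.0          # nm
    p_half_step: float = 0.0            # probability of an unpaired 8-nm step
    dwell_median: float = 0.023         # s
    p_switch: float = 1.0 / 65.0        # per-step protofilament-switch probability
    off_axis_range: tuple = (6.0, 26.0)  # nm, magnitude of a switch displacement
    phase_shift_prob: float = 0.5       # switch shifts the on-axis register by 8 nm
    axis_angle: float = 0.0             # rad, microtubule orientation
    bleach_mean: float | None = None    # s, exponential mean; None = no bleaching
    background_rate: float = 0.0        # detections per second

    def __post_init__(self) -> None:
        for name in ("p_half_step", "p_switch", "phase_shift_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dwell_median <= 0:
            raise ValueError("dwell_median must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")


def generate_walk(cfg: WalkerConfig, n_steps: int, rng: np.random.Generator):
    """Generate a piecewise-constant 2D walk and its ground-truth events.

    Returns ``(trajectory, events)``; each event is a dict with keys
    ``t``, ``kind`` ('step', 'half_step' or 'switch'), ``dx``, ``dy``
    (displacements along/across the walking axis, before the global
    rotation by ``axis_angle``).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rate = math.log(2.0) / cfg.dwell_median
    dwells = rng.exponential(1.0 / rate, size=n_steps)
    times = [0.0]
    xs, ys = [0.0], [0.0]
    events = []
    t = 0.0
    x = y = 0.0
    for i in range(n_steps):
        t += dwells[i]
        if rng.random() < cfg.p_switch:
            lo, hi = cfg.off_axis_range
            dy = rng.uniform(lo, hi) * (1.0 if rng.random() < 0.5 else -1.0)
            dx = cfg.step_on_axis / 2.0 if rng.random() < cfg.phase_shift_prob else 0.0
            kind = "switch"
        else:
            dy = 0.0
            if rng.random() < cfg.p_half_step:
                dx, kind = cfg.step_on_axis / 2.0, "half_step"
            else:
                dx, kind = cfg.step_on_axis, "step"
        x += dx
        y += dy
        times.append(t)
        xs.append(x)
        ys.append(y)
        events.append({"t": t, "kind": kind, "dx": dx, "dy": dy})

    xs = np.asarray(xs)
    ys = np.asarray(ys)
    c, s = math.cos(cfg.axis_angle), math.sin(cfg.axis_angle)
    positions = np.column_stack([c * xs - s * ys, s * xs + c * ys])
    traj = EmitterTrajectory(times=np.asarray(times), positions=positions)
    return traj, events


def generate_dataset(
    cfg: WalkerConfig,
    scan: ScanConfig,
    epsf: EPSF,
    n_traces: int,
    rng: np.random.Generator,
    n_steps: int = 60,
    terminate: bool = True,
):
    """Simulate tracked traces of synthetic walkers, with embedded truth.

    Each trace runs a fresh walk through the tracker simulation with the
    configured background and (optionally) an exponential bleaching time,
    then applies the low-rate termination rule.  Ground-truth events are
    stored in the trace metadata for recovery scoring.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    traces = []
    for _ in range(n_traces):
        traj, events = generate_walk(cfg, n_steps, rng)
        walk_end = float(traj.times[-1]) + float(rng.exponential(cfg.dwell_median))
        if cfg.bleach_mean is not None:
            bleach = float(rng.exponential(cfg.bleach_mean))
            duration = min(walk_end, bleach) + 2.0 * scan.termination_window
        else:
            bleach = None
            duration = walk_end
        tr = simulate_trace(
            traj, scan, epsf, duration, rng,
            background_rate=cfg.background_rate,
            bleach_time=bleach,
            meta={"truth_events": events,
                  "walker": {"step_on_axis": cfg.step_on_axis,
                             "p_half_step": cfg.p_half_step,
                             "dwell_median": cfg.dwell_median,
                             "p_switch": cfg.p_switch,
                             "axis_angle": cfg.axis_angle}},
        )
        if terminate:
            tr = apply_termination(tr)
        traces.append(tr)
    return traces
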