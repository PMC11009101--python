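"""Motor-protein stepping-trace analysis pipeline.

Takes raw MINSTED localization traces of a stepping motor (for example
kinesin-1 walking on a microtubule) through quality control, changepoint
step detection, plateau precision estimation, step temporal precision, and
signal-to-background estimation:

1. trimming (warm-up events and the final 16 photons, which may be pure
   background after bleaching);
2. quality filters on duration, covered distance, y-noise, aspect ratio
   and brightness stability;
3. two rounds of penalized mean-shift changepoint detection on the x and y
   coordinates, with an intervening rotation that aligns the median
   stepping direction with the x axis;
4. plateau statistics (position means, dwell times, localization
   precision via moving-mean extrapolation);
5. an exponential fit to the median overlaid step for the temporal
   precision, and a trailing-gap background-rate estimate for the SBR.

The changepoint detector is binary segmentation with a mean-shift cost: a
candidate split is accepted only if it reduces the total within-segment
sum of squared residuals by more than the penalty
``130 * (mean over traces of std(Y))**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .simulate import Trace
from .step_response import trim_warmup, zoh_interpolate
from .theory import fit_exponential_decay

__all__ = [
    "FilterConfig",
    "trim_trace",
    "QCResult",
    "qc_filters",
    "penalized_changepoints",
    "Plateau",
    "StepEvent",
    "TraceStepResult",
    "detect_steps",
    "PlateauPrecision",
    "plateau_precision",
    "TemporalPrecisionResult",
    "step_temporal_precision",
    "SBRResult",
    "estimate_sbr",
    "StepSummary",
    "switch_summary",
    "step_statistics",
]


@dataclass(frozen=True)
class FilterConfig:
    """Trace quality-control thresholds.

    Defaults are deliberately permissive; real datasets tune them per
    acquisition.  ``sigma_max_k`` bounds the standard deviation of the
    smoothed count-rate series, in counts per second.
    """

    t_min: float = 0.050       # minimum trace duration, s
    d_min: float = 50.0        # minimum covered x-distance, nm
    sigma_min: float = 1.0     # y-noise band, nm
    sigma_max: float = 10.0
    r_min: float = 2.0         # minimum aspect ratio std(X)/std(Y)
    sigma_max_k: float | None = None  # default: 0.5 * scan rate

    def __post_init__(self) -> None:
        if not (self.sigma_min < self.sigma_max):
            raise ValueError("sigma_min must be below sigma_max")
        for name in ("t_min", "d_min", "sigma_min", "r_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def trim_trace(trace: Trace):
    """Warm-up trimming plus removal of the final 16 photons.

    The last 16 photons may be pure background detected after a bleaching
    event and are always dropped.  Idempotent: a trace already trimmed (per
    its metadata marker) is returned unchanged.  Returns ``(trace, None)``
    or ``(None, reason)`` when fewer than one event would remain.
    """
    if trace.meta.get("trimmed"):
        return trace, None
    try:
        tr = trim_warmup(trace)
    except ValueError as exc:
        return None, str(exc)
    if tr.n < 17:
        return None, f"only {tr.n} events after warm-up; need more than 16"
    out = tr.select(slice(0, tr.n - 16))
    out.meta["trimmed"] = True
    return out, None


def _rotate(x, y, angle: float):
    c, s = math.cos(angle), math.sin(angle)
    return c * x - s * y, c * y + s * x


@dataclass
class QCResult:
    passed: bool
    failed_rule: str | None
    x: np.ndarray  # endpoint-rotated coordinates
    y: np.ndarray


def qc_filters(trace: Trace, cfg: FilterConfig) -> QCResult:
    """Apply the ordered trace quality filters; report the first failure.

    Order: duration >= t_min; rotation forcing the first and last center
    onto the x axis; x-extent >= d_min; std(Y) within [sigma_min,
    sigma_max]; aspect ratio std(X)/std(Y) >= r_min; std of the smoothed
    count-rate series <= sigma_max_k.  The rate series is the reciprocal
    of a 20-sample moving mean of the inter-photon times, smoothed by a
    50-sample moving mean (trailing windows, truncated at the start).
    """
    x0, y0 = trace.x - trace.x[0], trace.y - trace.y[0]
    angle = -math.atan2(y0[-1], x0[-1])
    x, y = _rotate(x0, y0, angle)

    def fail(rule):
        return QCResult(False, rule, x, y)

    duration = trace.t[-1] - trace.t[0]
    if duration < cfg.t_min:
        return fail(f"duration {duration * 1e3:.0f} ms < T_min")
    if x.max() - x.min() < cfg.d_min:
        return fail(f"x extent {x.max() - x.min():.0f} nm < D_min")
    sig_y = float(np.std(y, ddof=1))
    if not (cfg.sigma_min <= sig_y <= cfg.sigma_max):
        return fail(f"std(Y) = {sig_y:.2f} nm outside [sigma_min, sigma_max]")
    if float(np.std(x, ddof=1)) / sig_y < cfg.r_min:
        return fail("aspect ratio std(X)/std(Y) below r_min")
    rate = 1.0 / _trailing_mean(np.diff(trace.t), 20)
    rate_smooth = _trailing_mean(rate, 50)
    bound = cfg.sigma_max_k if cfg.sigma_max_k is not None else 0.5 * trace.scan.rate
    if float(np.std(rate_smooth, ddof=1)) > bound:
        return fail("count-rate fluctuation above sigma_max_k")
    return QCResult(True, None, x, y)


def _trailing_mean(values, window: int):
    """Trailing moving mean, truncated to shorter windows at the start."""
    v = np.asarray(values, dtype=float)
    c = np.concatenate([[0.0], np.cumsum(v)])
    n = v.size
    idx = np.arange(1, n + 1)
    lo = np.maximum(idx - window, 0)
    return (c[idx] - c[lo]) / (idx - lo)


def penalized_changepoints(values, penalty: float, min_size: int = 1):
    """Mean-shift changepoints by penalized binary segmentation.

    Recursively splits at the location maximizing the reduction of the
    within-segment sum of squared residuals; a split is accepted only if
    that reduction exceeds ``penalty``.  Returns sorted split indices k,
    each the first index of the right-hand segment.  Raising the penalty
    never increases the number of detected changepoints.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    cps: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * min_size:
            continue
        ks = np.arange(lo + min_size, hi - min_size + 1)
        sl = c1[ks] - c1[lo]
        sr = c1[hi] - c1[ks]
        stot = c1[hi] - c1[lo]
        gain = sl**2 / (ks - lo) + sr**2 / (hi - ks) - stot**2 / (hi - lo)
        best = int(np.argmax(gain))
        if gain[best] > penalty:
            k = int(ks[best])
            cps.append(k)
            stack.append((lo, k))
            stack.append((k, hi))
    return sorted(cps)


@dataclass
class Plateau:
    """Quasi-stationary segment between two detected steps."""

    start_idx: int
    end_idx: int  # exclusive
    mean_pos: np.ndarray
    sigma: float
    sigma_bar: float
    n_photons: int
    dwell: float  # nan for the censored first/last plateaus


@dataclass
class StepEvent:
    """One detected step: signed plateau-to-plateau displacement."""

    axis: str  # 'on' or 'off'
    size: float  # signed, along the classified axis, nm
    size_x: float
    size_y: float
    idx: int  # photon index of the first post-step event
    t_step: float
    pre_mean: np.ndarray
    post_mean: np.ndarray
    t0_refined: float = float("nan")
    tau_hat: float = float("nan")


@dataclass
class TraceStepResult:
    """Per-trace output of the step detector, in final rotated coordinates."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rotation: float  # total rotation applied, rad
    plateaus: list
    events: list


def _segment_once(t, x, y, penalty, y_exclusion, merge_distance, off_axis_threshold, min_size):
    cps_x = penalized_changepoints(x, penalty, min_size)
    cps_y = penalized_changepoints(y, penalty, min_size)
    # y-steps within y_exclusion photon indices of an x-step are discarded
    cps_y = [k for k in cps_y
             if not any(abs(k - kx) <= y_exclusion for kx in cps_x)]
    bounds = sorted(set(cps_x) | set(cps_y))

    def means(bs):
        edges = [0] + bs + [x.size]
        return [np.array([x[a:b].mean(), y[a:b].mean()]) for a, b in zip(edges[:-1], edges[1:])]

    # merge plateaus closer than merge_distance (Euclidean), nearest first
    while bounds:
        m = means(bounds)
        dists = [float(np.linalg.norm(m[i + 1] - m[i])) for i in range(len(m) - 1)]
        i_min = int(np.argmin(dists))
        if dists[i_min] > merge_distance:
            break
        bounds.pop(i_min)
    m = means(bounds)
    edges = [0] + bounds + [x.size]

    plateaus = []
    for j, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        interior = 0 < j < len(edges) - 2
        dwell = float(t[edges[j + 1]] - t[edges[j]]) if interior else float("nan")
        plateaus.append(Plateau(
            start_idx=a, end_idx=b, mean_pos=m[j],
            sigma=float(np.std(x[a:b], ddof=1)) if b - a > 1 else 0.0,
            sigma_bar=float("nan"), n_photons=b - a, dwell=dwell,
        ))
    events = []
    for j, k in enumerate(bounds):
        dx = float(m[j + 1][0] - m[j][0])
        dy = float(m[j + 1][1] - m[j][1])
        axis = "off" if abs(dy) > off_axis_threshold else "on"
        events.append(StepEvent(
            axis=axis, size=dy if axis == "off" else dx,
            size_x=dx, size_y=dy, idx=k, t_step=float(t[k]),
            pre_mean=m[j], post_mean=m[j + 1],
        ))
    return plateaus, events


def detect_steps(
    traces,
    penalty_factor: float = 130.0,
    y_exclusion: int = 20,
    merge_distance: float = 5.0,
    off_axis_threshold: float = 5.0,
    min_size: int = 1,
):
    """Two-round changepoint step detection across a set of traces.

    Round 1 rotates each trace parallel to its least-squares line fit and
    runs the penalized detector on both axes with penalty
    ``penalty_factor * (mean over traces of std(Y))**2``.  The stepping
    vectors between plateau means then define a median stepping angle per
    trace; each trace is re-rotated so that this angle vanishes and the
    detection is repeated.  A trace without accepted changepoints yields a
    single plateau.

    A step is classified off-axis when the lateral plateau-mean
    displacement exceeds ``off_axis_threshold`` (protofilament switches
    can carry a simultaneous on-axis register shift, so classification by
    the surviving y-changepoints alone would miss them).
    """
    if not traces:
        raise ValueError("no traces to analyze")
    items = []
    for tr in traces:
        if isinstance(tr, Trace):
            t, x, y = tr.t, tr.x, tr.y
        else:
            t, x, y = tr
        slope = np.polyfit(x, y, 1)[0]
        ang = -math.atan(slope)
        xr, yr = _rotate(np.asarray(x, float), np.asarray(y, float), ang)
        items.append([np.asarray(t, float), xr, yr, ang])

    def run_round(items):
        penalty = penalty_factor * float(np.mean([np.std(it[2], ddof=1) for it in items])) ** 2
        return [
            _segment_once(it[0], it[1], it[2], penalty, y_exclusion,
                          merge_distance, off_axis_threshold, min_size)
            for it in items
        ]

    first = run_round(items)
    for it, (plateaus, events) in zip(items, first):
        on_axis = [e for e in events if e.axis == "on"]
        if on_axis:
            angles = [math.atan2(e.size_y, e.size_x) for e in on_axis]
            extra = -float(np.median(angles))
            it[1], it[2] = _rotate(it[1], it[2], extra)
            it[3] += extra
    second = run_round(items)
    return [
        TraceStepResult(t=it[0], x=it[1], y=it[2], rotation=it[3],
                        plateaus=plateaus, events=events)
        for it, (plateaus, events) in zip(items, second)
    ]


@dataclass
class PlateauPrecision:
    sigma: float
    sigma_bar: float
    fit_converged: bool
    params: tuple = ()


def plateau_precision(values, fallback_correlation_photons: float = 9.62) -> PlateauPrecision:
    """Single-photon and averaged localization precision of one plateau.

    ``sigma`` is the sample standard deviation of the axial coordinate.
    For the averaged precision, the std is recomputed after moving means of
    increasing window M and modeled as ``sigma_est(M) = a / (b + M)**c``
    (a > 0, b > -1, 0 < c <= 0.5); extrapolating to the full plateau,
    ``sigma_bar = sigma_est(N)``.  For uncorrelated data the fit recovers
    c = 0.5, b = 0, i.e. the usual ``sigma / sqrt(N)``; correlated MINSTED
    data yield a larger amplitude, encoding the correlation penalty.

    If the fit fails, falls back to ``sigma / sqrt(N / N_corr)`` with the
    given correlation length in photons, flagged via ``fit_converged``.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 30:
        raise ValueError(f"plateau has {n} photons; need at least 30")
    sigma = float(np.std(v, ddof=1))
    if sigma == 0.0:
        return PlateauPrecision(0.0, 0.0, True)
    ms = np.arange(1, max(2, n // 5) + 1)
    stds = np.array([
        np.std(np.convolve(v, np.ones(m) / m, mode="valid"), ddof=1) for m in ms
    ])

    def model(m, a, b, c):
        return a / (b + m) ** c

    try:
        popt, _ = curve_fit(
            model, ms, stds, p0=[sigma, 0.0, 0.5],
            bounds=([1e-12, -0.999, 1e-9], [np.inf, np.inf, 0.5]),
            maxfev=20000,
        )
        sigma_bar = float(model(n, *popt))
        return PlateauPrecision(sigma, sigma_bar, True, tuple(float(p) for p in popt))
    except (RuntimeError, ValueError):
        return PlateauPrecision(sigma, float(sigma / math.sqrt(n / fallback_correlation_photons)), False)


@dataclass
class TemporalPrecisionResult:
    tau: float
    n_steps_used: int
    n_steps_total: int
    converged: bool


def step_temporal_precision(results, T: float = 0.010, tau_max: float = 0.005) -> TemporalPrecisionResult:
    """Temporal precision from the median overlay of detected steps.

    Each on-axis step is normalized (pre-step plateau mean to 0, post-step
    to 1) and fitted with ``f(t) = max[0, 1 - exp(-(t - t0)/tau_hat)]`` to
    refine its temporal offset t0.  Steps with ``tau_hat >= tau_max`` are
    discarded (inclusive; slow apparent responses usually reflect multiple
    steps in quick succession).  The surviving steps, shifted by t0, are
    mapped on a regular grid of spacing ``T/500``; the per-time median is
    flipped (1 - median) and fitted with an exponential decay for t >= 0.
    """
    windows = []
    n_total = 0
    for res in results:
        for e in res.events:
            if e.axis != "on":
                continue
            n_total += 1
            denom = e.post_mean[0] - e.pre_mean[0]
            if denom == 0:
                continue
            sel = np.abs(res.t - e.t_step) <= T
            trel = res.t[sel] - e.t_step
            u = (res.x[sel] - e.pre_mean[0]) / denom

            def f(p):
                t0, log_tau = p
                expo = np.clip(-(trel - t0) / math.exp(log_tau), None, 50.0)
                pred = np.maximum(0.0, 1.0 - np.exp(expo))
                return pred - u

            try:
                fit = least_squares(f, [0.0, math.log(1e-3)],
                                    bounds=([-T, math.log(1e-7)], [T, math.log(1.0)]))
            except ValueError:
                continue
            t0, tau_hat = float(fit.x[0]), float(math.exp(fit.x[1]))
            e.t0_refined, e.tau_hat = t0, tau_hat
            if tau_hat >= tau_max:
                continue
            windows.append((trel - t0, u))

    if len(windows) < 5:
        return TemporalPrecisionResult(float("nan"), len(windows), n_total, False)

    grid = np.linspace(-T, T, 1001)
    mat = np.empty((len(windows), grid.size))
    for i, (tt, uu) in enumerate(windows):
        order = np.argsort(tt)
        tt, uu = tt[order], uu[order]
        # hold the pre-step level (0 by normalization) before the first photon
        tt = np.concatenate([[grid[0] - 1.0], tt])
        uu = np.concatenate([[0.0], uu])
        mat[i] = zoh_interpolate(tt, uu, grid)
    med = np.median(mat, axis=0)
    pos = grid >= 0
    fit = fit_exponential_decay(grid[pos], 1.0 - med[pos], model="decay")
    return TemporalPrecisionResult(float(fit.tau), len(windows), n_total, bool(fit.converged))


@dataclass
class SBRResult:
    k_mean: float
    k_b: float
    sbr: float
    n_background: int
    flagged_infinite: bool


def estimate_sbr(traces, termination_window: float | None = None) -> SBRResult:
    """Signal-to-background ratio from trailing sparse photons.

    From the end of each trace, photons whose gap to the previous photon
    exceeds ``T_t/16`` (that is, arriving below the termination rate) are
    counted as background, stopping at the first denser gap.  The summed
    counts divided by the summed termination times give the background
    rate ``k_b``; the mean per-trace detection rate ``k`` then yields
    ``SBR = (k - k_b) / k_b``.  Applied to all recorded traces, not only
    the QC-passed subset.
    """
    if not traces:
        raise ValueError("no traces given")
    total_bg = 0
    total_tt = 0.0
    rates = []
    for tr in traces:
        tt = termination_window if termination_window is not None else tr.scan.termination_window
        total_tt += tt
        if tr.n >= 1 and tr.duration > 0:
            rates.append(tr.n / tr.duration)
        gaps = np.diff(tr.t)
        count = 0
        for g in gaps[::-1]:
            if g > tt / 16.0:
                count += 1
            else:
                break
        total_bg += count
    k_mean = float(np.mean(rates)) if rates else 0.0
    k_b = total_bg / total_tt
    if k_b == 0:
        return SBRResult(k_mean, 0.0, float("inf"), 0, True)
    return SBRResult(k_mean, float(k_b), float((k_mean - k_b) / k_b), int(total_bg), False)


def switch_summary(n_switches: int, n_steps: int):
    """Steps per protofilament switch and per-step switch probability."""
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    if n_switches == 0:
        return None, 0.0
    return n_steps / n_switches, n_switches / n_steps


@dataclass
class StepSummary:
    n_steps: int
    n_switches: int
    steps_per_switch: float | None
    switch_probability: float
    on_axis_sizes: np.ndarray
    dwell_median: float
    dwell_median_pre_switch: float


def step_statistics(results) -> StepSummary:
    """Aggregate step-size, dwell-time and switching statistics.

    Dwell times are the intervals between consecutive detected steps;
    first and last plateaus of each trace are censored and excluded.  The
    pre-switch dwell is the dwell of the plateau ending in an off-axis
    step.
    """
    sizes, dwells, pre_switch_dwells = [], [], []
    n_steps = n_switches = 0
    for res in results:
        for e in res.events:
            n_steps += 1
            if e.axis == "off":
                n_switches += 1
            else:
                sizes.append(e.size_x)
        for j, p in enumerate(res.plateaus):
            if math.isnan(p.dwell):
                continue
            dwells.append(p.dwell)
            # plateau j ends at event j (boundary after it)
            if j < len(res.events) and res.events[j].axis == "off":
                pre_switch_dwells.append(p.dwell)
    per_switch, prob = switch_summary(n_switches, n_steps) if n_steps else (None, 0.0)
    return StepSummary(
        n_steps=n_steps,
        n_switches=n_switches,
        steps_per_switch=per_switch,
        switch_probability=prob,
        on_axis_sizes=np.array(sizes),
        dwell_median=float(np.median(dwells)) if dwells else float("nan"),
        dwell_median_pre_switch=(float(np.median(pre_switch_dwells))
                                 if pre_switch_dwells else float("nan")),
    )
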