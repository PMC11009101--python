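# Methods

## Model and assumptions

The effective point-spread function (E-PSF) left by STED depletion is
modeled as an isotropic 2D Gaussian with standard deviation σ_E
(FWHM = 2√(2 ln 2)·σ_E). This is the same idealization used for the
analytical treatment of the temporal precision; real E-PSFs deviate near
the donut zero, and no donut imperfections, dark states or power→FWHM
calibration are modeled.

The beams circle the current position estimate at radius *r* (standard
operation: 2r = FWHM) with a circling frequency (default 125 kHz) well
above the photon detection rate. The continuous circular motion is
therefore not simulated; each detection samples the whole circle, and the
emission angle β is drawn from the normalized restriction of the Gaussian
E-PSF to the circle — a von Mises density with mean direction toward the
emitter and concentration κ = r·d/σ_E², where *d* is the center–emitter
distance. `ScanConfig` enforces circling_freq > rate; outside that regime
the angular law would acquire circling artifacts the model cannot
represent.

Photon detections are a homogeneous Poisson process at the configured mean
rate *k* — the assumption under which the temporal-precision theory is
derived. An emitter-position-dependent rate could be added by thinning but
is deliberately not the default, because it would decouple the simulated
operating point from the closed forms. Background detections arrive as an
independent Poisson process; their angle is uniform (the instrument cannot
know a detection is background, so background photons move the center
exactly like signal). How background is spatially distributed in a real
instrument is unknown; uniform-β is a modeling choice.

Detection times are quantized to a 1-ns grid (detector timing resolution
and the precision of the trace file format); photons coincident at that
resolution are dropped.

Units are nanometers, seconds and radians internally; milliseconds and
microseconds appear only in reports. Coordinates are real-valued in the 2D
focal plane — no pixel grid, no axial (z) dimension.

## Temporal precision

After an instantaneous displacement *s* along x, the mean per-photon
update projected on x is α·r·I₁(z)/I₀(z) with z = r·(s−x)/σ_E², giving the
mean-field ODE ẋ = kαr·I₁/I₀. The Bessel ratio is evaluated with
exponentially scaled functions (stable for arbitrary z), and the ODE is
integrated with an adaptive Runge–Kutta method at relative tolerance 1e-8
over a default horizon of ten small-step time constants. τ is then defined
*operationally* as the least-squares fit of s·(1−e^(−t/τ)) to the numeric
solution — the same extraction applied to measured responses, so theory
and analysis are comparable by construction. In the small-step limit the
fit reproduces the closed form τ = 2σ_E²/(αkr²) to better than 1%; at
s = 16 nm with FWHM = 26 nm the saturating Bessel ratio makes the true
response ~13% slower than the closed form.

## Step-response analysis

The planted-step protocol displaces the co-aligned beams, not the
fluorophore; the recorded coordinate therefore jumps by *s* at each step
and relaxes back (a sawtooth), rather than accumulating a staircase. The
simulator plants steps in the emitter frame, and the segmentation converts
to the equivalent beam-frame response W(t) = s·m(t) − x(t), with m(t) the
number of planted steps at or before t (a photon coinciding exactly with a
step counts as pre-step, matching the simulator tie-break). All subsequent
operations follow the standard recipe:

- windows of [−T, T] around each planted step, zero-order-hold
  interpolation onto a grid of spacing T/5000 (grid endpoints exactly ±T);
  windows kept only when the full interval lies inside the recorded
  duration and a photon exists at or before the window start;
- window filters: detection rate below 70% of the median (strict) and any
  gridded displacement from the pre-step baseline exceeding s + 2·std(Y)
  (strict; sample std). On clean simulated ensembles ≥95% of windows
  survive;
- two-pass zeroing and fitting: Z = (−10 ms, 0) for τ₀, then
  Z = (−T + 5τ₀, 0) for τ. Grid points at t ≥ 0 before the first
  post-step photon have s added (the displacement has happened but no
  photon has reported it yet). Intervals derived from 5τ are capped at
  5·(T/8) so a degenerate fit cannot empty them;
- σ = across-window std of the zeroed gridded response, averaged over
  5τ < t < T; σ̄ = std across windows of the per-window event-mean in
  (5τ, T), divided by √2 because the zeroing offset carries an equal,
  independent uncertainty.

The ensemble average for the τ fit uses the mean of the gridded windows
(a median option is easy to add at the caller level since the overlay
matrix is exposed); the exponential fits are unweighted nonlinear least
squares with τ constrained positive, and fits with τ beyond 10³ times the
data span are flagged non-convergent.

## Stepping-trace pipeline

Traces are trimmed (warm-up events plus the final 16 photons, which may be
pure post-bleach background; idempotent via a metadata marker), then
filtered in order: duration ≥ T_min; endpoint rotation onto the x axis;
x-extent ≥ D_min; std(Y) within [σ_min, σ_max]; aspect ratio
std(X)/std(Y) ≥ r_min; and stability of the count-rate series (reciprocal
of a 20-sample trailing moving mean of inter-photon times, smoothed by a
50-sample trailing moving mean, windows truncated at the series start).
The default thresholds (T_min = 50 ms, D_min = 50 nm, σ ∈ [1, 10] nm,
r_min = 2, σ_max^k = 0.5·k) are deliberately permissive and fully exposed;
real datasets tune them per acquisition.

Step detection is penalized mean-shift changepoint detection implemented
as binary segmentation: a candidate split (at the location maximizing the
reduction of within-segment squared error) is accepted only if the
reduction exceeds the penalty 130·(⟨std(Y)⟩_traces)². Binary segmentation
makes the number of accepted changepoints monotone non-increasing in the
penalty. Two rounds are run, with an intervening per-trace rotation that
zeroes the median stepping-vector angle; y-changepoints within 20 photon
indices of an x-changepoint are removed, and plateaus whose means lie
≤5 nm apart (Euclidean) are merged nearest-first.

A step is classified **off-axis (protofilament switch)** when the lateral
plateau-mean displacement exceeds 5 nm — the same scale as the merge rule.
Classification by surviving y-changepoints alone was considered and
rejected: a switch that also shifts the on-axis register by 8 nm produces
coincident x- and y-changepoints, the 20-photon exclusion then deletes the
y-changepoint, and such switches (about half of them) would be
systematically missed.

Plateau localization precision extrapolates the std of the axial
coordinate after moving means of increasing window M with
σ_est(M) = a/(b+M)^c. The constraints are a > 0, b > −1, 0 < c ≤ 0.5: a
parameterization with negative a and b would produce negative σ for
M > |b|, so the positive-σ form is used. For uncorrelated data the fit
recovers c = 0.5 and σ̄ = σ/√N; correlated tracking data (correlation
length N_C photons) yield a larger amplitude. On fit failure the fallback
σ̄ = σ/√(N/N_C) is returned, flagged.

Step temporal precision: each on-axis step is normalized by its plateau
means, fitted with f(t) = max[0, 1 − e^(−(t−t₀)/τ̂)] to refine t₀ (the
exponent is clipped to avoid overflow at extreme trial parameters); steps
with τ̂ ≥ 5 ms are discarded (inclusive); survivors are gridded at T/500,
overlaid by the per-time median, flipped, and fitted with an exponential
decay for t ≥ 0. With instantaneous planted steps the extracted τ floors
at roughly two mean inter-photon times (t₀ jitter of about half a gap per
step plus the grid spacing).

Signal-to-background: walking backward from the end of each trace, photons
whose gap to the previous photon exceeds T_t/16 are counted as background,
stopping at the first denser gap; k_b is the summed count over the summed
termination times, and SBR = (k − k_b)/k_b with k the mean per-trace
detection rate over the recorded duration. The estimator is applied to all
recorded traces, not only the QC-passed subset, and is intrinsically
biased low by ~10–20%: the termination rule erodes about 16/k of the
window, a background photon landing within T_t/16 of the last signal
photon is missed, and a dense gap between background photons stops the
backward walk early. The recovery test budgets for this bias inside the
25% tolerance by using a 40-ms termination window and a 10 s⁻¹ planted
background. k_b = 0 yields an SBR flagged infinite rather than an error.

The default termination window T_t = 5 ms is chosen so that the
termination threshold rate 16/T_t = 3.2 kHz sits well below the signal
rates simulated here (14–62 kHz) and well above typical background.

## Synthetic walker

The generator emulates a single-fluorophore-labeled kinesin-1 head:
16-nm on-axis advances (twice the 8-nm tubulin dimer spacing, because only
one head is labeled), an optional fraction of unpaired 8-nm steps, and
rare protofilament switches (default probability 1/65 per step) displacing
the motor laterally by 6–26 nm with random sign and, with probability 0.5,
shifting the on-axis register by 8 nm. Whether unpaired 8-nm steps arise
from switching, a slip state or inchworm stepping is not observable from a
single label; the generator treats 8-nm steps and switches as independent
configured processes. Dwells are exponential — memoryless stepping —
parameterized by the median (default 23 ms, rate = ln 2/median) to match
how dwell statistics are reported; the true dwell distribution of a
two-headed motor is closer to Erlang, so recovered dwell histograms should
not be over-interpreted. Switches are instantaneous relocations; diffusion
during detachment, force dependence, ATP dependence and the cylindrical
13-protofilament geometry are not modeled. Bleaching is exponential;
after the bleach time only background photons arrive.

What passing the end-to-end tests shows: the pipeline recovers step sizes,
dwell medians, switch rates and background rates planted by this
generator. What it does not show: robustness to instrument-specific
effects absent from the model — drift, donut imperfections, fluorophore
blinking, axial motion, or rate variations tied to STED power.

## Problem sizes and numerical choices

Simulated ensembles use 100 traces × 5 planted steps (≈400 analyzable
windows) for response-time estimates, 60 traces (≈240 windows) for the
36-kHz plateau precision, 30 walker traces × 60 steps for end-to-end
recovery, and 600 short bleaching traces for background recovery — sizes
chosen so Monte-Carlo error is small against the stated tolerances while a
full run stays fast on a single CPU. The first planted step of each trace
has no photon preceding its window start and is dropped by design, so *n*
traces yield ~4n windows.

Ties and degenerate inputs: a photon exactly at a step time sees the
pre-step position; a grid point exactly on a photon time takes that
photon's value; all standard deviations are sample (n−1); an empty zeroing
interval, an all-warm-up trace, or fewer than two windows raise immediate
errors rather than returning silent nonsense.
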