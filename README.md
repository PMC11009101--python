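# minsted-track

Simulation and analysis toolkit for **MINSTED single-fluorophore tracking**
— localization by circling a STED-shrunken effective point-spread function
(E-PSF) around the current position estimate and nudging the estimate
toward every detected photon. The package is aimed at microscopists and
single-molecule biophysicists who want to explore the spatiotemporal
precision of photon-by-photon tracking, benchmark analysis pipelines for
motor-protein stepping traces, or generate realistic synthetic data with
known ground truth.

## The model

The E-PSF is an isotropic 2D Gaussian with standard deviation σ_E
(FWHM = 2√(2 ln 2) σ_E). The beams circle at radius *r* around the current
estimate — in standard operation the circle diameter matches the FWHM
(2r = FWHM) — much faster than photons are detected, so each detection
samples the whole circle: the emission angle β follows a von Mises law
with concentration κ = r·d/σ_E² and mean direction pointing at the
emitter (distance *d* from the circle center). On each detection the
center moves by α·r toward the detection point (α = 0.15).

For an instantaneous emitter displacement *s* along x, the mean-field
response obeys

    dx/dt = k α r · I₁(z)/I₀(z),   z = r (s − x) / σ_E²,

with detection rate *k* and modified Bessel functions I₀, I₁. In the
small-step limit the response is exponential with

    τ = 2 σ_E² / (α k r²),    N_C = τ·k = 2 σ_E² / (α r²),

so a fixed photon budget N_C — about 9.6 photons at the standard operating
point, independent of σ_E and *k* — moves the estimate over 1−e⁻¹ of any
small displacement. N_C is also the correlation length, in photons, of the
center sequence.

On top of the simulator (`simulate`, `walker`) the package implements the
two standard analyses: the planted-step **step-response** characterization
(τ, single-photon precision σ, step-localization precision σ̄ with its
2^(−1/2) zeroing correction) and the **stepping-trace pipeline** for
motor-protein data (quality filters, penalized changepoint step detection,
plateau precision by moving-mean extrapolation, step temporal precision,
signal-to-background estimation from trailing photon gaps).

## Worked example

Analytical operating point:

```sh
$ minsted-track theory --alpha 0.15 --fwhm 26 --k 14000
tau = 0.6870 ms
N_C = 9.618 photons
```

A response time of 0.69 ms at 14 kHz means the tracker follows a small
displacement with under ten photons.

Simulate eight synthetic kinesin-1 traces (16-nm steps, 10% unpaired 8-nm
steps, ~1.5% protofilament switches, 25 s⁻¹ background, bleaching) and run
the full stepping pipeline:

```sh
$ minsted-track simulate --config kinesin.yaml --seed 11 --out traces/
wrote 8 traces to traces
$ minsted-track analyze-traces --traces traces/ --out analysis/
88 steps (2 switches), dwell median 28.3 ms, SBR 379.7
```

`analysis/summary.json` then holds the step-size histogram (peaked at
16 nm), dwell-time medians, the per-step switch probability
(2/88 ≈ 2.3% here — small-sample scatter around the planted 1.5%), the
temporal precision from the median step overlay (τ ≈ 0.53 ms), and the
background rate recovered from the trailing photon gaps
(k_b = 31 s⁻¹ against the planted 25 s⁻¹, giving SBR ≈ 380).
`analysis/steps.tsv` and `analysis/plateaus.tsv` list every detected step
and plateau; `qc_report.tsv` records why traces were discarded.

The same functionality is available as a library:

```python
import numpy as np
from minsted_track import (EPSF, ScanConfig, simulate_step_response_ensemble,
                           segment_and_interpolate, filter_steps, zero_overlay_fit)

epsf = EPSF.from_fwhm(26.0)
scan = ScanConfig.matched(epsf, rate=14000.0)
rng = np.random.default_rng(1)
traces = simulate_step_response_ensemble(100, 16.0, 0.015, scan, epsf, rng)
windows = [w for tr in traces for w in segment_and_interpolate(tr, T=0.015, s=16.0)]
windows, _ = filter_steps(windows, s=16.0)
result = zero_overlay_fit(windows, T=0.015, s=16.0)
print(result.tau, result.sigma, result.sigma_bar)
```

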