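# spimdiff

Quantification of vascular permeability from selective plane illumination
microscopy (SPIM) time-lapse imaging, via point-source diffusion modelling
of dye extravasation.

## The problem

In zebrafish-embryo permeability assays, a fluorescent tracer (e.g. 2 MDa
rhodamine-dextran) is microinjected into the blood flow and its leakage out
of a vessel plexus is recorded as a time-lapse of wide-field light-sheet
images. The rate at which the tracer spreads through the perivascular
tissue — its effective diffusion coefficient `D` — is a readout of the
state of that tissue: tumour xenografts, for example, raise interstitial
pressure and slow tracer diffusion by an order of magnitude relative to
healthy controls. `spimdiff` turns such image stacks (or synthetic
replicas of them) into estimates of `D`, of the tracer wavefront speed,
and of the injection-to-observation delay, with tests that validate every
stage against analytic ground truth.

## The model

A bolus of tracer of amount `B` released at the origin of a semi-infinite
medium and observed a delay `t0` after release gives the concentration

    C(x, t) = B / √(π D (t + t0)) · exp(−x² / (4 D (t + t0)))

at distance `x` (µm) and observation time `t` (s). Two independent
estimators are built on it:

- **Global fit** — intensity traces extracted from ROIs at known distances
  `R0ᵢ` are Savitzky–Golay smoothed and fitted jointly, with one shared
  `D`, a free amplitude `Bᵢ` per trace, and `t0` fixed at the known delay
  (or fitted).
- **Half-time trend** — the time `τ½` at which each trace halves its
  initial value grows linearly with `R0`. The inverse slope is a wavefront
  speed `v`; the generalized mean-squared-displacement relation
  `R0² = 4 D τ½ / f(D)` with `f(D) = 0.013 D² − 0.51 D + 8.14` (≈ 4 for
  1 ≤ D ≤ 20 µm²/s) converts it into an independent estimate `Dv`; and
  matching the measured trend against model `τ½(R0)` curves over a small
  `(D, t0)` grid estimates the delay `t0` (analytically, `τ½ → 3 t0` as
  `R0 → 0`).

Synthetic presets reproduce the assay's regimes: agarose-gel calibration
injections (`D` = 18.1/8.9/2.6 µm²/s, recording from injection), control
embryos (`D` = 12 µm²/s, `t0` = 320 s) and tumour-xenografted embryos
(`D` ≈ 0.82–1.9 µm²/s, `t0` = 600 s), with camera noise and an early-time
pressure ramp near the source. An optics-QC module characterises the
instrument (light-sheet thickness and bead PSF as Gaussian FWHM).

## Worked example

```python
from spimdiff import make_preset, simulate_traces, build_trend, estimate_t0
from spimdiff.fitting import FitConfig, fit_global

preset = make_preset("control_embryo")          # D = 12 um^2/s, t0 = 320 s
traces = simulate_traces(preset, noise_free=True)

fit = fit_global(traces, FitConfig(t0_s=preset.t0))
trend = build_trend(traces)
t0_hat = estimate_t0(trend)

print(f"D_hat  = {fit.D_hat:.3f} um^2/s")
print(f"v_hat  = {trend.v_hat:.3f} um/s")
print(f"Dv_hat = {trend.Dv_hat:.1f} um^2/s")
print(f"t0_hat = {t0_hat:.0f} s")
```

prints

```
D_hat  = 12.000 um^2/s
v_hat  = 0.140 um/s
Dv_hat = 12.9 um^2/s
t0_hat = 300 s
```

The global fit recovers the generating diffusion coefficient exactly; the
half-time route lands within a factor ~1.1 of it (the two agree within a
factor of 2 by construction of the `f(D)` correction), and the grid-based
delay estimate snaps to the grid value nearest the true 320 s delay.

The same pipeline runs from the shell on rendered image stacks:

```sh
spimdiff simulate --preset xenograft_embryo --output sim --seed 1
spimdiff analyze  --input sim --output out
spimdiff optics-qc --kind sheet --output sheet_qc.json
```

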