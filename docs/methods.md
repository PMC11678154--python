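# Methods

## Diffusion model

The forward model is the one-dimensional Gaussian point-source solution of
Fick's second law on a semi-infinite bar,

    C(x, t) = B / √(π D (t + t0)) · exp(−x² / (4 D (t + t0))),

where `D` (µm²/s) is the diffusion coefficient, `B` (intensity·µm) the
amount of tracer on the half-line `x ≥ 0` (the half-line integral of `C`
equals `B` at every time; the full-line integral would be `2B`), and `t0`
(s) the delay between tracer release and the first recorded frame. The
physical geometry of a dye-filled vessel is cylindrical; the Gaussian form
is the standard simplification that captures the observed behaviour —
the prefactor power is exactly −1/2 and no Bessel-superposition solution
is attempted. The model is singular at diffusion time `t + t0 = 0`;
conditions with `t0 = 0` therefore start recording one frame interval
after release.

Useful analytic companions, all derived from the closed form:

- peak passage at `t_peak = x²/(2D)` on the injection clock; ROIs whose
  peak falls inside the delay window (`t_peak < t0`) record monotonically
  decaying traces;
- half-decay time `τ½(x)`: the unique observation time at which the trace
  halves its initial value, the root beyond the peak of
  `½·ln(u/t0) + a/u − a/t0 = ln 2` with `u = t + t0`, `a = x²/(4D)`,
  solved by bracketed Brent iteration to 1e−10 relative tolerance.
  `τ½(0) = 3·t0` exactly. `τ½` is strictly increasing in `x`
  everywhere, but increasing in `t0` **only** in the decaying-trace regime
  `x² < 2·D·t0` (implicit differentiation of the root equation changes
  sign at `a = t0/2`); all trend-matching defaults operate inside that
  regime, and the property tests restrict to it.

## Half-time analysis

`τ½` is measured per trace as the first linear-interpolated crossing below
half the value at the first recorded frame (an early-window-maximum
convention is available for traces that still rise). The `(R0, τ½)` points
are fitted by ordinary least squares; the line's inverse slope is the
wavefront speed `v` (per-point ratios `R0/τ½` are also reported, since the
trend has a nonzero intercept `≈ 3·t0`). The speed converts to an
independent diffusion estimate through the empirical correction polynomial
`f(D) = 0.013·D² − 0.51·D + 8.14` (dimensionless, `D` in µm²/s, supported
for 1 ≤ D ≤ 20 where `f ≈ 4`), by solving

    R0² = 4 · D · τ½ / f(D)

for `D` at the reference point `R0 = v·τ½` (reference `τ½` default 700 s).
The quotient placement of `f(D)` is adopted because it reproduces the
consistency between the two estimator routes within tens of percent,
whereas the product placement is two orders of magnitude off; both are
exposed via a `reading` switch. The equation can have two roots because
`f` is quadratic; the solver returns the smallest root in the bracket
[0.01, 100] µm²/s (the physically supported low-`D` branch); roots outside
the bracket are an error, never an extrapolation.

The delay is estimated by simulating `τ½(R0)` curves with the same
half-time operator over a small grid (defaults `D ∈ {4, 10}` µm²/s,
`t0 ∈ {300, 450, 600, 1200, 1800}` s) and selecting the `t0` minimising
the sum of squared errors against the measured points, jointly over the
`D` grid, ties broken toward smaller `t0`. SSE rather than maximum
deviation is used as the criterion; the full SSE table is retained for
diagnostics.

## Global fit

Traces are smoothed with a Savitzky–Golay filter (default window 11
frames, order 3; endpoints by polynomial fit on the truncated window, no
reflection padding) and fitted jointly by bounded trust-region least
squares: one shared `D` (bounds 0.01–100 µm²/s), one amplitude `Bᵢ ≥ 0`
per trace, optionally one additive baseline per trace (off by default —
the model has none), and `t0` either fixed at the known experimental delay
(the default) or shared-free within 0–3600 s. ROI distances are metadata,
never fitted. Five log-spaced initial values of `D` span the bounds;
amplitudes are initialised by linear projection at each start. Standard
errors come from the Gauss–Newton covariance `(JᵀJ)⁻¹·RSS/dof`; a fitted
`D` at a bound is flagged and warned about, never silently returned.
Least squares is unweighted.

Misspecifying the fixed delay biases `D`: an understated `t0` forces the
exponential term to supply extra decay (biasing `D` low), an overstated
`t0` pushes `D` toward the upper bound. This is why the independent
trend-matching estimate of `t0` is valuable as a cross-check. Note on
units: the fit is unit-agnostic; expressing times in minutes yields `D` in
µm²/min, numerically 60× larger.

## Synthetic data

Presets encode the assay's regimes with the conditions of the underlying
study: agarose calibration gels (`D` = 18.1, 8.9, 2.6 µm²/s; `t0 = 0`;
ROIs 30–200 µm in 10 µm steps; 720 frames every 5 s, first frame 5 s after
injection), control embryos (`D` = 12 µm²/s, `t0` = 320 s, ROIs 10–40 µm
in 5 µm steps — 7 ROIs) and xenografted embryos (`D` = 1.0 µm²/s with
variants 1.9 and 0.82, `t0` = 600 s, same ROI grid). The 5 s cadence and
720-frame duration are used for all regimes. Camera noise is additive
Gaussian with variance `read_sigma² + shot_scale·signal`
(defaults 2² + 0.05·signal), seeded and bit-reproducible. The amplitude
default `B = 20000` a.u. puts the peak trace SNR near 50, which makes
replicate-to-replicate scatter of the fitted control `D` a few tenths of a
µm²/s — matching the reproducibility the assay is known to achieve; at
SNR of a few, the shared `D` of the embryo regime becomes weakly
identified (the spatial decay across a 10–40 µm ROI span is shallow), which
is a property of the estimation problem, not of the optimiser. A
"pressure ramp" — a linear intensity rise saturating after ~10 s within
10 µm of the source — emulates the injection-pressure artefact seen near
the needle; it is rendered but never fitted (agarose ROIs start at 30 µm).

Rendered stacks evaluate the model at each pixel's Euclidean distance from
a point or segment source (default pixel size 1.375 µm/px, the 4×-binned
camera scale), with a static binary vessel channel. What the generator
does **not** emulate: vascular-network morphology, photobleaching, embryo
motion, flow advection inside vessels. Passing tests therefore demonstrate
correctness of the estimators under the model's own assumptions, not
robustness to those real-data effects.

## Optics QC

Sheet thickness: every image line is fitted to a Gaussian plus constant
offset; `FWHM = 2√(2 ln 2)·σ·pixel_size`; lines failing the fit or with
amplitude below 3× the residual noise are excluded and counted. Bead PSF:
local maxima are gated to singletons by integrated intensity (within
0.7–1.4× the median, rejecting overlapping doublets), then each spot's
profile is fitted by an isotropic 2-D Gaussian with free centre and
background. Bead-size deconvolution is not applied (1 µm beads against a
~3 µm PSF bias the width by under 5%). The Rayleigh range is reported
under the standard 1/e² waist convention `z_R = π w0²/λ`,
`w0 = FWHM/√(2 ln 2)` — about 280 µm for a 7.8 µm sheet at 488 nm; other
conventions in circulation give larger figures.

## Numerical choices and degenerate inputs

- Brent root-finding everywhere a scalar root is needed (half time, `Dv`),
  with explicit brackets; bracket expansion by doubling for the half time.
- ROI bands are annuli `[d − w/2, d + w/2)` in physical distance; empty
  bands raise errors naming the offending distance. Band discretisation
  biases extracted traces by ≲2% against the ideal point evaluation, and
  the stack-level pipeline recovers preset `D` within ~5% (the trace-level
  route is exact).
- Re-binning is sum-binning (camera semantics); trailing rows/columns are
  dropped.
- Traces that never cross half their initial value are skipped with a
  warning in trend building (common for far ROIs of slow-diffusion
  presets within a finite recording); at least 3 valid points are required.
- Problem sizes: 720-frame presets, 7–18 ROIs, 128×128 rendered stacks,
  200-replicate noise-statistics checks, 20-replicate noisy-recovery
  checks — all chosen so the entire suite validates in well under a
  minute per module.

## Known limitations

The `f(D)` polynomial is empirical and only supported on 1–20 µm²/s; `Dv`
is an order-of-magnitude cross-check, not a precision estimator (it agrees
with the global fit within a factor of 2 on control-regime data). The
delay estimator returns a grid value, not a continuous optimum. The
global fit assumes a single diffusion component and known ROI distances.
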