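# Methods

## The estimation problem

Wide-field RGB imaging of exposed cortex carries quantitative information
about cerebral hemodynamics: the diffuse reflectance spectrum of brain tissue
is shaped by hemoglobin absorption (oxygenation-dependent) and by light
scattering (morphology-dependent), and a color camera samples that spectrum
through three broad channels. `oximap` implements a spectrocolorimetric
method that inverts this: a linear estimator, calibrated against Monte Carlo
simulations of light transport, maps each pixel's (R, G, B) to oxygenated and
deoxygenated hemoglobin concentration and to the scattering power, from which
total hemoglobin and oxygen saturation follow.

## Tissue model

The cortex is treated as a single homogeneous layer. Absorption comes from
hemoglobin only:

    mu_a(lambda) = (C_HbO / 100) * mu_a,HbO,blood(lambda)
                 + (C_HbR / 100) * mu_a,HbR,blood(lambda),

where concentrations are percentages of a whole-blood reference (150 g/L
hemoglobin, 44% hematocrit); `C_HbT = 100` means the tissue absorbs like
whole blood. Reduced scattering follows a power law,

    mu_s'(lambda) = a * lambda**(-b),

with `lambda` in nm and `a` in cm^-1 nm^b (a unit convention this package
fixes, since several conventions circulate; with the typical amplitude
a = 12e4 and b = 1.38 this gives mu_s' ~ 23 cm^-1 at 500 nm, a plausible
cortical value). The scattering power `b` is a proxy for scatterer size and
falls when cells swell, e.g. during anoxic depolarization.

The shipped hemoglobin extinction table
(`data/hemoglobin_extinction_synthetic.csv`) is a synthetic reconstruction
from widely published landmark values (Soret maxima, Q-bands, isosbestic
points, red-tail oximetry values), not a verbatim copy of any tabulation. The
pipeline is self-consistent — calibration and estimation share the table — so
its absolute accuracy affects realism, not the method's internal validity.
Molar extinction is converted to whole-blood absorption with
mu_a = ln(10) * eps * (150 / 64500) cm^-1.

All spectra live on a fixed working grid, 400–700 nm at 10 nm (31 samples).
Input curves are linearly resampled onto it; extrapolation is refused.

## Monte Carlo transport

Total diffuse reflectance is estimated by a weighted-photon random walk in a
plane-parallel slab with isotropic scattering and, by default, a matched
(refractive-index 1) boundary:

- free path: `dl = -ln(xi) / (mu_a + mu_s')` (Beer's law);
- at each interaction a fraction `mu_a / (mu_a + mu_s')` of the photon weight
  is deposited, so the weight after k interactions is `albedo**k` — the
  deposit rule is applied at *every* interaction site, including the first;
- new direction: `cos(theta) = 2 xi - 1`, azimuth uniform (the azimuth never
  affects plane-parallel escape and is not tracked);
- weight escaping the top surface, divided by launched weight, is the
  reflectance O = I / I0.

Termination: photons below a weight threshold (default 1e-4) play Russian
roulette (survival 0.1, unbiased). With roulette disabled the residual weight
is tallied instead, making the energy balance
reflected + transmitted + absorbed + residual = launched *exact* (tested to
float precision). An optional Fresnel boundary (relative index 1.4) models
internal reflection; it is off by default because the matched boundary
realizes the sampling equations above exactly.

One caveat on limits: for `mu_a = 0` in a semi-infinite medium every photon
escapes eventually (the walk is recurrent) so R = 1 analytically, but the
escape time has infinite mean and the simulation cannot terminate reliably.
The no-absorption limit is therefore verified in a thick finite slab as zero
deposited weight plus an exact escape balance.

### Albedo lookup table

In mean-free-path units the sampling rules depend on (mu_a, mu_s') only
through the single-scattering albedo `mu_s'/(mu_s'+mu_a)`; for a semi-infinite
medium the reflectance is a function of the albedo alone (verified by a
scale-invariance test, R(mu_a, mu_s') = R(c mu_a, c mu_s')). The calibration
therefore simulates reflectance once on a set of albedo knots — uniform in
sqrt(1 - albedo), which linearizes the steep approach of R to 1 — and
interpolates with a monotone cubic (PCHIP) in that variable. The analytic
endpoints R(0) = 0 and R(1) = 1 anchor the table. This reduces a full
calibration from 450 states x 31 wavelengths Monte Carlo runs to ~25 runs.

Default photon budgets: 1e5 per run for calibration-grade tables (the LUT
build takes seconds), 2e4 in the test suite. The LUT route is validated
against direct simulation (off-knot interpolation within 3 combined standard
errors) and against an independently coded unweighted absorb-or-scatter
simulator.

## Calibration grid and regression

The calibration grid is the Cartesian product of

- scattering amplitude: 0.5, 0.75, 1.0, 1.25, 1.5 x the typical 12e4 cm^-1
  nm^b (i.e. 6e4 … 18e4);
- scattering power b: 1.24, 1.31, 1.38, 1.45, 1.52 (explicit values; note
  these are *not* 0.5–1.5 x 1.38 — the explicit list is authoritative);
- total hemoglobin C_HbT: 5, 10, 20 %;
- saturation StO2: 0, 20, 40, 60, 80, 100 %,

i.e. 450 states, enumerated in a documented nested-loop order (a, b, C_HbT,
StO2, each ascending) so calibration is bit-reproducible given a seed. Each
state's simulated spectrum is pushed through the camera model to an RGB
triple, and three ordinary-least-squares regressions of C_HbO, C_HbR and b on
(1, R, G, B) — unweighted, with intercept, no regularization — yield the 4x3
coefficient matrix N. Estimation is then `[C_HbO, C_HbR, b] = N^T [1, R, G,
B]` per pixel, with `C_HbT = C_HbO + C_HbR` and `StO2 = 100 C_HbO / C_HbT`
(guarded by eps = 1e-6 in concentration units; undefined pixels are excluded
from ROI means and counted).

The linear map is a deliberate simplification of nonlinear physics: training
R^2 is around 0.5 per target on the default grid and camera, individual-pixel
estimates can overshoot (negative concentrations, StO2 outside [0, 100]), and
at a calibration grid point the pipeline converges to that row's *fitted*
value, not the truth. Estimates are therefore reported raw with flagged-pixel
counts; clipping is presentation-only and off by default. What the method is
good at — and what the tests assert — is *tracking*: monotone response to
isolated parameter changes and strong rank correlation between estimated and
true trajectories.

## Camera model and white reference

A channel value is the rectangle-rule integral over 400–700 nm of
illuminant x sensitivity x reflectance, normalized per channel so a perfect
reflector maps to (1, 1, 1). The real camera and LED illuminant of the
original imaging system are unpublished, so the default model is synthetic:
Gaussian sensitivities peaking at 460/540/610 nm with 70 nm FWHM under an
equal-energy illuminant, overridable by CSV curves. The model is strictly
linear (no gamma); measured images are converted to reflectance by dividing
by a white-diffuser image of known reflectance (99% default), which makes the
estimator invariant to illumination intensity. A calibration file stores the
hash of the camera model it was trained with, and estimation warns on
mismatch.

## Synthetic sequences

The generator renders the inspired-oxygen protocol the method targets:
hyperoxia (StO2 80%, C_HbT 9%), normoxia (55%, 10%), hypoxia (30%, 12%),
anoxia (5%, 15%), with exponential approach to episode targets (time constant
10 s) and, during anoxia, a delayed (60 s) rapid (tau 5 s) scattering-power
drop from 1.45 to 1.26 emulating anoxic depolarization. These defaults were
chosen once as physiologically plausible values inside the calibration grid.
Frames are rendered through the same optics -> LUT -> camera forward chain,
quantized to 16-bit counts (gain 30000), with optional additive Gaussian
noise applied after quantization (shot noise is out of scope). The spatial
layout is two dark vessel strips (C_HbT 20%) over uniform parenchyma; vessels
deliberately violate the homogeneity assumption (the method lacks depth
resolution), so accuracy checks use the parenchyma mask. Frame timing is
configuration-driven (the frame interval is a scenario parameter).

What passing tests show: the pipeline recovers programmed *trajectories*
(StO2 correlation > 0.95 on the zero-noise phantom; negative relative change
of b after the programmed drop). What they do not show: absolute quantitative
accuracy on real cortex, which depends on the true camera curves, the real
extinction spectra, heterogeneous vasculature and specular/curvature effects
absent from the phantom.

## Numerical and design choices

- Slab thickness defaults to 10 cm (effectively semi-infinite for cortical
  optical properties); `inf` is accepted. Transmitted weight is tallied
  separately.
- RNG: numpy PCG64, integer-seeded; per-wavelength substreams `seed + index`,
  per-LUT-knot `seed + knot index`. Same seed, same platform, same result
  bit-for-bit.
- ROIs are `(x0, y0, width, height)` rectangles, 0-based, origin top-left,
  half-open on the right/bottom.
- Relative changes dM = (M - M_c)/M_c use the mean over an inclusive control
  time window, normally the normoxia episode.
- Degenerate inputs fail loudly: mu_s' = 0, nonpositive white-reference
  pixels (with a count), ROIs out of bounds, rank-deficient regressors (the
  collinear channels are named), calibration files with missing provenance or
  wrong shape.

## Problem sizes

The shipped defaults keep a full calibration-plus-recovery run at around ten
seconds on one core: 25-knot LUT at 1e5 photons, 450-state grid via the LUT,
20-frame 64x64 phantom. A brute-force calibration without the LUT (one
simulation per state and wavelength) is supported (`use_lut=False`) and used
only for spot checks; budgets of 5e6 photons per wavelength are configurable
but bring hours of compute for no change in the conclusions the tests check.
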