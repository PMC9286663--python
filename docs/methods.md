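# Methods

This note documents the model as implemented, the defaults and why they
were chosen, what the synthetic-scene generator does and does not emulate,
and the numerical conventions that matter for reproducing results.

## Kernel model

The directional term is the linear kernel expansion
ρ = f_iso + f_geo·K_geo + f_vol·K_vol, fitted per band and per NDVI bin by
ordinary least squares. Kernel formulas:

* **Li geometric kernels** operate on "primed" zeniths
  θ′ = arctan((b/r)·tan θ) with crown shape b/r (default 10) and relative
  height h/b (default 2). With
  D² = tan²θ_s′ + tan²θ_v′ − 2 tan θ_s′ tan θ_v′ cos φ,
  cos t = (h/b)·√(D² + (tan θ_s′ tan θ_v′ sin φ)²)/(sec θ_s′ + sec θ_v′),
  O = (1/π)(t − sin t cos t)(sec θ_s′ + sec θ_v′), and
  cos ξ′ = cos θ_s′ cos θ_v′ + sin θ_s′ sin θ_v′ cos φ:
  - Li-Sparse (default): K = O − sec θ_s′ − sec θ_v′ + ½(1 + cos ξ′)·sec θ_v′.
    This is the *non-reciprocal* form — the last term carries sec θ_v′
    only. The reciprocal (MODIS) variant is deliberately not offered.
  - Li-Dense: K = (1 + cos ξ′)·sec θ_v′/(sec θ_s′ + sec θ_v′ − O) − 2.
* **Ross volumetric kernels** use the *unprimed* phase angle
  cos ξ = cos θ_s cos θ_v + sin θ_s sin θ_v cos φ:
  - Ross-Thick (default): K = [(π/2 − ξ)cos ξ + sin ξ]/(cos θ_s + cos θ_v) − π/4.
  - Ross-Thin: K = [(π/2 − ξ)cos ξ + sin ξ]/(cos θ_s · cos θ_v) − π/2.

Numerical guards: cos t and both phase cosines are clamped to [−1, 1]
before arccos (grazing geometries), D² is floored at 0. Both kernels
vanish at θ_s = θ_v = 0, so f_iso is the modeled nadir-sun/nadir-view
reflectance. At θ_v = 0 both kernels are azimuth-independent, which is why
the relative azimuth of the modeled nadir term, φ_n, is arbitrary; it is
fixed to 0 and a property test verifies output invariance to it.

With b/r = 10 the Li-Sparse kernel reaches magnitudes of ~5–15 over a
±17.5° swath at mid solar zeniths, so physically plausible f_geo/f_iso
ratios are of order 0.01 — worth knowing when judging fitted coefficients.

## Topographic correction (SCS+C)

Applied per flightline before any BRDF fitting. The per-band moderator
C = a/b comes from OLS of reflectance on cos i over a seeded random sample
(default minimum 1,000 pixels) restricted to valid pixels with NDVI ≥ 0.05
— the same population the BRDF fit draws from, which keeps C
vegetation-driven. The sun–terrain azimuth is φ_t = fold(φ_s − aspect)
into [0, 180°], with aspect the downslope direction.

Degenerate bands (|b| < 1e−6 reflectance units) pass through unchanged:
forcing a correction through a near-zero slope would amplify noise without
an explanatory model. Pixels with |cos i + C| < 1e−8 are masked and
counted. The correction factor is computed as a single ratio so that flat
terrain (cos i ≡ cos α·cos θ_s) is the bit-exact identity.

## NDVI stratification and smoothing

NDVI uses the nearest bands to 665 and 850 nm (≤ 20 nm away, else a
configuration error). Static bins are equal-width over [0.05, 1.0];
dynamic bins place equal-count quantile edges over (0.05, 0.9) from the
pooled group sample, with the top bin extended to 1.0. Bin membership is
right-open, [e_i, e_{i+1}), the last bin closed.

Smoothing knots are bin centers: edge midpoints for static bins, the
median member NDVI for dynamic bins. Modes:

* `none` — per-bin constants; unfitted/empty bins borrow the nearest
  fitted bin so no vegetated stratum is left uncorrectable;
* `linear_interpolation` (default) — piecewise linear between knots inside
  [0.25, 0.85], constant extension outside, hence continuous everywhere;
* `linear_regression` / `weighted_linear_regression` — straight line per
  coefficient over the in-range knots (weights = bin sample counts),
  evaluated at NDVI clamped into the range.

The [0.25, 0.85] restriction avoids letting sparsely vegetated and
near-saturated bins lever the smoothing line. Outside the range the
smoothed curve is extended as a constant; the alternative reading — out-
of-range bins keeping their own per-bin constants — was considered and
rejected for continuity's sake.

## Sampling, fitting, reference zenith

The group sample draws up to `per_bin` pixels (default 10,000) per bin
uniformly at random from the pooled eligible pixels of all lines, so each
line contributes in proportion to its eligible area; the RNG seed is part
of the configuration and of the model sidecar. Bins need ≥ 3 samples and a
full-rank [1, K_geo, K_vol] design; others are flagged unfitted. The fit
stores per-coefficient OLS standard errors (residual variance times the
diagonal of (XᵀX)⁻¹), used by the recovery tests.

The reference solar zenith θ_sr options: solar noon on the acquisition
date; daily solar-noon mean over a season window (inclusive endpoints,
daily sampling); observed mean θ_s over the group (pixel-weighted by
default, line-weighted optional); solar noon on the summer solstice of the
acquisition year; a fixed value; or none (per-pixel θ_s, i.e. pure
nadir-view normalization — the single-line convention). The ephemeris is
the NOAA solar-position equation set with declination evaluated at 0h UT
of the calendar day (the daily-almanac convention); declination accuracy
is ~0.1°, and no refraction correction is applied. Correction divides by
ρ(θ_v, θ_s, φ); pixels with |ρ| < 1e−6 are masked and counted.

## Assessment conventions

RMSE is the root mean squared residual of the simple linear regression of
the later line's overlap values on the earlier line's; MAD is the mean
absolute raw paired difference. The conventions differ on purpose — a pure
offset between lines appears in MAD but not in the regression RMSE — and
the two alternative pairings (difference-RMSE, residual-MAD) are computed
and stored alongside. The regression is direction-dependent; the report
records which line was the predictor (the earlier-acquired line, by list
order). Pixel pairing requires a shared pixel size and grid orientation
and pairs centers within half a pixel; real data must be co-registered
beforehand.

## Synthetic scenes

The generator lays several lines over one world-coordinate surface:
an NDVI field (smooth sinusoidal, or quantized to discrete levels in a
patch checkerboard), analytic sinusoidal hills (or flat terrain), a linear
cross-track view-zenith sweep (±17.5° default) with the sensor azimuth
flipping 180° across nadir, and constant per-line solar geometry spanning
25–50° across the group. Reflectance is the kernel model composed with
the inverse SCS+C modulation plus optional Gaussian noise.

Two deliberate simplifications make truth recoverable and are also the
limits of what passing tests demonstrate:

* anisotropy ratios f_geo/f_iso and f_vol/f_iso are band-independent
  functions of NDVI, and the 665/850 nm bands are generated as s(1 − n)
  and s(1 + n) — so the cube's computed NDVI equals the intended field to
  float precision (real spectra have band-dependent anisotropy and only
  approximately BRDF-resistant NDVI);
* in `discrete` mode the surface takes a fixed set of NDVI levels; with
  fit bins centered on those levels the per-bin constant-coefficient model
  is *exactly* true, which is the only configuration in which noiseless
  fits recover truth at numerical precision and the full pipeline closes
  overlaps to ~1e−15. Smooth-field scenes leave small within-bin model
  error, as real data do.

The generator does not emulate atmosphere, adjacency, sensor noise beyond
additive Gaussian, spatial misregistration, or radiative-transfer realism.
Consequently the tests demonstrate correctness of the estimator and the
workflow, not field performance on real spectra.

Default test problem sizes (3 lines of 120×80 pixels, 10 bands; 260×240
for the noisy-recovery check with 10,000 samples per bin over 18 bins)
were chosen as the smallest scenes in which every bin is well populated
and overlap strips contain all NDVI strata.

## Determinism and sidecars

All randomness flows through explicit integer seeds (topographic sample,
stratified sample, scene generation). The model sidecar and assessment
reports contain no timestamps, so identical configuration plus seed
reproduces byte-identical artifacts; a `manifest.json` with the config
hash, seeds and package version accompanies every fit.

## Known limitations

* Kernel shape constants b/r, h/b are taken as given, not estimated.
* Only SCS+C topographic correction is implemented (the config enum is
  reserved for alternatives).
* NDVI is the only implemented stratifier; the land-cover-classification
  code path is declared but not built.
* ENVI-style rasters are the single I/O dialect; HDF5 products must be
  exported first. Reprojection/mosaicking is out of scope.
* The daily (0h UT) declination convention can differ from an
  instantaneous solar-noon ephemeris by up to ~0.3° on fast-moving parts
  of the declination curve.
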