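# Methods

## Model

The left ventricle (LV) in an apical long-axis view shortens along its
apex–annulus axis during systole.  Between consecutive frames the motion
of the imaged tissue is modeled as a planar affine map,
`x' = F·x + T`, with deformation gradient `F` and translation `T`.
After rigid co-registration (translation removed, long axis vertical)
the residual deformation is dominated by the diagonal stretches
`a11, a22`, and the Lagrange strain along the long axis is
`ε = l/l0 − 1 = a22 − 1` per frame pair.

The estimator never tracks material points.  It uses two spectral facts:
the Fourier magnitude `|G(u,v)|` of a frame is invariant to translation,
and a spatial stretch by `a` maps `|G|` to a wavenumber-rescaled copy
(`u → u/a`).  Expressed on logarithmic wavenumber axes the rescaling is
an additive shift, and the vertical component `Δy'` of that shift gives
the per-pair strain `ε = exp(Δy') − 1` and, divided by the frame
interval, the global longitudinal strain rate (GLSr, 1/s).  Per-pair
rates are integrated with classic RK4 (cubic interpolation of the
midpoint-timed rate series supplies the substep values) and a linear
drift ramp is removed so the strain returns to zero at end-beat.  GLS is
reported in percent, contraction negative; the clinical scalars GLS_P
and GLSrs are peak absolute values, averaged across views when several
are supplied.

Assumptions: the deformation within the region of interest is spatially
homogeneous per frame pair (global, not segmental strain); rotation and
shear have been minimized by the registration; longitudinal shortening
dominates the vertical spectral scale change.

## Measuring the log-domain shift

Implementing "correlate the log-resampled magnitude spectra" naively —
resampling both spectra onto one shared logarithmic grid and phase
correlating — is numerically treacherous at cardiac per-pair strains
(0.5–2.5 %, i.e. sub-sample log shifts).  Three failure modes were
identified and drive the design:

1. **Grid-anchored resampling artifacts.**  The expected value of an
   interpolated magnitude sample depends on its fractional position on
   the source grid.  That deterministic pattern is identical in the two
   frames, so it correlates at exactly zero lag and captures the peak
   whenever the true shift is below about a sample.  The heavily
   oversampled low-wavenumber region of a log grid (many log samples per
   spectral bin) is the worst offender.
2. **Aliasing near Nyquist.**  Beyond roughly half the Nyquist extent
   the spectral fine structure changes per spectral bin while log-grid
   spacing exceeds a bin, so resampled values are aliased noise.
3. **Window re-graining.**  The finite aperture convolves the spectrum
   with a fixed kernel; spectral fine structure whose displacement under
   the scale hypothesis stays below the kernel width is re-anchored to
   the static grain.  This limits resolvable per-pair scale changes to
   roughly `4/side` (≈1 % for 250 px sub-images) — a genuine dead zone
   around zero strain, discussed under limitations.

The production path therefore evaluates the log-domain correlation
profile *lag by lag without a shared grid*: the second frame's
log-compressed, lightly smoothed, high-passed magnitude spectrum is
rescaled in the linear wavenumber domain for each log-spaced scale
hypothesis (with a fixed subsample grid offset so resampler artifacts
never align), scored by zero-mean normalized correlation over a fixed
annulus, and the score curve's peak is refined by a three-point fit.
Scans are run for an isotropic hypothesis and for each axis separately;
the family whose peak scores highest is used (an isotropic scan on
single-axis deformation, or vice versa, leaves one axis mismatched and
scores lower).  The classic quadrant-resampled ensemble-correlation
path is retained in `ltc_core` (`log_resample`, `ensemble_correlate`,
`dynamic_phase_filter`) and behaves well on clean constructed inputs;
`pairwise_strain` uses the scan.

Key parameters (units, default, rationale):

| parameter | default | meaning |
| --- | --- | --- |
| spectral band | 0.06–0.25 cycles/px | annulus used for correlation; below it aperture/clutter dominate, above it the speckle envelope has decayed |
| `log_step` | 0.004 | scale-hypothesis spacing (natural log) |
| `n_lags` | 14 | hypotheses per scan (±5.7 % scale range) |
| apodization | raised cosine, 10 % margin | suppresses crop-edge spectral leakage |
| FFT padding | 2× | resolves spectral fine structure for interpolation |
| ROI radius | 1.3 × max landmark distance | covers the LV; a tighter aperture clips the moving wall ends and biases the scale estimate |
| ROI taper | 25 % of radius | a sharp aperture edge is static spectral content |
| tracking window | 96 px | wide enough to stay locked on the wall under heavy clutter |
| tracking peak-ratio gate | 1.2 | ambiguous correlations hold the landmark |
| tracking step cap | 10 px/frame | cardiac tissue cannot move faster; larger peaks are clutter lock-ons |

Failed pairs (no interior, concave score peak) are flagged missing and
linearly interpolated before integration; more than 25 % failures is an
error.

## Baselines

DCC correlates 32 px interrogation windows (75 % overlap) by zero-mean
normalized, zero-padded spatial correlation; the triangular overlap
weighting of linear correlation is divided out and the peak search
restricted to a quarter of the window, both standard block-matching
practice.  FTC uses the circular conjugate spectral product of
raised-cosine-apodized windows (apodization suppresses wrap-around
leakage).  Displacement fields advect the initial myocardial midwall
polyline with RK4 (bilinear in space, linear in time between fields),
and GLS is the relative arc-length change of the advected polyline,
drift-corrected.  No co-registration is applied to the baselines.

## Synthetic data

`synthetic_phantom` provides the ground truth every stage is tested
against.  Speckle is a sum of Gaussian blobs (FWHM 3 px, matching a
typical B-mode point-spread function at conventional pixel spacing) at
*continuous* random positions.  Frames are rendered by evaluating the
blob sum analytically under each affine deformation — never by warping a
reference grid.  Grid warping leaves an interpolation-error ghost of the
undeformed content, identical across frames, that real acquisitions do
not have; with exact rendering consecutive frames share no artifacts.

The LV phantom draws a U-shaped speckled myocardial band (two straight
walls joined by a semicircular apex cap, wall thickness 20 px) around a
dark blood pool and contracts it by an isotropic scale about the annulus
midpoint following `GLS(t) = −|peak|·sin²(πt/T)`.  Isotropic scaling
makes the midwall arc length shorten by exactly the prescribed strain,
so the waveform, the boundary geometry and the per-pair scale ratios are
mutually consistent to machine precision.  Cavity clutter is spatially
correlated Gaussian noise (3 px correlation length — reverberation haze,
not pixel noise), evolving as an AR(1) process between frames (φ = 0.8),
filling the blood pool and an 18 px halo around the walls; its amplitude
is calibrated by bisection so the contrast-to-noise ratio
`CNR = |μ_V − μ_T| / sqrt(σ_V² + σ_T²)` measured on the emitted frames
hits the requested target within ±0.5 dB.

What the phantom does **not** emulate: out-of-plane motion and speckle
decorrelation, attenuation and shadowing, vendor post-processing, and
beam-geometry (sector) sampling.  Passing tests therefore demonstrate
the estimator's geometric and noise behaviour, not its performance on
vendor-realistic images; in particular the phantom's high-CNR error
floor is lower than real data would give, which makes *relative*
CNR-stability statements stricter here than on real images.

## Numerical choices

- Intensities are rescaled by dtype maximum on load, preserving
  inter-frame brightness for CNR computation.
- The registered sub-image side is `2·ceil(roi_radius)+1` (odd, so DC
  lands on a pixel); angle convention is positive clockwise in image
  coordinates (y down), correction rotates by the negative angle.
- Subpixel peaks use a three-point Gaussian fit per axis, falling back
  to parabolic when neighbors are non-positive; border peaks, flat
  planes and tied maxima raise.
- Cross-spectrum bins below 1e-12 of the maximum are zeroed before
  phase normalization (they carry no phase information).
- Bootstrap ROC: percentile method, subjects resampled with replacement
  and repeated measurements resampled within selected subjects, 1000
  resamples by default; lower metric values indicate disease.
- CNR bins for error reports span 1–8 dB in 0.5 dB steps, left-closed,
  with the final edge included.

## Limitations

- **Small-strain dead zone**: per-pair scale changes below roughly
  `4/side` (≈0.5–1 % for the sizes used here) are pulled toward zero by
  the window re-graining effect.  Integration and drift correction mask
  most of the impact on the beat-level GLS curve, but per-pair rates
  near the beat's turning points are underestimated.
- At a raw-ratio CNR of 2 the clutter amplitude is several times the
  tissue texture amplitude; the direct estimator degrades gracefully
  (normalized MAE roughly doubling relative to its very low high-CNR
  floor) rather than being unaffected.
- Landmark tracking with the wide clutter-robust window averages motion
  over its support and slightly under-tracks the fast-moving apex; the
  strain kernel is translation invariant, so this mostly affects the
  ROI placement, not the strain.
- Only global longitudinal strain is estimated: no segmental strain, no
  rotation/shear recovery, no circumferential or radial components.
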