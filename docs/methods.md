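# Methods

`ulmkit` reconstructs super-resolved cerebral microvascular maps from
ultrafast contrast-enhanced ultrasound frame stacks and quantifies the
regional vascular properties used to compare cohorts (blood volume,
vascularity, velocity, sum-of-angles tortuosity, velocity-distribution
skewness). Because in vivo acquisitions of this kind are rarely shareable,
the package carries a synthetic-scene simulator that emulates their
statistical structure and provides ground truth for every stage.

## The reconstruction model

One acquisition is a stack of complex beamformed in-phase/quadrature (IQ)
frames, `(depth, lateral, frames)`, acquired at a compounded frame rate of
1000 Hz with a 20 MHz center frequency. The processing chain is:

1. **SVD clutter filtering.** The stack is reshaped into a Casorati matrix
   (space x time) and decomposed; tissue echo is orders of magnitude
   stronger than microbubble signal but spatiotemporally coherent, so it
   concentrates in the leading singular components. Components `1..k` are
   zeroed and the stack reassembled. `k` is chosen adaptively as the elbow
   (maximum discrete curvature) of the log10 singular-value curve, clamped
   to a configurable range.
2. **Noise equalization.** Electronic noise grows with depth, so a
   per-depth gain profile is estimated and divided out. The noise surrogate
   is the reconstruction from the trailing singular components — everything
   below the strongest 10% of components, which carry bubble and residual
   tissue energy. The trailing-90% construction is used because restricting
   the surrogate to only the lowest-energy components biases the estimate:
   sample singular vectors align with the quieter rows, compressing the
   recovered depth gradient (tested: a 2x linear amplitude ramp is
   recovered flat to ~0.5 dB with this surrogate versus ~1.4 dB with a
   bottom-10% surrogate). The profile (mean |amplitude| per depth row,
   smoothed over 5% of rows) equalizes amplitude, and is returned so power
   equalization can be reconstructed if preferred.
3. **Microbubble separation (optional).** A partition-of-unity bank of
   Fourier-domain transfer functions splits the stack into sparser subsets
   by axial flow direction (temporal-frequency sign) and Doppler speed
   band. The subsets sum exactly back to the input. Hard frequency edges
   ring in time: flow perpendicular to the beam sits at zero Doppler and a
   direction split smears such bubbles into both subsets with slowly
   decaying temporal tails. The separation step therefore defaults off in
   the cohort pipeline, whose scenes are already sparse, and on (4 subsets)
   as the standalone operation's default for high-concentration data.
4. **Upsampling and localization.** Each frame's magnitude is
   cubic-spline-interpolated onto an isotropic 4.928 µm grid (an exact x10
   of the 49.28 µm native pitch; grids registered center-to-center). A
   normalized 2-D cross-correlation with an empirically fitted anisotropic
   Gaussian PSF (least-squares fit to an isolated bubble; defaults
   sigma_axial 60 µm, sigma_lateral 65 µm, consistent with the ~150 µm
   lateral FWHM of a 20 MHz system at f-number ~2) yields a coefficient
   map. The PSF width also bounds usable bubble concentration: the
   correlation is normalized over the template support (3 sigma), so a
   neighboring bubble inside that window displaces the peak — scenes keep
   concurrent bubbles at least ~2.5 lateral sigma apart;
   pixels under the correlation threshold (default 0.5) are discarded and
   each surviving regional maximum contributes one centroid at its pixel
   center. Correlation is amplitude-blind, so the pipeline additionally
   gates detections at a configurable fraction (default 0.30) of the
   stack's 99.5th-percentile magnitude: without it, low-level PSF-shaped
   residue — in particular the negative "trail" a slow bubble leaves in the
   removed rank-1 component — is detected alongside real bubbles. An
   optional correlation-weighted centroid refinement provides subpixel
   positions; `localize_frame` keeps the pixel-center convention by default
   (mirroring the regional-maximum step of the original workflow) while the
   cohort pipeline enables refinement, which removes most of the
   quantization jitter that otherwise inflates step-based speeds.
5. **Tracking.** Centroids are paired frame-to-frame by minimum-total-
   distance linear assignment (Hungarian algorithm) under a speed gate
   (default 50 mm/s; the gate is an explicit configuration value). Ties
   break deterministically. Gap closing defaults to 0 (strict
   frame-to-frame) and can be raised. Tracks shorter than 20 frames (20 ms
   at 1000 Hz) are discarded.
6. **Mapping.** Each track deposits along the rasterized line between
   consecutive centroids: density counts traversals per super-resolved
   pixel (one per track), and the speed and direction channels average the
   depositing tracks' mean speed and axial direction sign. Per-acquisition
   maps are rigidly registered to the first acquisition by FFT-based
   normalized cross-correlation over integer-pixel cyclic shifts, the
   shifts are applied to the localizations, and the maps merged.
   Diffraction-limited comparators: power Doppler (temporal mean power),
   contrast power (ROI- and time-summed power), and color flow via the 2-D
   autocorrelation estimator, `v = c*PRF*phi / (4*pi*f_hat)` with `phi` the
   lag-1 slow-time autocorrelation phase and `f_hat` the mean RF frequency
   from the lag-1 fast-time autocorrelation (nominal f0 where degenerate);
   velocities clip at the Nyquist limit `c*PRF/(4*f0)`.

## Quantification

Regions of interest are closed Hobby splines through ordered control
vertices (in-repo implementation of the cyclic tangent-angle system and
velocity function; default tension 1, higher tension pulls the boundary
toward the control polygon), rasterized by the even-odd rule at pixel
centers; self-intersecting boundaries are rejected naming the crossing
segment pair. Metrics per region:

- **Blood volume** — mean number of distinct tracks entering the ROI per
  acquisition (a track is counted once however often it crosses).
- **Vascularity** — percent of ROI pixels with density at or above the
  binarization threshold (default 1 traversal).
- **Velocity and SOAM** — track-weighted means over intersecting tracks.
  Per-track speed is the arithmetic mean of frame-to-frame step speeds;
  SOAM is the summed unsigned turning angle divided by path length
  (deg/mm), with the raw angle sum and the distance metric (path /
  end-to-end) also available.
- **Vessel stratification** — 1-D K-means (k = 6) on log10 of nonzero
  density values, deterministic quantile initialization (so the
  segmentation is invariant to pixel ordering), clusters ranked by
  centroid; the top 2 form the large-vessel mask. Intervessel distance is
  twice the mean distance-transform value of non-vessel ROI pixels to the
  nearest large-vessel pixel (wall-to-wall convention, recorded in output).
- **Velocity skewness** — adjusted Fisher-Pearson G1 of per-track mean
  speeds across the whole field.

Statistics: two-way ANOVA (age group x region; Type II sums of squares,
appropriate for the unbalanced cohorts typical of aging studies) with Tukey
HSD pairwise post-tests filtered to the age contrast within each region;
ordinary least squares of each metric on age (weeks) and sex; Welch's
t-test for the skewness comparison (the comparison's test is a recorded
choice). Subjects failing quality control carry a flag honored by the
aggregation layer.

## The simulator

The synthetic-scene module (`ulmkit.synthetic`) builds planar vascular scenes (straight, sinusoidal, or
piecewise centerlines) and renders acquisitions with three components:

- **Microbubbles**: Poisson arrivals per vessel advected along the
  centerline (plug flow by default, parabolic optional) at a fixed
  perpendicular lumen offset, rendered as the scene PSF times a carrier
  whose phase advances with axial position as `-4*pi*f0*z/c`, so
  autocorrelation estimators see the physically correct Doppler.
  Arrivals are thinned to a minimum along-vessel separation (default
  250 µm, ~2.5 lateral sigma): plug flow preserves chance close pairs for
  their entire transit, and such interfering point targets violate the
  sparsity the localization model presumes (the same role the separation
  filter plays for real high-concentration data).
- **Tissue**: a spatially correlated complex field, static by default or
  drifting subpixel sinusoidally, scaled 30 dB above the unit bubble peak.
- **Noise**: circular white noise with amplitude growing with depth
  (default 1 dB/mm).

Ground truth (tracks at frame resolution, per-vessel masks, assigned
speeds, centerline tortuosity) is recorded for every acquisition.

Cohort presets share one base layout per seed: a cortical band of eight
near-vertical penetrating vessels and a deep band of five lateral
sinusoidal vessels, speeds lognormal around 5 and 8 mm/s. The aged preset
applies documented multiplicative contrasts — cortical vessel count x0.7,
group mean speed exactly x0.8 (rescaling applied last, after a heavier-tail
reshaping of the speed distribution and a floor at ~2.4 mm/s), sinusoid
amplitude x1.5. The speed floor reflects the slowest flow the 20-frame
track minimum and pixel-grid localizer resolve cleanly; without it the
slowest vessels' bubbles dwell so long at one site that their imprint on
the removed clutter component leaves trail artifacts.

### What the simulator does not emulate

No wave propagation or beamforming, no nonlinear bubble oscillation, no
out-of-plane motion or elevational beamwidth, no aberration, and tissue
motion limited to subpixel rigid drift. Passing tests therefore show the
processing chain is correct under its own model assumptions — filter
separability, PSF-shaped point targets, Poisson-sparse bubbles — not that
it is robust to in vivo physics such as respiratory motion, skull
aberration, or concentration-dependent bubble signal changes.

## Numerical choices and scale

- Reduced-scale cohort runs use a 64 x 64 native grid (3.15 x 3.15 mm) and
  400-frame clips, one per subject. Clip length matters: the clutter
  filter's removed components carry the time-averaged bubble trail, whose
  amplitude scales with the bubble's residence-to-clip-length ratio; 400
  frames keeps it below the amplitude gate for the presets' slowest flow
  (the full-scale protocol's 1600-frame clips serve the same purpose). The
  `scale="full"` switch selects 1600 frames x 80 acquisitions.
- The pipeline's SVD clamp defaults to [1, 30] because the synthetic static
  tissue is near-rank-1 and a higher floor would delete slow-bubble signal;
  the module-level default clamp [5, 30] matches the 10-20 components
  typically removed from in vivo data with tissue motion.
- The cross-correlation localizer matches `skimage.feature.match_template`
  to ~1e-13 (verified in tests) but caches the template spectrum across
  frames.
- One master seed derives per-subject, per-acquisition child seeds through
  `numpy` seed sequences; reruns are bit-identical, and every output file's
  checksum lands in the run manifest.
- Assignment ties, K-means initialization, and ROI rasterization are all
  deterministic; degenerate inputs (empty frames, single-point tracks,
  zero-variance samples, all-zero registration images) return empty results
  or raise with specific messages as documented per function.

## Known limitations

- Per-track mean speed is biased upward by localization jitter (step
  lengths are strictly positive). With subpixel refinement the bias is
  below 1% on clean plug-flow scenes and modest (order 10%) in full cohort
  scenes with tissue, noise and interference; it is common to both cohorts,
  so group contrasts keep their direction. The end-to-end checks assert
  contrast direction; absolute recovery is verified separately on plug-flow
  scenes.
- The elbow cutoff assumes a visible knee between clutter and
  bubble/noise singular values; spectra without one fall back to the lower
  clamp with a warning.
- Registration is integer-pixel and rigid; subpixel and non-rigid motion
  are out of scope.
- SOAM on recovered tracks includes a jitter floor; comparisons are valid
  between groups processed identically, not against centerline analytics.
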