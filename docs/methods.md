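# Methods

`brachytrack` is a desk-scale simulator and analysis pipeline for a
six-camera gamma imaging system that localizes an Ir-192 HDR brachytherapy
source in 3D during treatment.  This note describes the models the package
implements, the parameters that matter, the design decisions taken where the
design was genuinely open, and what the package's tests do and do not show
about a physical system.

## System geometry

Six compact detector panels sit on a 500 mm-radius ring around the patient
axis at ring angles 270°, 306°, 342°, 18°, 54° and 90° (a semicircular
arrangement leaving the couch side free).  Each panel is a 25.8 × 25.8 × 4 mm
pixelated scintillator (38 × 38 pixels, 0.6 mm pitch, 0.5 mm active aperture)
behind a diverging tungsten collimator: a 38 × 38 array of square holes whose
axes all pass through a focal point *behind* the detector, so the camera
minifies a large field of view onto its small face.  Collimator parameters
are the open hole width *d*, septal wall *t* (with fixed pitch
*d* + *t* = 0.6 mm), height *h*, and the acceptance angle.

The acceptance angle is interpreted as the full field angle subtended by the
outermost hole axes across the detector face, giving the focal length

    F = (face_size / 2) / tan(acceptance_angle / 2),

i.e. F ≈ 31.14 mm for the default 45°.  This is one of two plausible
parameterizations of "acceptance angle" for a diverging collimator (an
alternative fixes the magnification at a reference distance); the focal
length can therefore be overridden directly (`focal_length_override`).
With the default geometry the minification from the isocenter plane to the
detector is ≈ 18×: 1 mm at the patient maps to 0.055 mm on the detector
face, which is the single number that drives most of the behavior discussed
below.

Because all six panels near one axial plane constrain the longitudinal (z)
coordinate only weakly, the panels are staggered in z; the default stagger
is ±25, ±15, ±5 mm in ring-angle order.  The world frame is right-handed,
origin at the isocenter, z along the patient axis, millimetres throughout.

## Photon transport

Transport is geometric: monoenergetic photons emitted isotropically from the
source capsule (0.6 mm ⌀ × 3.5 mm cylinder, 360 mCi default) are detected by
pixel (i, j) iff their straight path threads the matching collimator hole —
it must cross both the patient-side (entrance) and detector-side (exit)
apertures of the same hole, which by the convexity of the tapered hole is
necessary and sufficient.  The energy window and scintillator stopping power
collapse into a single `detection_efficiency` scalar; phantom scatter, the
Ir-192 emission spectrum and detector saturation are out of scope.  A flat
`ambient_background` expected count per pixel is available to emulate the
room/scatter pedestal the geometric model lacks (used by the collimator
sweep so that SNR is well defined; default 0).

Two evaluation routes share this model:

* **Analytic expectation** (`expected_image`): for each source sub-volume
  point the exit aperture is projected onto the entrance plane, intersected
  with the entrance aperture, and the exact solid angle of the intersection
  rectangle accumulated (arctangent formula).  The source cylinder is
  discretized into ≤ 1000 deterministic sub-volumes (axial layers × sunflower
  discs; default 96).  Deterministic, no RNG.
* **Monte Carlo** (`simulate_image`): emission points uniform in the
  cylinder; directions importance-sampled onto the entrance apertures
  (uniform hole choice, uniform point in the aperture) with the exact
  `A·cosθ / 4πr²` weight; accepted weights accumulate an unbiased estimate
  of the expected image whose Poisson realization is returned.  Per-panel
  generators are spawned from the master seed via numpy's `SeedSequence`,
  so acquisitions are bit-reproducible.

Septal penetration is optional (off by default): blocked paths are
attenuated by `exp(−μℓ)` with the tungsten path length ℓ estimated by
sampling the chord against the focal-scaled hole lattice (the hole pattern
at height z is the detector-face pattern scaled by z/F).  μ defaults to
0.625 /mm (tungsten near the 300 keV window center).  The penetration model
uses the central ray per hole and is deliberately approximate; it supplies
the qualitative thin-septa resolution loss, not dosimetric accuracy.

## Image-quality metrics

Profiles are the row and column through the brightest pixel (lexicographic
tie-break).  The background estimate is the mean of the outer 25 % of
samples at each end of the profile.  FWHM interpolates the two half-maximum
crossings nearest the peak linearly; the half level is measured above the
background by default (robust to penetration pedestals), or above zero on
request.  SNR is `(N_signal − N_noise) / N_noise` with the profile peak as
signal.

With this purely geometric transport the on-axis point response of the
default design is essentially two pixel rows wide at every height — i.e.
the optimized system sits at its sampling-resolution floor (FWHM = 1.2 mm =
2 pixels), which is the plateau value the height sweep converges to.  The
*decreasing* branch of the resolution-vs-height trend seen with full
physics is driven by septal penetration and scatter at low heights; with
penetration enabled the thin-septa (t = 0.1 mm) response degrades
accordingly.  A genuinely geometric effect the sweep does reproduce: at
t = 0.4 mm (d = 0.2 mm) and large heights the on-axis source falls into the
blind gap between the four central holes and the signal collapses — the
counterpart of the poor SNR observed for thick septa.

## Reconstruction

Raw 38 × 38 count images are resampled onto a `factor`-times finer grid and
smoothed with an isotropic Gaussian (`σ` = 0.6 mm, factor 4 by default;
total intensity preserved), then a Simultaneous Iterative Reconstruction
Technique inverts the multi-view geometry:

    X_{k+1} = X_k + C Aᵀ R (b − A X_k),   X_0 = 0,

with `R = diag(1/row sums)` and `C = diag(1/column sums)` of the weight
matrix, exactly `iterations` = 3 updates, and nonnegativity clamping after
each update (both configurable).  Rows/columns with vanishing sums are
guarded (inverse set to zero), so no NaN/Inf can arise.

The projector pair is the package's central numerical design decision.  A
conventional pencil-ray discretization (one ray per detector pixel) fails
here outright: at 18× minification adjacent pixel rays are ≈ 5.4 mm apart
at the isocenter, so most 1 mm voxels fall between rays and acquire zero
column sum.  Instead the forward model of a voxel is the collimator's own
point response at the voxel center — the separable product of entrance/exit
aperture overlaps for the (at most 2 × 2) nearby holes, times the
solid-angle factor — deposited on the raw pixel grid and passed through the
same up-sample + Gaussian operator applied to measured images.  The
backprojector is the exact transpose, so ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ holds to
machine precision (the adjoint property SIRT's scaling assumes), and the
model reproduces the hole-lattice structure of real projections.  The
solid angle uses the area/r² approximation, which differs from the exact
rectangle solid angle by O((aperture/distance)²) ≈ 10⁻⁵ here.

Reconstruction support is restricted to the intersection of all panels'
fields of view with the ball inscribed in the volume grid.  Cube-corner
voxels see only short projection chords; their large row-sum corrections
would otherwise amplify any signal tail crossing them into spurious bright
rim voxels (observed, and eliminated by the ball mask, which also matches
the system's quasi-spherical effective volume).

Default grid: 160 mm cube at 1 mm voxels, centered on the isocenter —
covering the ~12–13 cm effective volume with margin.  Sub-voxel accuracy
comes from the centroid, not the grid.

## Localization

The source position is the intensity-weighted centroid of the reconstructed
volume over voxels above `threshold_fraction × max(w)`.  `centroid()`
defaults to 0.1 and accepts 0.0 (the literal center-of-mass equation); the
*pipeline* default is 0.3, because at 3 SIRT iterations the volume still
carries backprojection streak mass which, below ~0.3 of the peak, dominates
the thresholded set and drags the centroid toward the volume center by tens
of millimetres.

### The quantization systematic, and bias correction

The geometric point response is lattice-locked: which holes light up, and
with what weights, is a periodic function of the source position with the
object-side hole pitch (≈ 10.8 mm) as period.  The resulting localization
bias of the SIRT-centroid estimator is a deterministic sawtooth — amplitude
up to ≈ 2.5 mm, period ≈ 5.4 mm (half the lattice period, by the two
symmetric alignments per period) — independent of the up-sampling factor,
smoothing width and iteration count (verified by scanning the bias map).
Because the forward model is matched, this systematic is predictable:
`track_source` therefore applies `refine_passes` (default 1) fixed-point
corrections, simulating the noiseless pipeline at the current estimate and
subtracting the predicted bias.  This removes the systematic wherever the
composite position→centroid map is invertible.  Where the sawtooth's slope
reaches −1 the map plateaus — positions ~3 mm apart produce identical
outputs, the information is destroyed upstream of any estimator — leaving
residual worst-case errors of ≈ 1.5–2 mm at a few displacement phases.
Over the ±60 mm scan range the pipeline achieves a mean 3D error of
≈ 0.8 mm with per-axis errors ≤ 1 mm at most, but not all, scan positions;
a broader, smoother physical response (scatter, spectrum, detector blur —
all outside this model) dithers the lattice and is how a full-physics
system avoids the worst phases.

Error metrics: per-axis absolute differences and the Euclidean distance
between original and reconstructed positions.  Summary averages count
repeated original coordinates once (`dedupe`), the convention under which
the embedded reference tables' printed averages reproduce exactly; it is
exposed as a flag.  Comparisons against printed tables use round-half-even
to 3 decimals.

## Reference tables

The published solid-phantom scans (x/y/z, 0–80 mm in 10 mm steps) and the
19 patient dwell positions ship as CSV fixtures with original coordinates,
reconstructed coordinates and printed Euclidean distances.
`recompute_reference_metrics` recomputes every distance and every summary
average from the coordinate pairs and compares at one printed ulp (0.001).
Two distance cells and one summary average are internally inconsistent with
their own published coordinates beyond that tolerance (the source data were
evidently summarized from unrounded values); they are flagged as documented
outliers and pinned to their frozen recomputed values, and any undocumented
mismatch fails loudly.

## Problem sizes

Unit tests reconstruct on 2–4 mm voxel grids with up-sampling factor 1–2
and Monte Carlo budgets of 2 × 10⁴–10⁶ photons; the acceptance evaluation
uses the full default pipeline (1 mm voxels, factor 4) for the noiseless
±60 mm tracking scans and 10⁶ Monte Carlo samples per panel for the
counting-statistics checks.  These sizes keep a full run of the suite to a
few minutes on one CPU while exercising every code path at the default
geometry.

## Known limitations

* No energy spectrum, phantom/collimator scatter, detector energy
  resolution or electronics dead-time: absolute count rates are
  order-of-magnitude only, and the simulated point response is narrower
  (hence more lattice-quantized) than a full-physics system's.
* The septal-penetration option uses a central-ray path-length estimate,
  not an aperture-integrated one.
* Localization accuracy is limited by the quantization plateaus described
  above; positions at unfavourable lattice phases carry ~2 mm systematics
  that no post-processing can remove under this transport model.
* Dwell positions are localized independently; no temporal smoothing across
  a source trajectory.
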