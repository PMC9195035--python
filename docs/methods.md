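# Methods

This note documents the models, estimators and numerical choices behind
`epidpsm`, in the package's own terms.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The decomposition and its conventions

A raw portal image is modelled as `raw = k · PSM · BR + noise`: the
pixel-sensitivity-map `PSM` is the multiplicative non-uniformity the
imager introduces and the Beam-Response `BR` is the one the beam
introduces, sampled at each pixel's beam-frame off-axis position.  Both
factors are only defined up to a scale, so fixed normalizations are
applied throughout:

* **PSM** — divided by the mean of the central 10 × 10 pixel block.  On
  the even-sized grids used here the beam axis falls *between* pixels;
  the block is the one symmetric about the array centre.
* **Beam-Response** — divided by its central-axis value, defined as the
  mean of the central 2 × 2 pixels (again an even-grid convention; the
  choice of a 2 × 2 mean rather than a single pixel is a documented
  convention, not forced by anything).

Indices are 0-based, row 0 on the negative-y (longitudinal) panel edge;
all lengths are cm in the isocenter plane.  Division by a Beam-Response
uses an explicit masked policy: pixels where `BR ≤ 1e-9 ×` its central
value get PSM value 0 and `valid_mask = False`, so dead pixels and
out-of-field regions are flagged instead of becoming infinities.

## The simulator

The simulator provides ground truth; every method is validated against
panels and beams it generates.

**Panel.**  The full detector is 1190 × 1190 pixels over a
40 × 40 cm² active area at isocenter (0.336 mm pitch).  The working
"desk" geometry is 238 × 238 pixels over the same 40 cm (1.68 mm pitch):
large enough for every method's geometry (offset grids, 37 cm fields,
multi-pixel shifts) and small enough for second-scale runs.  Parameters
tied to the full grid in pixel units are converted by physical size, not
pixel count (see the per-method notes).

**Ground-truth PSM** = smooth gain field × (1 + static pixel spread),
with dead columns zeroed and blob defects applied, then normalized:

* smooth gain: Gaussian-filtered white noise, amplitude 2% (1 SD),
  correlation length 10 cm — slow panel-scale gain variation;
* pixel spread: i.i.d. Gaussian, SD 2% — the per-pixel sensitivity
  differences that are the whole point of a PSM;
* blob defects: compactly supported smooth bumps `(1 − (r/R)²)²`
  (a defect has finite extent; an infinite-tail profile would leak into
  every anchor region at the 1e-6 level and blur exactness checks);
* one dead column near x = −4.2 cm, emulating a real panel's dead-pixel
  column.

The static panel structure is frozen per seed — it is a property of the
panel — while acquisition noise is redrawn per frame.

**Beam.**  Relative fluence
`f(x, y) = p(r) · (1 + horn(r)) · shadow(r) · edge(x) · edge(y) ·
(1 + a_x x/10)(1 + a_y y/10)` with

| term | form | default | why |
| --- | --- | --- | --- |
| dome `p(r)` | polynomial in r | `1 + 2e-4 r²` (+4.5% at 15 cm) | flattened 6 MV-like response rises off-axis |
| horns | Gaussian ring | amplitude 5%, radius 16 cm, width 3 cm | an EPID over-responds to the softened off-axis spectrum, exaggerating the horns near the field edge |
| field edge | sigmoid per axis | σ = 0.4 cm at the collimated edge | finite penumbra |
| corner shadow | radial sigmoid dip | onset 26 cm, depth 20%, falloff 1.5 cm | primary-collimator shadow clipping the panel corners |
| asymmetry | linear tilt per 10 cm | 0.3%/10 cm (study default; 0 in the noise-isolation suite, 0.5%/10 cm in the leakage study) | clinically acceptable beams are slightly asymmetric |

The value at the origin is normalized to exactly 1 for symmetric models.

**Acquisition.**  Signal `mu · o · PSM · f(x, y) · (SID_ref/SID)²` with
`o` a per-irradiation output factor (SD 0.05%), additive readout noise
(0.1% of the frame's nominal central signal, per pixel per frame), a
constant dark offset, and a lag term carrying 2% of each frame into the
next.  Beam-frame coordinates include the panel shift and the SID
magnification; changing SID scales signal by the inverse square and the
field footprint linearly.  ABDF sequences alternate beam and dark
frames; the chain is primed with a signal-level residual frame so the
conventional discard of early pairs has something to protect against.
Each acquisition derives its random stream from a counter-based subseed
of the campaign seed, so appending acquisitions never perturbs earlier
ones.

**What the simulator does not emulate:** radiation transport, spectral
or energy dependence, EPID-arm backscatter (the modelled panel class has
a backscatter plate), glare/optical spread, pixel-level nonlinearity or
saturation, and arm-position irreproducibility.  Passing tests therefore
demonstrate the *estimators'* correctness and their characteristic
biases under the stated statistical model — not clinical accuracy on any
particular linac.

## Study scenarios

Two canonical panels:

* **exactness panel** (`defects_exact`): uniform background + dead
  column + blobs, no smooth gain, no pixel spread, no acquisition noise.
  The shift-ratio methods anchor their solution on a central seed
  region; with a uniform seed their recovery is exact to machine
  precision, making this the right scenario for verifying the chain
  algebra, masks and geometry with zero tolerance.
* **realistic panel** (`defects_realistic`): full defect model, noise as
  above.  Used for the quantitative recovery and repeatability studies.

Beam asymmetry is a systematic, not a noise term, so the noisy recovery
suite runs a symmetric beam and a separate campaign injects a 0.5%/10 cm
tilt to demonstrate the radial method's leakage signature.

## Constant-beam offset method (`epidpsm.cmn`)

A 5 × 5 cm field is delivered at a 7 (lateral, −15…+15 cm) ×
6 (longitudinal, −15…+10 cm) grid of panel offsets (5 cm steps, 42
offsets) plus a centred reference, 100 MU each.  In every image a square
ROI (half-width 0.5 cm, ≈15 px at full resolution) is read at the
beam-centre projection; `s_rel = offset ROI mean / centred ROI mean`
cancels the constant beam and equals the relative PSM at the sampled
panel point.  A wide-field raw image read with the *identical pixel
ROIs* then gives Beam-Response samples `wide ROI / s_rel` in which the
PSM content of the ROI cancels exactly.  Beam-centre projections fall on
fractional pixels; ROIs are centred on the nearest whole pixel and the
*actual* ROI-centre coordinates are used as sample locations, so
rounding never breaks the cancellation (the residual effect — the 5 cm
field's penumbra tails sampled at sub-pixel different positions — is a
few 1e-4 on the desk grid and shrinks with resolution).

The samples are fitted by a tensor-product cubic spline with not-a-knot
end conditions; outside the sampled rectangle the surface continues
linearly along each axis with the boundary gradient of the spline
(x-extension first, then y; the construction is order independent).
Bicubic functions are reproduced exactly inside the hull.  The PSM is
the wide-field image divided by the fitted Beam-Response.  Known
limitations reproduced by design: the corner shadow and the beam
structure beyond the sampled rectangle (horns, penumbra) are not in the
spline's reach, so errors concentrate in the 15–20 cm band — the
method's documented edge weakness.

## Small-shift overlapping-field method (`epidpsm.washu`)

ABDF sequences (100 pairs of 2 MU frames, first 40 pairs discarded,
net = mean beam − mean dark) are acquired for a centred 37 × 37 cm field
and whole-pixel panel shifts.  When the panel is shifted by (dr, dc)
pixels, pixel (r, c) of the shifted image and pixel (r+dr, c+dc) of the
reference saw the same beam location, so
`s(r,c)/s(r+dr,c+dc) = shifted(r,c)/reference(r+dr,c+dc)` exactly — the
beam cancels identically because the shifted grid realigns with the
reference grid.

**Solver.**  In the log domain every ratio is a linear constraint
`u_i − u_j = d_ij`.  Rather than walking individual chains and averaging
them pairwise, the full constraint set is solved by sparse linear least
squares — the symmetric merge of *every* chain (the natural completion
of geometric-mean chain merging; for consistent constraints it is
exact).  Each connected component of the constraint graph is determined
up to one constant, anchored by setting the geometric mean over its
intersection with the central 20 × 20 seed region to 1; components that
never touch the seed are masked as unreachable, and pixels whose net
signal falls below 5% of the central value (dead pixels, out-of-field)
contribute no constraints.

**Shift plan.**  A shift of k pixels only links pixels k apart: the
panel decomposes into k × k interleaved lattices with no constraints
between them, and a dead column severs every chain of the lattice it
sits on.  The default plan therefore snaps the nominal 4 mm shift to the
nearest whole pixel k and delivers *two coprime shift sizes per axis*
(k and k+1), which makes the graph a single component and lets chains
step over dead columns; an explicitly requested shift size gives the
minimal reference + lateral + longitudinal pattern and raises on
non-integer pixel shifts (the solver never resamples).  Pixels outside
the mutual 37 cm footprint stay masked — the method's documented edge
limitation — and the dead column itself is masked rather than smoothed
into the Beam-Response.

## Three-stage method (`epidpsm.varian`)

*Stage 1* applies the same ratio solver with a long chain step — 50 px
at full resolution, i.e. 1.68 cm, hence 10 px on the desk grid (the
physical shift, not the pixel count, is the invariant) — on three
ABDF-averaged 40 × 40 cm acquisitions.  The anchor seed stays at its
default 60 px: with step k the seed must exceed k so that every residue
class is anchored, and each class should contain enough seed pixels to
average the per-pixel gain spread out of its anchor.  With a uniform
seed region the stage is exact; with a realistic panel each class keeps
a small anchor offset that the later stages cannot remove (it is
high-frequency) — reproducing the method's characteristically noisy
Beam-Response.

*Stage 2* corrects smooth error using two centred images at different
SIDs, interpreted as 115 cm and 175 cm (panel positions −15 and −75 cm
relative to the 100 cm isocenter).  Each image is divided by the stage-1
PSM, scaled by (SID/SID_ref)², and expressed in the common beam frame;
their log-difference contains only the smooth PSM error seen at two
magnifications.  It is fitted by a bivariate polynomial (total degree 4,
coordinates scaled to the half panel) via linear least squares on the
difference of the basis evaluated at the two magnifications; the
constant term cancels between the two images and a free intercept
absorbs the output ratio and is discarded on application.  The common
grid uses the smaller-SID image's own pixel centres so only the second
image needs (bilinear) resampling; invalid pixels are bridged by
along-row interpolation before resampling and excluded from the fit
through the sampled validity mask.  Equal SIDs or < 25% footprint
overlap are rejected.

*Stage 3* tunes quadrants with four images of one 24 × 24 cm field
centred on (±6, ±6) cm via panel shifts (the beam never moves).  Each
PSM-corrected image's log-ratio to the four-image mean is fitted by a
degree-3 polynomial over the beam-frame footprint and applied back on
the panel with cosine-feathered blending (2 cm feather) between
quadrant footprints; about 70% of the panel is covered, the rest is left
untouched.  Intercepts are *kept*: the method assumes constant beam
output across the four deliveries, so output fluctuation enters the
result as a small systematic — the assumption is stated, not hidden.
Both stage 2 and stage 3 never increase their own objective (internal
RMS log-difference), which the tests assert.

## Radial ring-average method (`epidpsm.radial`)

The idealized, radially symmetric response image (in the emulated study,
a unit-sensitivity render of the symmetric beam component with additive
per-pixel noise standing in for transport-calculation statistics) is
averaged in concentric 5 mm rings around the central pixel.  Inner rings
hold few pixels and stay noisy; outer rings are well averaged; rings
reaching past the panel half-width are flagged partial.

The ring profile is smoothed with a penalized cubic B-spline (knot per
ring, second-difference penalty) weighted by ring counts; the penalty
strength is selected by generalized cross-validation, which requires no
absolute noise scale, with a floor of 12 effective degrees of freedom so
a flat GCV curve cannot collapse the dome + horn + edge-drop structure.
With zero within-ring spread the fit degenerates to interpolation.  The
per-pixel noise scale, when needed, is estimated from the within-ring
pixel spread (the radial trend across a 5 mm ring is far below the
statistical noise this method is designed around).

The desk-scale scenario sets the idealized image's per-pixel noise to
3% × (n/1190): rings on a coarser grid hold quadratically fewer pixels,
so scaling the pixel noise linearly with the grid keeps the *ring-level*
noise — the quantity the smoothing stage consumes — resolution
independent.

The PSM is a measured raw image divided by the radial function evaluated
at every pixel radius.  Two idealization biases follow from the
construction and are demonstrated, not suppressed, by the tests: any
beam asymmetry in the raw image leaks into the PSM as an x-antisymmetric
error (quantified as the correlation of the deviation map with its
mirrored negation over the in-field disc r < 16 cm, i.e. inside the
field edge and its penumbra), and the square field edge cannot be
represented by rings, so the outermost annulus and corners are biased.

## Comparison metrics (`epidpsm.metrics`)

Percentage deviation maps `100 (a − b)/b` with joint validity masks;
histograms with fixed 0.05% bins whose counts conserve the pixel count;
mean, median, SD (sample, n−1 divisor — also for n = 3 repeatability)
and the 95th percentile of |deviation|.  Medians are emphasised because
edge and corner tails dominate the means.  Repeatability is the
per-pixel `100 · SD/mean` over repeated determinations; its headline
number is the 95th percentile over valid pixels.  Recovery reports
additionally break deviations into concentric bands (0–10, 10–15,
15–20 cm) to separate centre from edge behaviour.  For repeated
determinations with the radial method, the Beam-Response is derived once
and reused — only the raw image is re-acquired — so its repeatability
measures the raw image itself, which is the reference role the idealized
method plays.

The noise-propagation prediction for repeatability treats the sample SD
of n Gaussian repeats as `σ · sqrt(χ²_{n−1}/(n−1))` per pixel and
computes the 95th percentile of the *mixture* of those laws over pixels
(closed-form CDF average, solved by bisection); comparing the measured
p95 against this prediction validates the entire repeatability pipeline,
not just the SD arithmetic.

## Numerical choices and degenerate inputs

* Ratio solver: normal equations with one gauge-pin per component,
  solved by sparse LU; the pin selects the representative of the
  least-squares family without biasing it (verified to 1e-10 on
  consistent systems).
* Resampling between frames: bilinear; higher-order spline prefilters
  ring across the whole array from masked-region edges and are avoided.
* Polynomial fits use total-degree monomial bases on coordinates scaled
  to order 1, solved by `lstsq`.
* Degenerate inputs raise typed errors: non-positive normalization
  regions, dark frames with MU, non-integer pixel shifts (with the
  nearest valid shift suggested), seed regions smaller than the chain
  step, equal stage-2 SIDs, missing quadrant coverage, fewer than 8
  rings, fewer than 4 spline samples per axis, fewer than 2 repeats.

## Known limitations

* The noise model is additive Gaussian readout plus global output
  fluctuation; no Poisson statistics, gain drift or spectral effects.
* The shift-ratio solver assumes exactly whole-pixel shifts; real
  arm-position error between nominally identical shifts is not
  modelled (it would appear as extra repeatability spread).
* Stage-2 polynomial corrections are extrapolated from the mutual SID
  footprint (±11 cm in the beam frame) to the panel corners; a degree-4
  surface can amplify there.  In the emulated study the stage-1 error it
  corrects is nearly tile-periodic with near-zero smooth component, so
  the fitted coefficients stay small, but this is a structural caveat of
  the method.
* Desk-scale results quantify estimator behaviour under the stated
  model; the full 1190 × 1190 geometry is supported throughout but not
  exercised by the default test suite.
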