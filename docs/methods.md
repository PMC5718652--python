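# Methods

## Problem and model

A portal radiograph acquired with the treatment beam is registered to
the planning DRR to measure the patient setup error.  Two geometric
effects separate the raw portal image from the DRR's beam's-eye-view
(BEV) frame: an in-plane similarity transform (zoom `b`, rotation `θ`,
translation), and — when the imaging plate is not orthogonal to the
beam axis — an out-of-plane tilt.  The tilt is modeled as a rotation of
the plate by `ϕ` about an in-plane axis at azimuth `φ`, which to first
order stretches the projection by `1/cos ϕ` perpendicular to that axis:

    p' = b · Rot(θ) · Rot(φ) · St(ϕ) · Rot(−φ) · p + t,
    St(ϕ) = diag(1, 1/cos ϕ).

This affine model is anchored by three control points per image
(isocenter plus one graticule point per axis, `axis_length_mm` = 100 mm
by default).  The area spanned by the control points is the *working
area*, formalized here as the closed box `|x|,|y| ≤ axis_length_mm`;
since the true plate distortion is perspective, not affine, residuals
grow outside that box (demonstrated by the tilted-plate experiment in
`synthetic.tilt_experiment_residuals`).

### Factorization

Parameters are recovered from the solved 2×2 matrix `M` by polar /
singular-value decomposition rather than by closed-form angle formulas:
`M = R·S` with `S` symmetric positive definite; the smaller singular
value is the zoom `b`, `cos ϕ = σ_min/σ_max`, `φ` is the azimuth of the
unstretched singular direction (the tilt axis, a direction mod 180°,
reported in [−90°, 90°)), and `θ` is the rotation of the orthogonal
factor.  Equal singular values (no tilt) are reported deterministically
as `ϕ = φ = 0`.  This factorization satisfies the composition contract
exactly (recomposition error < 1e−9 over random draws, enforced by
tests) and has no trigonometric edge cases.

### Conventions

* Beam frame: mm, isocenter origin, +x right, +y up.
* Pixels: `(col, row)`, 0-based, continuous coordinates at pixel
  centers; the right-handed "plate math" frame `(col, −row)` is used for
  all linear algebra so physical maps have positive determinant.
* Resampling: bilinear (`scipy.ndimage.map_coordinates`); pixels pulled
  from outside the source footprint, or from masked input, are flagged
  background rather than written as zero intensity.
* Couch correction (collimator 0, gantry about the longitudinal axis):
  `long = −dy`, `lat = −dx·cos g`, `vert = +dx·sin g` — the movements
  that cancel the measured BEV offset.  The convention is a documented
  package choice.

## Mutual-information auto-registration

The similarity measure is Shannon mutual information in bits over the
binned joint histogram of the overlapping valid pixels,
`I = H(A) + H(B) − H(A,B)`, with marginal entropies taken from the
joint histogram's own marginals so all three terms see identical
pixels.  Defaults and their rationale:

* **64 equal-width bins** per image over the image's full valid
  intensity range, frozen once per registration so the objective is
  consistent across candidate shifts.  10-bit raw histograms (1024²
  joint cells) would be far too sparse.  Note the plug-in MI estimator
  has an upward bias of ≈ `(k−1)²/(2N ln 2)` bits for `k` bins and `N`
  pixels; statistical checks of independence (MI ≈ 0) therefore use
  coarser binning (16 bins at 10⁴ pixels, bias ≈ 0.016 bits).
* **Working-area restriction** (default on): MI is computed only inside
  the ±100 mm control-point box, where the geometric correction is
  trustworthy.
* **Burned-in graphics exclusion** (default on): the field border and
  graticule ticks are burned into both images at the *nominal* field
  position, so they are offset-invariant by construction: they carry no
  information about the setup error, and including them rewards zero
  shift with a spurious MI peak that can trap the optimizer.  Saturated
  pixels (top histogram bin of each image) are therefore excluded from
  the optimizer's joint histogram.  The pure `entropy` /
  `mutual_information` functions apply no such masking.

The optimizer is a deterministic hill climb: at the current step size
the portal is trial-shifted ±step in x and y (candidate order +x, −x,
+y, −y; strict improvement only, so ties never cycle) until the current
position scores highest; the step then halves, from 4 mm down to 1 mm
by default (sub-millimeter final steps are allowed; the schedule must
halve exactly).  When rotation search is enabled the shift climb
alternates with a 1D rotation climb (default 2° → 0.25° steps, clamped
to ±5°, pivot at the isocenter) until neither improves.  Everything is
pure arithmetic on fixed inputs: two runs on identical inputs return
bit-identical estimates.  `exhaustive_grid_search` provides the
brute-force MI argmax used as an oracle in tests; hill climbing matches
it whenever the landscape is unimodal along the multiresolution path,
and like any local method can differ on multimodal landscapes.

## Synthetic phantom studies

The generator emulates the phantom-study construction: one anatomy
scene per phantom; the DRR is its clean orthographic projection with
the 10×10 cm field border and 1-cm graticule burned in; each portal
renders the *anatomy* displaced by the known offset while the graticule
stays at the nominal position — exactly the construction that makes the
planted offset recoverable.  Study design defaults: five offsets drawn
uniformly in ±10 mm per axis, each presented twice (ten cases), order
shuffled; 512×512 images at 0.5 mm/px (a desk-scale stand-in for
1760×1760 CR plates); 10-bit intensity scale.

Scenes are sums of analytic primitives.  The chest scene combines
periodic bony structure (28 mm posterior-rib interspaces rendered as
tilted ellipse shells, 26 mm vertebral pitch) with the large aperiodic
anatomy that dominates real chest films — diaphragm dome, heart border,
shoulder mass, an asymmetric lung-field gradient.  The balance matters:
a scene of purely periodic ribs would make offsets beyond half the rib
period alias to the neighboring period, which is a property of the
scene, not of the method.  The pelvis scene is broad, low-gradient
structure (iliac wings, sacrum, soft tissue), which is what makes its
registration collapse first as contrast drops.

Megavoltage portal degradation is modeled as linear compression of
intensities toward the scene mean by a `contrast` factor (chest default
0.5, pelvis 0.35) plus seeded additive Gaussian noise (σ = 8 on the
10-bit scale, ≈1% of range — mild CR-grade noise).  This monotone
contrast knob reproduces the qualitative failure mode (mean error grows
as contrast → 0) without pretending to model scatter, beam hardening,
or detector physics.  What passing tests on these phantoms do *not*
show: performance on real anatomy with soft-tissue deformation,
scatter-limited contrast, or operator-dependent control-point placement.

The tilted-plate simulator uses the full perspective projection (point
source at `source_mm` = 1000 mm above the isocenter, plate `plate_mm` =
400 mm beyond it — typical linac geometry, configurable), returning
both the plate image and the exact projected control-point locations.
The absolute inside/outside-working-area residuals depend on that
unstated-by-design geometry; only their ordering is a stable property.

## Numerical choices and degenerate inputs

* Histogram ranges collapse for constant images: a one-unit-wide range
  centered on the value is substituted (entropy 0).
* Control points that are coincident or collinear, orientation-
  reversing or singular linear maps, empty mask overlaps, zero-variance
  paired differences in the t-test, and rays parallel to the tilted
  plate all raise specific errors rather than returning garbage.
* Distance bins are right-closed (`d ≤ 2` Good, `≤ 5` Fair, `≤ 10`
  Poor, `> 10` Terrible); boundary values go to the smaller bin.
* Summary statistics use the sample (n−1) standard deviation.
* Auto window/level spans the 1st–99th percentile of valid intensities
  (robust to the burned-in graticule extremes), level at the midpoint.

## Problem sizes

Default study images are 512×512 at 0.5 mm/px.  Oracle-backed tests
(exhaustive grid search over ±10 mm) run at 128×128 / 1 mm/px and the
contrast-degradation sweep at 256×256 / 1 mm/px — scales chosen so the
whole anatomy stays in the field of view while brute-force MI
evaluation stays cheap.

## Known limitations

* The affine tilt model is first-order; large tilts (≥ 45° rejected)
  and points far outside the working area are not corrected accurately
  — by design, matching the control-point workflow.
* Hill climbing inherits local-maximum risk on strongly periodic or
  near-contrast-free images (the pelvis failure mode); the
  multiresolution schedule mitigates but cannot eliminate it.
* No automatic tick-mark detection: control points are supplied by the
  operator (or, for synthetic tilts, by the simulator's ground truth).
* No 8-DOF projective correction, no CT-based DRR ray casting, no GUI.
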