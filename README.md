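# portalreg

Portal-image / DRR registration for radiotherapy patient-setup
verification.

Before each treatment fraction, a megavoltage **portal radiograph** is
compared with the planning **DRR** (digitally reconstructed radiograph)
to measure the patient's setup error — the displacement of the anatomy
relative to the planned treatment field, expressed as a field shift in
the beam's-eye view (BEV). `portalreg` implements that workflow for
medical physicists and RT software developers:

* **Geometry** — the portal plate is mapped into the DRR's beam frame
  from three clicked control points (isocenter + one point on each
  graticule axis).  The 2×2 linear part factorizes as

  ```
  p' = b · Rot(θ) · Rot(φ) · St(ϕ) · Rot(−φ) · p + t,   St(ϕ) = diag(1, 1/cos ϕ)
  ```

  where `b` is the zoom, `θ` the in-plane rotation, and `St(ϕ)` the
  stretch produced by an out-of-plane plate tilt `ϕ` about the in-plane
  axis at azimuth `φ`.  The factorization is recovered by singular-value
  (polar) decomposition, and images are corrected by inverse-map
  bilinear resampling.
* **Fusion** — corrected portal and DRR are overlaid on complementary
  color channels (red-cyan by default): aligned content renders neutral
  gray, misalignments appear as color shadows.
* **Auto-registration** — the setup error is estimated by maximizing the
  mutual information `I(A,B) = H(A) + H(B) − H(A,B)` of the binned joint
  intensity histogram over candidate shifts, with a deterministic
  multiresolution hill climb (4 mm initial step halved to 1 mm, optional
  alternating rotation search).
* **Synthetic phantoms** — seeded chest/pelvis scenes rendered as DRR +
  degraded portal pairs with known offsets, burned-in 10×10 cm field and
  1-cm graticule, megavoltage contrast compression, noise, and optional
  perspective plate tilt.  Every fixture is reproducible from its seeds.
* **Evaluation** — distance-from-truth and repeat-consistency statistics,
  Good/Fair/Poor/Terrible bins (≤2 / ≤5 / ≤10 / >10 mm), paired t-test,
  and couch-correction conversion.

## Worked example

```python
from portalreg import auto_register, make_scene, render_drr, render_portal
from portalreg.synthetic import SyntheticCase

scene = make_scene("chest", seed=11)
drr = render_drr(scene, shape=(256, 256), pixel_spacing_mm=1.0)
case = SyntheticCase("demo", (7.0, -3.0), contrast=0.5, noise_sigma=8.0, seed=11)
portal = render_portal(scene, case, shape=(256, 256), pixel_spacing_mm=1.0)
est = auto_register(portal, drr)
print(est.dx_mm, est.dy_mm)
```

prints `7.0 -3.0`: the optimizer recovers the planted 7 mm lateral /
−3 mm vertical setup error exactly at the 1 mm final step.  Running the
full ten-case study (`examples/04_phantom_study.py`) prints

```
mean distance from truth: 0.36 ± 0.16 mm over 10 cases
mean consistency between repeats: 0.00 mm
distance bins: Good=10  Fair=0  Poor=0  Terrible=0
```

— sub-millimeter mean error (the residual is mostly the 1 mm final step
quantizing continuous offsets) and perfect repeat consistency, because
the optimizer is fully deterministic.

More narrative scripts live in `examples/` (tilt correction, fusion,
auto-registration, the phantom study).  A thin CLI exposes the same
workflow: `portalreg simulate | register | auto | evaluate |
tilt-experiment` (see `portalreg --help`).

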