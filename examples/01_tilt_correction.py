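"""Out-of-plane plate tilt: distortion, control-point correction, residuals.

A portal imaging plate tilted 10 degrees away from the beam axis warps
the projected image.  Three control points (isocenter + one point on
each graticule axis) determine an affine correction.  This script
projects points through the true perspective geometry, corrects them,
and shows that the residual error is small near the control points
(inside the "working area") and grows outside it.
"""

import numpy as np

from portalreg import decompose_transform, recompose_transform
from portalreg.synthetic import project_beam_points, tilt_experiment_residuals

# the transform factorization: zoom x rotation x tilt-stretch
M = recompose_transform(zoom_b=1.4, theta_deg=3.0, phi_deg=0.0, tilt_deg=10.0)
b, theta, phi, tilt = decompose_transform(M)
print(f"factorization of the plate map: zoom={b:.3f}  rotation={theta:.2f} deg  "
      f"tilt={tilt:.2f} deg about azimuth {phi:.1f} deg")

# perspective projection of graticule points onto a 10-degree tilted plate
pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
proj = project_beam_points(pts, tilt_deg=10.0, source_mm=1000.0, plate_mm=400.0)
print("\nbeam-frame points (mm) -> tilted-plate positions (mm):")
for p, q in zip(pts, proj):
    print(f"  ({p[0]:6.1f}, {p[1]:6.1f}) -> ({q[0]:8.3f}, {q[1]:8.3f})")

inside, outside = tilt_experiment_residuals(tilt_deg=10.0)
print(f"\nafter affine control-point correction at 10 deg tilt:")
print(f"  residual at (50, 50) mm, inside the working area:   {inside:.3f} mm")
print(f"  residual at (150, 150) mm, outside the working area: {outside:.3f} mm")
print("the correction is trustworthy near the control points; outside the")
print("working area the uncorrected perspective component dominates.")
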