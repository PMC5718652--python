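"""Control-point planar transform between portal-plate and beam coordinates.

A portal radiograph acquired on a freely held imaging plate differs from
the planning DRR by an in-plane rotation, a zoom, and — when the plate is
not orthogonal to the beam axis — an out-of-plane tilt.  Writing the tilt
as a rotation about an axis x' at azimuth φ in the image plane, the plate
coordinates of a beam-frame point are

    p' = b · Rot(θ) · Rot(φ) · St(ϕ) · Rot(−φ) · p + t

with Rot the 2D rotation matrix and St(ϕ) = diag(1, 1/cos ϕ) the stretch
the tilt produces perpendicular to its axis.  Three control points per
image (isocenter plus one point on each graticule axis, usually 100 mm
out) determine the 2×2 linear part and the translation; the image is
corrected by resampling through the inverse map.

The affine model is exact only near the control points; the region they
span is the "working area", and residuals of the underlying perspective
distortion grow outside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BeamFrame, ImageGrid, resample_by_pixel_map

__all__ = [
    "ControlPointSet",
    "PlanarTransform",
    "PointPairList",
    "BeamFrame",
    "DegenerateControlPointsError",
    "OrientationError",
    "solve_linear_map",
    "decompose_transform",
    "recompose_transform",
    "forward_distort",
    "invert_distort",
    "correct_image",
    "working_area",
    "transform_from_control_points",
]


class DegenerateControlPointsError(ValueError):
    """Control points are collinear/coincident and cannot anchor a frame."""


class OrientationError(ValueError):
    """The linear map is orientation-reversing or singular (det ≤ 0)."""


def _px_to_math(p: np.ndarray) -> np.ndarray:
    """(col, row) -> right-handed (u, v) = (col, -row)."""
    p = np.asarray(p, dtype=float)
    return np.stack([p[..., 0], -p[..., 1]], axis=-1)


def _math_to_px(p: np.ndarray) -> np.ndarray:
    return _px_to_math(p)  # involution


@dataclass(frozen=True)
class ControlPointSet:
    """The three clicked points anchoring a beam frame on one image.

    ``isocenter``, ``axis_point_x``, ``axis_point_y`` are ``(col, row)``
    pixel coordinates; the axis points sit on the graticule axes at
    ``axis_length_mm`` from the isocenter (100 mm by default — the
    operator clicks the 10 cm tick).
    """

    isocenter: tuple[float, float]
    axis_point_x: tuple[float, float]
    axis_point_y: tuple[float, float]
    axis_length_mm: float = 100.0

    def __post_init__(self) -> None:
        if not self.axis_length_mm > 0:
            raise ValueError(f"axis_length_mm must be > 0, got {self.axis_length_mm}")
        iso = np.asarray(self.isocenter, dtype=float)
        ax = np.asarray(self.axis_point_x, dtype=float)
        ay = np.asarray(self.axis_point_y, dtype=float)
        vx, vy = ax - iso, ay - iso
        cross = vx[0] * vy[1] - vx[1] * vy[0]
        scale = max(np.linalg.norm(vx), np.linalg.norm(vy), 1.0)
        if np.linalg.norm(vx) == 0 or np.linalg.norm(vy) == 0 or abs(cross) < 1e-9 * scale**2:
            raise DegenerateControlPointsError(
                "control points are collinear or coincident: "
                f"isocenter={self.isocenter}, axis_point_x={self.axis_point_x}, "
                f"axis_point_y={self.axis_point_y}"
            )

    def axis_vectors_px(self) -> tuple[np.ndarray, np.ndarray]:
        iso = np.asarray(self.isocenter, dtype=float)
        return (
            np.asarray(self.axis_point_x, dtype=float) - iso,
            np.asarray(self.axis_point_y, dtype=float) - iso,
        )

    def beam_frame(self) -> BeamFrame:
        """Pixel spacing calibrated from the clicked axis lengths."""
        vx, vy = self.axis_vectors_px()
        dist = 0.5 * (np.linalg.norm(vx) + np.linalg.norm(vy))
        return BeamFrame(
            isocenter_px=(float(self.isocenter[0]), float(self.isocenter[1])),
            pixel_spacing_mm=self.axis_length_mm / dist,
        )


@dataclass(frozen=True)
class PointPairList:
    """Ordered (beam-frame mm, plate-frame) vector pairs about the isocenter.

    ``beam`` and ``plate`` are (N, 2) arrays, N ≥ 2, with the beam-frame
    vectors linearly independent.  Plate vectors are in right-handed
    "plate math" units.
    """

    beam: np.ndarray
    plate: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "beam", np.atleast_2d(np.asarray(self.beam, dtype=float)))
        object.__setattr__(self, "plate", np.atleast_2d(np.asarray(self.plate, dtype=float)))
        if self.beam.shape != self.plate.shape or self.beam.shape[0] < 2 or self.beam.shape[1] != 2:
            raise ValueError("need matching (N>=2, 2) beam and plate point arrays")
        if np.linalg.matrix_rank(self.beam) < 2:
            raise DegenerateControlPointsError(
                f"beam-frame vectors are linearly dependent: {self.beam.tolist()}"
            )


def solve_linear_map(pairs: PointPairList) -> np.ndarray:
    """Solve the 2×2 matrix taking beam-frame vectors to plate vectors.

    With exactly two pairs the map interpolates them exactly; with more it
    is the least-squares fit.  Raises ``DegenerateControlPointsError``
    when the plate vectors are collinear (the map would be singular).
    """
    B, P = pairs.beam, pairs.plate
    if np.linalg.matrix_rank(P) < 2:
        raise DegenerateControlPointsError(
            f"plate-frame vectors are linearly dependent: {P.tolist()}"
        )
    if B.shape[0] == 2:
        # M @ B.T = P.T  exactly
        M = P.T @ np.linalg.inv(B.T)
    else:
        M, *_ = np.linalg.lstsq(B, P, rcond=None)
        M = M.T
    return M


def _rot(deg: float) -> np.ndarray:
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s], [s, c]])


def recompose_transform(
    zoom_b: float, theta_deg: float, phi_deg: float, tilt_deg: float
) -> np.ndarray:
    """b · Rot(θ) · Rot(φ) · St(ϕ) · Rot(−φ) with St(ϕ) = diag(1, 1/cos ϕ)."""
    st = np.diag([1.0, 1.0 / np.cos(np.deg2rad(tilt_deg))])
    return zoom_b * _rot(theta_deg) @ _rot(phi_deg) @ st @ _rot(-phi_deg)


def decompose_transform(M: np.ndarray, *, tol: float = 1e-9) -> tuple[float, float, float, float]:
    """Factor M = b·Rot(θ)·Rot(φ)·St(ϕ)·Rot(−φ) -> (b, θ, φ, ϕ) in degrees.

    The factorization is the polar decomposition M = R·S: the symmetric
    part S has eigenvalues b (unstretched, along the tilt axis at azimuth
    φ) and b/cos ϕ, so b is the smaller singular value of M and
    cos ϕ = σ_min/σ_max.  Equal singular values are reported as ϕ = 0,
    φ = 0 (no tilt).  φ is reported in [−90°, 90°) — a tilt axis is a
    direction, defined modulo 180°.
    """
    M = np.asarray(M, dtype=float)
    det = np.linalg.det(M)
    if det <= 0:
        raise OrientationError(f"linear map must be orientation-preserving, det={det:g}")
    U, s, Vt = np.linalg.svd(M)
    if np.linalg.det(U) < 0:  # det(M)>0 forces det(U)=det(V); flip both
        U = U @ np.diag([1.0, -1.0])
        Vt = np.diag([1.0, -1.0]) @ Vt
    smax, smin = float(s[0]), float(s[1])
    R = U @ Vt
    theta = float(np.rad2deg(np.arctan2(R[1, 0], R[0, 0])))
    if smax - smin <= tol * smax:
        return smin, theta, 0.0, 0.0
    tilt = float(np.rad2deg(np.arccos(np.clip(smin / smax, 0.0, 1.0))))
    v_min = Vt[1]  # right singular vector of σ_min: the unstretched direction
    phi = float(np.rad2deg(np.arctan2(v_min[1], v_min[0])))
    phi = (phi + 90.0) % 180.0 - 90.0
    return smin, theta, phi, tilt


@dataclass(frozen=True)
class PlanarTransform:
    """Portal→DRR planar map: 2×2 linear part + translation, with its
    (b, θ, φ, ϕ) factorization.

    ``linear`` maps beam-frame mm vectors to plate-math vectors about the
    isocenter; ``translation`` is the plate-math position of the beam
    isocenter.
    """

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "linear", np.asarray(self.linear, dtype=float).reshape(2, 2))
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float).reshape(2)
        )
        # validates det > 0 and caches the factorization
        b, th, ph, ti = decompose_transform(self.linear)
        object.__setattr__(self, "_factors", (b, th, ph, ti))

    @property
    def zoom_b(self) -> float:
        return self._factors[0]  # type: ignore[attr-defined]

    @property
    def theta_deg(self) -> float:
        return self._factors[1]  # type: ignore[attr-defined]

    @property
    def phi_deg(self) -> float:
        return self._factors[2]  # type: ignore[attr-defined]

    @property
    def tilt_deg(self) -> float:
        return self._factors[3]  # type: ignore[attr-defined]


def transform_from_control_points(
    cps_drr: ControlPointSet, cps_portal: ControlPointSet
) -> PlanarTransform:
    """Build the beam→portal-plate transform from matched control points.

    The DRR control points define the beam frame (the clicked axis points
    are at (L, 0) and (0, L) mm); the portal control points give the
    plate-frame images of those vectors and the isocenter translation.
    """
    L = cps_drr.axis_length_mm
    beam = np.array([[L, 0.0], [0.0, L]])
    vx, vy = cps_portal.axis_vectors_px()
    plate = _px_to_math(np.stack([vx, vy]))
    M = solve_linear_map(PointPairList(beam, plate))
    t = _px_to_math(np.asarray(cps_portal.isocenter, dtype=float))
    return PlanarTransform(linear=M, translation=t)


def forward_distort(point_mm: np.ndarray, transform: PlanarTransform) -> np.ndarray:
    """Map beam-frame mm point(s) to plate-math coordinates."""
    p = np.asarray(point_mm, dtype=float)
    return p @ transform.linear.T + transform.translation


def invert_distort(point_plate: np.ndarray, transform: PlanarTransform) -> np.ndarray:
    """Map plate-math point(s) back to beam-frame mm (the correction map)."""
    p = np.asarray(point_plate, dtype=float) - transform.translation
    return p @ np.linalg.inv(transform.linear).T


def correct_image(
    portal: ImageGrid,
    transform: PlanarTransform,
    target_frame: BeamFrame,
    out_shape: tuple[int, int] | None = None,
) -> ImageGrid:
    """Resample the portal image into the DRR beam frame.

    Each output pixel pulls from the plate location ``M·p + t`` of its
    beam coordinate (inverse mapping, bilinear); pixels pulled from
    outside the portal footprint are flagged background.
    """
    shape = out_shape or portal.shape
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    mm = target_frame.px_to_mm(np.stack([cols.ravel(), rows.ravel()], axis=-1))
    plate = forward_distort(mm, transform)
    src = _math_to_px(plate)
    s = target_frame.pixel_spacing_mm
    return resample_by_pixel_map(
        portal,
        src[:, 0].reshape(shape),
        src[:, 1].reshape(shape),
        frame=target_frame,
        pixel_spacing_mm=(s, s),
    )


def working_area(cps: ControlPointSet, point_mm: np.ndarray) -> bool:
    """True iff the beam-frame point lies in the closed axis-aligned box
    spanned by ±axis_length_mm on both axes.

    The affine tilt correction is anchored at the control points; this box
    formalizes the region where it can be trusted.
    """
    p = np.asarray(point_mm, dtype=float)
    L = cps.axis_length_mm
    return bool(np.all(np.abs(p) <= L))
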