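"""Synthetic phantom study fixtures: scenes, DRR/portal renders, tilt.

Emulates the phantom-study construction: a single anatomy image per
phantom, onto which the treatment field border and graticule tick marks
are burned at their *nominal* position while the anatomy itself is drawn
shifted by the (known) setup error.  The graticule therefore stays fixed
while the anatomy moves — exactly what makes the true offset recoverable
by registration.

Scenes are sums of analytic primitives (rotated ellipses and bars):

* ``chest`` — periodic high-contrast ribs and a vertebral column; strong
  gradients, the easy case for MI registration.
* ``pelvis`` — broad iliac wings and smooth low-gradient structure; the
  hard case whose registration degrades first as portal contrast drops.

Portal images model megavoltage acquisition as a linear compression of
intensities toward the scene mean (the ``contrast`` factor) plus seeded
Gaussian noise, and can optionally be projected onto a tilted imaging
plate with full perspective geometry.

Everything is deterministic under its seeds; no external data is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BeamFrame, ImageGrid, resample_by_pixel_map

__all__ = [
    "PhantomScene",
    "SyntheticCase",
    "CaseList",
    "make_scene",
    "render_drr",
    "render_portal",
    "make_case_list",
    "simulate_tilted_plate",
    "project_beam_points",
    "tilt_experiment_residuals",
]

#: 10-bit intensity scale of the rendered images
INTENSITY_MAX = 1023.0
_TICK_VALUE = INTENSITY_MAX
_BASE_LEVEL = 120.0

DEFAULT_SHAPE = (512, 512)
DEFAULT_SPACING_MM = 0.5
DEFAULT_NOISE_SIGMA = 8.0  # ~1% of the 10-bit range: mild CR noise
DEFAULT_CONTRAST = {"chest": 0.5, "pelvis": 0.35}


@dataclass(frozen=True)
class _Ellipse:
    cx: float
    cy: float
    a: float
    b: float
    angle_deg: float
    weight: float
    ring: float = 0.0  # >0: hollow shell of this half-thickness (mm), like cortical bone

    def render(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        r = np.deg2rad(self.angle_deg)
        xr = (x - self.cx) * np.cos(r) + (y - self.cy) * np.sin(r)
        yr = -(x - self.cx) * np.sin(r) + (y - self.cy) * np.cos(r)
        q = np.sqrt((xr / self.a) ** 2 + (yr / self.b) ** 2)
        if self.ring > 0:
            shell = np.abs(q - 1.0) * min(self.a, self.b)
            return self.weight * np.exp(-0.5 * (shell / self.ring) ** 2)
        return self.weight * np.clip(1.0 - q**2, 0.0, 1.0)


@dataclass(frozen=True)
class _Bar:
    cx: float
    cy: float
    half_w: float
    half_h: float
    weight: float
    soft: float = 1.5  # edge softness, mm

    def render(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        fx = np.clip((self.half_w - np.abs(x - self.cx)) / self.soft, 0.0, 1.0)
        fy = np.clip((self.half_h - np.abs(y - self.cy)) / self.soft, 0.0, 1.0)
        return self.weight * fx * fy


@dataclass(frozen=True)
class PhantomScene:
    """Analytic 2D attenuation scene standing in for a physical phantom."""

    kind: str
    structures: tuple
    extent_mm: float
    seed: int

    def attenuation(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        """Summed attenuation of all primitives at beam-frame mm points."""
        out = np.zeros(np.broadcast(x_mm, y_mm).shape, dtype=float)
        for s in self.structures:
            out += s.render(x_mm, y_mm)
        return out


def make_scene(kind: str, seed: int = 0) -> PhantomScene:
    """Build a chest- or pelvis-like scene, jittered deterministically by seed."""
    rng = np.random.default_rng(seed)
    extent = 120.0
    structures: list = []
    if kind == "chest":
        # vertebral column: stacked bars down the midline (body + disc pitch)
        for i in range(-4, 5):
            cy = i * 26.0 + rng.uniform(-1.0, 1.0)
            structures.append(_Bar(rng.uniform(-1.5, 1.5), cy, 13.0, 10.0, 200.0))
        # rib pairs: elongated tilted ellipse shells, roughly periodic in y
        # (posterior-rib interspace ~28 mm in AP projection)
        for i in range(-3, 4):
            cy = i * 28.0 + rng.uniform(-2.5, 2.5)
            for side in (-1.0, 1.0):
                structures.append(
                    _Ellipse(
                        cx=side * (52.0 + rng.uniform(-3.0, 3.0)),
                        cy=cy + side * 2.0,
                        a=40.0,
                        b=9.0,
                        angle_deg=side * (12.0 + rng.uniform(-3.0, 3.0)),
                        weight=240.0,
                        ring=2.2,
                    )
                )
        # mediastinum: broad soft-tissue blob
        structures.append(_Ellipse(0.0, 0.0, 38.0, 95.0, 0.0, 120.0))
        # large-scale aperiodic anatomy that dominates the MI landscape, as
        # in a real chest film: diaphragm dome, heart border, shoulder mass
        # at the apex, and an asymmetric lung-field density gradient
        structures.append(_Ellipse(0.0, -62.0, 115.0, 42.0, 0.0, 520.0))
        structures.append(_Ellipse(-22.0, -30.0, 36.0, 30.0, 15.0, 220.0))
        structures.append(_Ellipse(0.0, 64.0, 118.0, 34.0, 0.0, 380.0))
        structures.append(_Ellipse(45.0, 22.0, 48.0, 58.0, 10.0, 110.0))
    elif kind == "pelvis":
        # iliac wings: large smooth ellipses either side
        for side in (-1.0, 1.0):
            structures.append(
                _Ellipse(side * 55.0, 25.0, 45.0, 55.0, -side * 20.0, 230.0)
            )
        # sacrum + broad soft tissue: low-gradient background structure
        structures.append(_Ellipse(0.0, 5.0, 26.0, 42.0, 0.0, 170.0))
        structures.append(_Ellipse(0.0, -10.0, 110.0, 90.0, 0.0, 140.0))
        for _ in range(3):
            structures.append(
                _Ellipse(
                    rng.uniform(-60.0, 60.0),
                    rng.uniform(-70.0, 30.0),
                    rng.uniform(30.0, 50.0),
                    rng.uniform(25.0, 45.0),
                    rng.uniform(-30.0, 30.0),
                    60.0,
                )
            )
    else:
        raise ValueError(f"unknown phantom kind {kind!r}; expected 'chest' or 'pelvis'")
    return PhantomScene(kind=kind, structures=tuple(structures), extent_mm=extent, seed=seed)


@dataclass(frozen=True)
class SyntheticCase:
    """One phantom trial: known offset plus degradation parameters."""

    case_id: str
    true_offset: tuple[float, float]
    repeat_index: int = 1
    contrast: float = 0.5
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    tilt_params: tuple[float, float, float, float] | None = None  # tilt, azimuth, source, plate mm
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError(f"contrast must be in (0, 1], got {self.contrast}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if max(abs(self.true_offset[0]), abs(self.true_offset[1])) > 10.0 + 1e-9:
            raise ValueError(f"offsets are limited to ±10 mm per axis, got {self.true_offset}")


@dataclass(frozen=True)
class CaseList:
    cases: tuple[SyntheticCase, ...]
    shuffle_seed: int


def make_case_list(
    kind: str,
    n_offsets: int = 5,
    seed: int = 0,
    contrast: float | None = None,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
) -> CaseList:
    """Draw ``n_offsets`` uniform offsets in ±10 mm per axis, present each
    twice, and shuffle the order (5 × 2 = 10 cases by default)."""
    if n_offsets < 1:
        raise ValueError("n_offsets must be >= 1")
    contrast = DEFAULT_CONTRAST.get(kind, 0.5) if contrast is None else contrast
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(-10.0, 10.0, size=(n_offsets, 2))
    cases = [
        SyntheticCase(
            case_id=f"{kind}-{i:02d}",
            true_offset=(float(ox), float(oy)),
            repeat_index=rep,
            contrast=contrast,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for i, (ox, oy) in enumerate(offsets)
        for rep in (1, 2)
    ]
    shuffle_seed = int(rng.integers(0, 2**31 - 1))
    order = np.random.default_rng(shuffle_seed).permutation(len(cases))
    return CaseList(cases=tuple(cases[i] for i in order), shuffle_seed=shuffle_seed)


def _beam_grid(shape: tuple[int, int], spacing: float) -> tuple[BeamFrame, np.ndarray, np.ndarray]:
    frame = BeamFrame(((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0), spacing)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    x = (cols - frame.isocenter_px[0]) * spacing
    y = -(rows - frame.isocenter_px[1]) * spacing
    return frame, x, y


def _burn_graticule(
    img: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    spacing: float,
    field_size_mm: float,
    tick_spacing_mm: float,
) -> None:
    """Burn the square field border and 1-cm axis tick marks in place."""
    half = field_size_mm / 2.0
    line = max(spacing, 0.6)  # line half-thickness, mm
    on_v = (np.abs(np.abs(x) - half) <= line) & (np.abs(y) <= half + line)
    on_h = (np.abs(np.abs(y) - half) <= line) & (np.abs(x) <= half + line)
    img[on_v | on_h] = _TICK_VALUE
    n_ticks = int(half // tick_spacing_mm) + 5
    tick_half = 1.2  # tick mark half-length, mm
    for k in range(-n_ticks, n_ticks + 1):
        t = k * tick_spacing_mm
        img[(np.abs(x - t) <= line) & (np.abs(y) <= tick_half)] = _TICK_VALUE
        img[(np.abs(y - t) <= line) & (np.abs(x) <= tick_half)] = _TICK_VALUE


def render_drr(
    scene: PhantomScene,
    field_size_mm: float = 100.0,
    tick_spacing_mm: float = 10.0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    pixel_spacing_mm: float = DEFAULT_SPACING_MM,
) -> ImageGrid:
    """Orthographic scene projection with burned-in field and graticule."""
    frame, x, y = _beam_grid(shape, pixel_spacing_mm)
    img = _BASE_LEVEL + scene.attenuation(x, y)
    np.clip(img, 0.0, INTENSITY_MAX, out=img)
    _burn_graticule(img, x, y, pixel_spacing_mm, field_size_mm, tick_spacing_mm)
    return ImageGrid(img, (pixel_spacing_mm, pixel_spacing_mm), frame)


def render_portal(
    scene: PhantomScene,
    case: SyntheticCase,
    field_size_mm: float = 100.0,
    tick_spacing_mm: float = 10.0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    pixel_spacing_mm: float = DEFAULT_SPACING_MM,
) -> ImageGrid:
    """Render the portal image of a case.

    The anatomy is drawn displaced by ``case.true_offset`` while the field
    border and ticks are burned at the nominal graticule position, then
    intensities are compressed toward the scene mean by ``case.contrast``
    and seeded Gaussian noise is added.  If ``case.tilt_params`` is set,
    the result is re-imaged onto a tilted plate with perspective geometry.
    """
    frame, x, y = _beam_grid(shape, pixel_spacing_mm)
    ox, oy = case.true_offset
    # anatomy moved by +offset: value at p comes from the scene at p − offset
    img = _BASE_LEVEL + scene.attenuation(x - ox, y - oy)
    np.clip(img, 0.0, INTENSITY_MAX, out=img)
    mean = float(img.mean())
    img = mean + case.contrast * (img - mean)  # megavoltage contrast compression
    if case.noise_sigma > 0:
        rng = np.random.default_rng(case.seed)
        img = img + rng.normal(0.0, case.noise_sigma, size=img.shape)
    np.clip(img, 0.0, INTENSITY_MAX, out=img)
    # graticule burned at the NOMINAL position: the field stays, anatomy moved
    _burn_graticule(img, x, y, pixel_spacing_mm, field_size_mm, tick_spacing_mm)
    grid = ImageGrid(img, (pixel_spacing_mm, pixel_spacing_mm), frame)
    if case.tilt_params is not None:
        tilt, azimuth, source, plate = case.tilt_params
        grid, _ = simulate_tilted_plate(grid, tilt, azimuth, source, plate)
    return grid


# ---------------------------------------------------------------------------
# Perspective tilted-plate geometry
# ---------------------------------------------------------------------------


def _plate_basis(tilt_deg: float, azimuth_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tilt axis u (in-plane), second in-plane basis vector, and the plate
    normal, for a plate rotated ``tilt_deg`` about u at ``azimuth_deg``."""
    a = np.deg2rad(azimuth_deg)
    t = np.deg2rad(tilt_deg)
    u = np.array([np.cos(a), np.sin(a), 0.0])
    w = np.array([-np.sin(a), np.cos(a), 0.0])  # in-plane, perpendicular to u
    z = np.array([0.0, 0.0, 1.0])
    e2 = np.cos(t) * w + np.sin(t) * z
    n = -np.sin(t) * w + np.cos(t) * z
    return u, e2, n


def project_beam_points(
    points_mm: np.ndarray,
    tilt_deg: float,
    azimuth_deg: float = 0.0,
    source_mm: float = 1000.0,
    plate_mm: float = 400.0,
) -> np.ndarray:
    """Perspectively project beam-plane points onto the tilted plate.

    The source sits ``source_mm`` above the isocenter plane on the beam
    axis; the plate passes ``plate_mm`` beyond the isocenter, tilted by
    ``tilt_deg`` about the in-plane axis at ``azimuth_deg``.  Returns 2D
    plate coordinates (mm, in the plate's in-plane basis).  At zero tilt
    this is a pure magnification by (source+plate)/source.
    """
    if not tilt_deg < 45.0:
        raise ValueError(f"tilt must be < 45°, got {tilt_deg}")
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    e1, e2, n = _plate_basis(tilt_deg, azimuth_deg)
    S = np.array([0.0, 0.0, source_mm])
    C = np.array([0.0, 0.0, -plate_mm])
    Q = np.column_stack([pts, np.zeros(len(pts))])
    d = Q - S
    dn = d @ n
    if np.any(np.abs(dn) < 1e-12):
        raise ValueError("degenerate geometry: ray parallel to the imaging plate")
    t = ((C - S) @ n) / dn
    hit = S + t[:, None] * d - C
    out = np.column_stack([hit @ e1, hit @ e2])
    return out[0] if np.ndim(points_mm) == 1 else out


def simulate_tilted_plate(
    grid: ImageGrid,
    tilt_deg: float,
    azimuth_deg: float = 0.0,
    source_mm: float = 1000.0,
    plate_mm: float = 400.0,
    out_shape: tuple[int, int] | None = None,
    out_spacing_mm: float | None = None,
    axis_length_mm: float = 100.0,
) -> tuple[ImageGrid, dict[str, tuple[float, float]]]:
    """Image a beam-frame grid onto a tilted plate (full perspective).

    Returns the plate image together with the exact plate *pixel*
    positions of the isocenter and the two graticule axis points — the
    ground-truth control points for downstream correction.
    """
    if grid.frame is None:
        raise ValueError("simulate_tilted_plate needs a beam-framed image")
    mag = (source_mm + plate_mm) / source_mm
    shape = out_shape or grid.shape
    spacing = out_spacing_mm or grid.pixel_spacing_mm[0] * mag
    plate_frame_center = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)

    def plate_mm_to_px(p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        return np.column_stack(
            [plate_frame_center[0] + p[:, 0] / spacing, plate_frame_center[1] - p[:, 1] / spacing]
        )

    # render the plate image: plate pixel -> 3D point -> ray back to beam plane
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    p1 = (cols - plate_frame_center[0]) * spacing
    p2 = -(rows - plate_frame_center[1]) * spacing
    e1, e2, n = _plate_basis(tilt_deg, azimuth_deg)
    S = np.array([0.0, 0.0, source_mm])
    C = np.array([0.0, 0.0, -plate_mm])
    X = C + p1[..., None] * e1 + p2[..., None] * e2
    denom = source_mm - X[..., 2]
    t = source_mm / denom
    bx = S[0] + t * (X[..., 0] - S[0])
    by = S[1] + t * (X[..., 1] - S[1])
    src = grid.frame.mm_to_px(np.stack([bx.ravel(), by.ravel()], axis=-1))
    plate_img = resample_by_pixel_map(
        grid,
        src[:, 0].reshape(shape),
        src[:, 1].reshape(shape),
        frame=None,
        pixel_spacing_mm=(spacing, spacing),
    )
    plate_img.frame = None  # raw plate pixels: the frame must be re-anchored

    beam_cp = np.array([[0.0, 0.0], [axis_length_mm, 0.0], [0.0, axis_length_mm]])
    plate_cp = project_beam_points(beam_cp, tilt_deg, azimuth_deg, source_mm, plate_mm)
    px = plate_mm_to_px(plate_cp)
    control_points = {
        "isocenter": (float(px[0, 0]), float(px[0, 1])),
        "axis_point_x": (float(px[1, 0]), float(px[1, 1])),
        "axis_point_y": (float(px[2, 0]), float(px[2, 1])),
    }
    return plate_img, control_points


def tilt_experiment_residuals(
    tilt_deg: float = 10.0,
    azimuth_deg: float = 0.0,
    source_mm: float = 1000.0,
    plate_mm: float = 400.0,
    axis_length_mm: float = 100.0,
    inside_point_mm: tuple[float, float] = (50.0, 50.0),
    outside_point_mm: tuple[float, float] = (150.0, 150.0),
) -> tuple[float, float]:
    """Residual (mm) of the control-point tilt correction at a test point
    inside vs outside the working area, under true perspective projection.

    The three control points (isocenter + axis points) are projected onto
    the tilted plate, an affine correction is solved from them, and each
    test point's perspective projection is pulled back through it; the
    residual is the distance to the true beam-frame point.  Because the
    affine model only approximates the perspective map, the residual
    grows away from the control points.
    """
    from .geometry import PlanarTransform, PointPairList, invert_distort, solve_linear_map

    beam = np.array([[axis_length_mm, 0.0], [0.0, axis_length_mm]])
    proj = lambda p: project_beam_points(  # noqa: E731
        np.asarray(p, dtype=float), tilt_deg, azimuth_deg, source_mm, plate_mm
    )
    iso = proj((0.0, 0.0))
    plate_vecs = np.stack([proj(beam[0]) - iso, proj(beam[1]) - iso])
    M = solve_linear_map(PointPairList(beam, plate_vecs))
    transform = PlanarTransform(linear=M, translation=iso)

    def residual(p: tuple[float, float]) -> float:
        corrected = invert_distort(proj(p), transform)
        return float(np.linalg.norm(corrected - np.asarray(p)))

    return residual(inside_point_mm), residual(outside_point_mm)
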