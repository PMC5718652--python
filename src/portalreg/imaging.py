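"""Image I/O, display windowing, manual shift/rotate, and color fusion.

Portal radiographs are deep-bit (typically 10-bit) CR scans; DRRs come
from the planning system in any common raster format.  Both are handled
as :class:`ImageGrid` — raw intensities kept as-is, display mapping done
separately through a window/level.  The fused view assigns the two
windowed images to complementary RGB channel sets so that perfectly
aligned content renders neutral gray and misalignments appear as color
shadows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import BeamFrame, ImageGrid, resample_by_pixel_map

__all__ = [
    "ImageGrid",
    "WindowLevel",
    "FusionView",
    "ImageFormatError",
    "COLOR_PAIRS",
    "load_image",
    "save_png",
    "auto_window_level",
    "apply_window_level",
    "shift_rotate",
    "fuse_complementary",
    "load_control_points",
    "save_control_points",
]

_DICOM_SUFFIXES = {".dcm", ".dicom", ".ima"}

#: channel indices driven by image A for each complementary pair; B gets the rest
COLOR_PAIRS = {
    "red-cyan": (0,),
    "green-magenta": (1,),
    "blue-yellow": (2,),
}


class ImageFormatError(ValueError):
    """The file could not be read as a supported image format."""


@dataclass(frozen=True)
class WindowLevel:
    """Linear display mapping: ``window`` width and ``level`` center, in
    raw intensity units."""

    window: float
    level: float

    def __post_init__(self) -> None:
        if not self.window > 0:
            raise ValueError(f"window width must be > 0, got {self.window}")


@dataclass
class FusionView:
    """RGB composite of two windowed images on complementary channels."""

    rgb: np.ndarray
    color_pair: str
    components: tuple[np.ndarray, np.ndarray]


def load_image(path: str | Path, format_hint: str | None = None) -> ImageGrid:
    """Read a DICOM or PNG/BMP/JPEG file into an :class:`ImageGrid`.

    Pixel spacing is taken from DICOM metadata when present; otherwise it
    stays at 1 mm/px and is expected to be calibrated later from the
    graticule control points.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such image file: {path}")
    hint = (format_hint or path.suffix).lower()
    try:
        if hint in _DICOM_SUFFIXES or hint.lstrip(".") == "dicom":
            import pydicom

            ds = pydicom.dcmread(str(path))
            arr = ds.pixel_array.astype(float)
            spacing = (1.0, 1.0)
            for key in ("ImagerPixelSpacing", "PixelSpacing"):
                if key in ds:
                    vals = [float(v) for v in ds[key].value]
                    spacing = (vals[0], vals[1])
                    break
            return ImageGrid(intensities=arr, pixel_spacing_mm=spacing)
        from PIL import Image

        with Image.open(path) as im:
            if im.mode not in ("I", "I;16", "F", "L"):
                im = im.convert("L")
            arr = np.asarray(im, dtype=float)
        return ImageGrid(intensities=arr)
    except ImageFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize reader failures
        raise ImageFormatError(f"cannot read image file {path}: {exc}") from exc


def save_png(path: str | Path, array01: np.ndarray) -> None:
    """Write a [0,1] gray or RGB array as an 8-bit PNG."""
    from PIL import Image

    arr = np.clip(np.asarray(array01, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(str(path))


def auto_window_level(img: ImageGrid) -> WindowLevel:
    """Histogram-based automatic window/level.

    The window spans the 1st–99th percentile of the valid (non-background)
    intensities — robust against the burned-in graticule extremes — with
    the level at its midpoint.  A constant image gets a minimal window of
    one intensity unit centered on the value.
    """
    vals = img.valid_values()
    if vals.size == 0:
        raise ValueError("image has no valid pixels to window")
    p1, p99 = np.percentile(vals, [1.0, 99.0])
    width = p99 - p1
    if width <= 0:
        return WindowLevel(window=1.0, level=float(p1))
    return WindowLevel(window=float(width), level=float(0.5 * (p1 + p99)))


def apply_window_level(img: ImageGrid, wl: WindowLevel) -> np.ndarray:
    """Map raw intensities linearly to display values in [0, 1]."""
    return np.clip((img.intensities - wl.level) / wl.window + 0.5, 0.0, 1.0)


def shift_rotate(img: ImageGrid, dx_mm: float, dy_mm: float, rot_deg: float) -> ImageGrid:
    """Rigidly move image content by (dx, dy) mm and rotate it ``rot_deg``
    counter-clockwise about the isocenter (beam-frame convention).

    Content is rotated first, then shifted; resampling is bilinear and
    pixels pulled from outside the source are flagged background.
    """
    if img.frame is None:
        raise ValueError("shift_rotate requires an image with a beam frame")
    frame = img.frame
    rows, cols = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(float)
    mm = frame.px_to_mm(np.stack([cols.ravel(), rows.ravel()], axis=-1))
    r = np.deg2rad(rot_deg)
    c, s = np.cos(r), np.sin(r)
    rot_inv = np.array([[c, s], [-s, c]])
    src_mm = (mm - np.array([dx_mm, dy_mm])) @ rot_inv.T
    src_px = frame.mm_to_px(src_mm)
    return resample_by_pixel_map(
        img, src_px[:, 0].reshape(img.shape), src_px[:, 1].reshape(img.shape)
    )


def fuse_complementary(
    imgA: ImageGrid,
    imgB: ImageGrid,
    color_pair: str = "red-cyan",
    wlA: WindowLevel | None = None,
    wlB: WindowLevel | None = None,
) -> FusionView:
    """Overlay two co-framed images on complementary color channels.

    A drives one channel set and B the complementary set (for red-cyan:
    A→R, B→G+B), so wherever the windowed images agree the composite is
    neutral gray and any misalignment shows as a color shadow.
    """
    if imgA.shape != imgB.shape:
        raise ValueError(f"fusion requires equal shapes, got {imgA.shape} vs {imgB.shape}")
    if color_pair not in COLOR_PAIRS:
        raise ValueError(f"unknown color pair {color_pair!r}; choose from {sorted(COLOR_PAIRS)}")
    a = apply_window_level(imgA, wlA or auto_window_level(imgA))
    b = apply_window_level(imgB, wlB or auto_window_level(imgB))
    rgb = np.empty(imgA.shape + (3,), dtype=float)
    a_channels = COLOR_PAIRS[color_pair]
    for ch in range(3):
        rgb[..., ch] = a if ch in a_channels else b
    return FusionView(rgb=rgb, color_pair=color_pair, components=(a, b))


def save_control_points(path: str | Path, cps) -> None:
    """Persist a :class:`~portalreg.geometry.ControlPointSet` as a JSON sidecar."""
    payload = {
        "isocenter": list(cps.isocenter),
        "axis_point_x": list(cps.axis_point_x),
        "axis_point_y": list(cps.axis_point_y),
        "axis_length_mm": cps.axis_length_mm,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_control_points(path: str | Path):
    from .geometry import ControlPointSet

    data = json.loads(Path(path).read_text())
    return ControlPointSet(
        isocenter=tuple(data["isocenter"]),
        axis_point_x=tuple(data["axis_point_x"]),
        axis_point_y=tuple(data["axis_point_y"]),
        axis_length_mm=float(data.get("axis_length_mm", 100.0)),
    )
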