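"""Shared containers: the beam's-eye-view coordinate frame and the image grid.

Conventions used throughout the package
---------------------------------------
* Beam frame ("BEV"): millimetres, origin at the isocenter, +x to the
  right, +y up.  This is the frame in which setup offsets are reported.
* Pixel coordinates: ``(col, row)``, 0-based, row increasing downward.
  Continuous pixel coordinates address pixel centers.
* "Plate math" coordinates: ``(u, v) = (col, -row)`` — a right-handed
  version of pixel coordinates so that orientation-preserving physical
  transforms have positive determinant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class BeamFrame:
    """Anchors beam-frame mm coordinates onto an image's pixel grid.

    Parameters
    ----------
    isocenter_px : (col, row) continuous pixel coordinate of the isocenter.
    pixel_spacing_mm : physical size of one pixel (isotropic).
    """

    isocenter_px: tuple[float, float]
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        if not self.pixel_spacing_mm > 0:
            raise ValueError(f"pixel_spacing_mm must be > 0, got {self.pixel_spacing_mm}")

    def mm_to_px(self, points_mm: np.ndarray) -> np.ndarray:
        """Beam-frame mm ``(x, y)`` -> pixel ``(col, row)`` (y axis flips)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        col = self.isocenter_px[0] + p[..., 0] / self.pixel_spacing_mm
        row = self.isocenter_px[1] - p[..., 1] / self.pixel_spacing_mm
        out = np.stack([col, row], axis=-1)
        return out[0] if np.ndim(points_mm) == 1 else out

    def px_to_mm(self, points_px: np.ndarray) -> np.ndarray:
        """Pixel ``(col, row)`` -> beam-frame mm ``(x, y)``."""
        p = np.atleast_2d(np.asarray(points_px, dtype=float))
        x = (p[..., 0] - self.isocenter_px[0]) * self.pixel_spacing_mm
        y = -(p[..., 1] - self.isocenter_px[1]) * self.pixel_spacing_mm
        out = np.stack([x, y], axis=-1)
        return out[0] if np.ndim(points_px) == 1 else out


@dataclass
class ImageGrid:
    """A 2D intensity image with spacing, an optional beam frame, and a
    validity mask.

    ``background_mask`` is True where the pixel holds real image content;
    resampling operations flag pixels pulled from outside the source
    footprint as background rather than writing zero intensity.
    """

    intensities: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)  # (row, col)
    frame: BeamFrame | None = None
    background_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        sr, sc = self.pixel_spacing_mm
        if not (sr > 0 and sc > 0):
            raise ValueError(f"pixel spacing must be > 0, got {self.pixel_spacing_mm}")
        if self.background_mask is None:
            self.background_mask = np.ones(self.intensities.shape, dtype=bool)
        else:
            self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if self.background_mask.shape != self.intensities.shape:
            raise ValueError("background_mask shape must match intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    def valid_values(self) -> np.ndarray:
        return self.intensities[self.background_mask]

    def copy(self) -> "ImageGrid":
        return replace(
            self,
            intensities=self.intensities.copy(),
            background_mask=self.background_mask.copy(),
        )


def resample_by_pixel_map(
    img: ImageGrid,
    src_cols: np.ndarray,
    src_rows: np.ndarray,
    *,
    frame: BeamFrame | None = None,
    pixel_spacing_mm: tuple[float, float] | None = None,
) -> ImageGrid:
    """Pull-resample ``img`` through a per-output-pixel source location map.

    ``src_cols``/``src_rows`` give, for every output pixel, the continuous
    pixel coordinate in ``img`` to sample (bilinear).  Output pixels whose
    source location falls outside the image footprint, or on masked input,
    are flagged background.
    """
    coords = np.stack([src_rows, src_cols])  # map_coordinates wants (row, col)
    vals = ndimage.map_coordinates(img.intensities, coords, order=1, mode="constant", cval=0.0)
    mask_f = ndimage.map_coordinates(
        img.background_mask.astype(float), coords, order=1, mode="constant", cval=0.0
    )
    h, w = img.shape
    inside = (src_rows >= 0) & (src_rows <= h - 1) & (src_cols >= 0) & (src_cols <= w - 1)
    out_mask = inside & (mask_f > 1.0 - 1e-9)
    vals[~out_mask] = 0.0
    return ImageGrid(
        intensities=vals,
        pixel_spacing_mm=pixel_spacing_mm or img.pixel_spacing_mm,
        frame=frame if frame is not None else img.frame,
        background_mask=out_mask,
    )
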