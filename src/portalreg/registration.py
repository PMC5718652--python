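"""Mutual-information auto-registration of portal and DRR images.

The setup error is estimated by maximizing the mutual information (MI)
between the corrected portal image and the DRR over candidate shifts
(and, optionally, small in-plane rotations).  For images A and B with
binned intensity histograms,

    H(A)   = Σ_i p_i log2 (1/p_i)
    H(A,B) = −Σ_ij p(i,j) log2 p(i,j)
    I(A,B) = H(A) + H(B) − H(A,B)

computed over the overlapping valid pixels only.  MI is maximal when the
images are aligned and makes no assumption about how portal and DRR
intensities relate, which suits megavoltage portal contrast.

The optimizer is a deterministic hill climb: the portal is trial-shifted
left/right/up/down by the current step and the strictly best neighbor is
accepted until no move improves the score.  A multiresolution schedule
(step 4 mm, halved down to 1 mm by default) reduces the chance of
stopping on a local maximum; when rotation search is enabled, shift and
rotation climbs alternate at each resolution until neither improves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import ImageGrid
from .imaging import shift_rotate

__all__ = [
    "HistogramSpec",
    "RegistrationConfig",
    "OffsetEstimate",
    "EmptyOverlapError",
    "IterationLimitError",
    "entropy",
    "joint_entropy",
    "mutual_information",
    "hill_climb_shift",
    "auto_register",
    "MIEvaluator",
]

_MAX_MOVES = 10_000


class EmptyOverlapError(ValueError):
    """No valid overlapping pixels to histogram."""


class IterationLimitError(RuntimeError):
    """The hill climb failed to converge within the move budget."""


@dataclass(frozen=True)
class HistogramSpec:
    """Binning for the (joint) intensity histogram.

    ``range_a``/``range_b`` fix the intensity bounds per image; when None
    they default to the min/max of the valid pixels at evaluation time.
    64 equal-width bins keep the joint histogram well populated for
    10-bit data.
    """

    n_bins: int = 64
    range_a: tuple[float, float] | None = None
    range_b: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        for r in (self.range_a, self.range_b):
            if r is not None and not (r[1] > r[0]):
                raise ValueError(f"histogram range must be nondegenerate, got {r}")

    @staticmethod
    def from_images(imgA: ImageGrid, imgB: ImageGrid, n_bins: int = 64) -> "HistogramSpec":
        """Fix both ranges from the full valid intensity span of each image,
        so that the binning does not change between candidate offsets."""
        return HistogramSpec(
            n_bins=n_bins,
            range_a=_safe_range(imgA.valid_values()),
            range_b=_safe_range(imgB.valid_values()),
        )


def _safe_range(vals: np.ndarray) -> tuple[float, float]:
    if vals.size == 0:
        raise EmptyOverlapError("no valid pixels")
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:  # constant image: one unit wide, everything in one bin
        lo, hi = lo - 0.5, lo + 0.5
    return lo, hi


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log2(p)).sum())


def _overlap_values(imgA: ImageGrid, imgB: ImageGrid) -> tuple[np.ndarray, np.ndarray]:
    if imgA.shape != imgB.shape:
        raise ValueError(f"images must share a shape, got {imgA.shape} vs {imgB.shape}")
    joint = imgA.background_mask & imgB.background_mask
    if not joint.any():
        raise EmptyOverlapError("valid-pixel overlap of the two images is empty")
    return imgA.intensities[joint], imgB.intensities[joint]


def entropy(img: ImageGrid, spec: HistogramSpec = HistogramSpec()) -> float:
    """Shannon entropy (bits) of the binned valid-pixel histogram."""
    vals = img.valid_values()
    rng = spec.range_a or _safe_range(vals)
    counts, _ = np.histogram(vals, bins=spec.n_bins, range=rng)
    if counts.sum() == 0:
        raise EmptyOverlapError("no valid pixels inside the histogram range")
    return _entropy_bits(counts)


def _joint_counts(imgA: ImageGrid, imgB: ImageGrid, spec: HistogramSpec) -> np.ndarray:
    a, b = _overlap_values(imgA, imgB)
    ra = spec.range_a or _safe_range(a)
    rb = spec.range_b or _safe_range(b)
    counts, _, _ = np.histogram2d(a, b, bins=spec.n_bins, range=[ra, rb])
    if counts.sum() == 0:
        raise EmptyOverlapError("no overlapping pixels inside the histogram ranges")
    return counts


def joint_entropy(imgA: ImageGrid, imgB: ImageGrid, spec: HistogramSpec = HistogramSpec()) -> float:
    """Joint Shannon entropy (bits) over the overlapping valid pixels."""
    return _entropy_bits(_joint_counts(imgA, imgB, spec))


def mutual_information(
    imgA: ImageGrid, imgB: ImageGrid, spec: HistogramSpec = HistogramSpec()
) -> float:
    """I(A,B) = H(A) + H(B) − H(A,B), in bits, over the joint valid mask.

    Marginal entropies are taken from the joint histogram's marginals so
    all three terms see exactly the same pixels; the result is symmetric
    and nonnegative up to rounding.
    """
    counts = _joint_counts(imgA, imgB, spec)
    return (
        _entropy_bits(counts.sum(axis=1))
        + _entropy_bits(counts.sum(axis=0))
        - _entropy_bits(counts)
    )


@dataclass(frozen=True)
class RegistrationConfig:
    """Optimizer schedule and MI options.

    Shift steps start at ``initial_step_mm`` (4 mm) and halve exactly down
    to ``final_step_mm`` (1 mm; may be sub-millimeter).  Rotation search
    is off by default — phantom-study cases have no rotation — and when
    enabled climbs ±``rot_*_step_deg`` within ±``rot_range_deg``.
    ``restrict_to_working_area`` limits the MI computation to the
    ±``working_area_mm`` box around the isocenter, where the control-point
    correction is trustworthy.

    ``exclude_burned_in`` drops saturated pixels (the top histogram bin of
    each image) from the MI computation.  Burned-in field borders and
    graticule ticks sit at the nominal position in *both* images by
    construction, so they carry no information about the setup error and,
    if included, reward zero shift with a spurious MI peak.
    """

    initial_step_mm: float = 4.0
    final_step_mm: float = 1.0
    rot_enabled: bool = False
    rot_initial_step_deg: float = 2.0
    rot_final_step_deg: float = 0.25
    rot_range_deg: float = 5.0
    max_outer_iterations: int = 50
    restrict_to_working_area: bool = True
    working_area_mm: float = 100.0
    n_bins: int = 64
    exclude_burned_in: bool = True

    def __post_init__(self) -> None:
        if not (self.initial_step_mm >= self.final_step_mm > 0):
            raise ValueError("need initial_step_mm >= final_step_mm > 0")
        for ini, fin, what in (
            (self.initial_step_mm, self.final_step_mm, "shift"),
            (self.rot_initial_step_deg, self.rot_final_step_deg, "rotation"),
        ):
            ratio = ini / fin
            if abs(ratio - 2.0 ** round(math.log2(ratio))) > 1e-9 * ratio:
                raise ValueError(
                    f"{what} steps must halve exactly from initial to final "
                    f"(initial/final = {ratio:g} is not a power of two)"
                )

    def shift_steps(self) -> list[float]:
        steps, s = [], self.initial_step_mm
        while s > self.final_step_mm * (1 + 1e-12):
            steps.append(s)
            s /= 2.0
        steps.append(self.final_step_mm)
        return steps

    def rot_steps(self) -> list[float]:
        steps, s = [], self.rot_initial_step_deg
        while s > self.rot_final_step_deg * (1 + 1e-12):
            steps.append(s)
            s /= 2.0
        steps.append(self.rot_final_step_deg)
        return steps

    @staticmethod
    def from_file(path: str | Path) -> "RegistrationConfig":
        """Load from a JSON or ``key = value`` config file."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                data[key.strip()] = json.loads(val.strip().lower())
        return RegistrationConfig(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass(frozen=True)
class OffsetEstimate:
    """Setup error in beam's-eye-view field-shift convention: the portal
    anatomy sits at (+dx, +dy) mm, rotated ``rot_deg`` CCW, relative to
    the planned position in the DRR."""

    dx_mm: float
    dy_mm: float
    rot_deg: float = 0.0
    mi_score: float = float("nan")
    n_evaluations: int = 0

    def offset(self) -> tuple[float, float]:
        return (self.dx_mm, self.dy_mm)


def _mask_saturated(img: ImageGrid, n_bins: int) -> ImageGrid:
    """Flag the top-bin (saturated) pixels invalid: burned-in graphics."""
    vals = img.valid_values()
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return img
    thresh = hi - (hi - lo) / n_bins
    return ImageGrid(
        intensities=img.intensities,
        pixel_spacing_mm=img.pixel_spacing_mm,
        frame=img.frame,
        background_mask=img.background_mask & (img.intensities < thresh),
    )


class MIEvaluator:
    """Caches MI evaluations of candidate (dx, dy, rot) offsets.

    A candidate is scored by shifting the portal back by (−dx, −dy, −rot)
    and computing MI against the stationary DRR; histogram ranges are
    frozen from the full images once so the objective is consistent
    across candidates.
    """

    def __init__(self, portal: ImageGrid, drr: ImageGrid, config: RegistrationConfig):
        if portal.frame is None or drr.frame is None:
            raise ValueError("auto-registration requires beam-framed images")
        if portal.shape != drr.shape:
            raise ValueError("portal and DRR must be resampled to the same grid")
        self.config = config
        if config.exclude_burned_in:
            portal = _mask_saturated(portal, config.n_bins)
            drr = _mask_saturated(drr, config.n_bins)
        self.portal = portal
        self.spec = HistogramSpec.from_images(portal, drr, n_bins=config.n_bins)
        drr_eval = drr
        if config.restrict_to_working_area:
            rows, cols = np.mgrid[0 : drr.shape[0], 0 : drr.shape[1]].astype(float)
            mm = drr.frame.px_to_mm(np.stack([cols.ravel(), rows.ravel()], axis=-1))
            box = (np.abs(mm[:, 0]) <= config.working_area_mm) & (
                np.abs(mm[:, 1]) <= config.working_area_mm
            )
            drr_eval = ImageGrid(
                intensities=drr.intensities,
                pixel_spacing_mm=drr.pixel_spacing_mm,
                frame=drr.frame,
                background_mask=drr.background_mask & box.reshape(drr.shape),
            )
        self.drr = drr_eval
        self._cache: dict[tuple[float, float, float], float] = {}

    def mi(self, dx: float, dy: float, rot: float = 0.0) -> float:
        key = (round(dx, 9), round(dy, 9), round(rot, 9))
        if key not in self._cache:
            moved = shift_rotate(self.portal, -dx, -dy, -rot)
            self._cache[key] = mutual_information(moved, self.drr, self.spec)
        return self._cache[key]

    @property
    def n_evaluations(self) -> int:
        return len(self._cache)


def _climb_shift(ev: MIEvaluator, est: OffsetEstimate, step_mm: float) -> OffsetEstimate:
    dx, dy, rot = est.dx_mm, est.dy_mm, est.rot_deg
    best = ev.mi(dx, dy, rot)
    for _ in range(_MAX_MOVES):
        # fixed neighbor order gives a deterministic tie-break
        candidates = [(dx + step_mm, dy), (dx - step_mm, dy), (dx, dy + step_mm), (dx, dy - step_mm)]
        move = None
        move_score = best
        for cx, cy in candidates:
            score = ev.mi(cx, cy, rot)
            if score > move_score:  # strict improvement only
                move, move_score = (cx, cy), score
        if move is None:
            return OffsetEstimate(dx, dy, rot, mi_score=best, n_evaluations=ev.n_evaluations)
        (dx, dy), best = move, move_score
    raise IterationLimitError(f"shift hill climb exceeded {_MAX_MOVES} moves at step {step_mm} mm")


def _climb_rotation(ev: MIEvaluator, est: OffsetEstimate, step_deg: float) -> OffsetEstimate:
    dx, dy, rot = est.dx_mm, est.dy_mm, est.rot_deg
    lim = ev.config.rot_range_deg
    best = ev.mi(dx, dy, rot)
    for _ in range(_MAX_MOVES):
        move = None
        move_score = best
        for cand in (rot + step_deg, rot - step_deg):
            if abs(cand) > lim + 1e-12:
                continue
            score = ev.mi(dx, dy, cand)
            if score > move_score:
                move, move_score = cand, score
        if move is None:
            return OffsetEstimate(dx, dy, rot, mi_score=best, n_evaluations=ev.n_evaluations)
        rot, best = move, move_score
    raise IterationLimitError(f"rotation hill climb exceeded {_MAX_MOVES} moves")


def hill_climb_shift(
    portal: ImageGrid,
    drr: ImageGrid,
    start: OffsetEstimate,
    step_mm: float,
    config: RegistrationConfig = RegistrationConfig(),
) -> OffsetEstimate:
    """Four-neighbor hill climb of the x–y shift at a fixed step size.

    The portal is trial-shifted ±step in x and y; the strictly best
    neighbor is accepted (ties broken in +x, −x, +y, −y order) until the
    current shift scores highest.
    """
    ev = MIEvaluator(portal, drr, config)
    return _climb_shift(ev, start, step_mm)


def auto_register(
    portal: ImageGrid,
    drr: ImageGrid,
    config: RegistrationConfig = RegistrationConfig(),
    start: OffsetEstimate | None = None,
) -> OffsetEstimate:
    """Multiresolution MI registration of a corrected portal to its DRR.

    At each step size (initial, halved repeatedly to final) the shift
    climb runs; when rotation is enabled, shift and rotation climbs
    alternate until neither improves.  Fully deterministic: identical
    inputs and config always return the identical estimate.
    """
    ev = MIEvaluator(portal, drr, config)
    est = start or OffsetEstimate(0.0, 0.0, 0.0)
    rot_steps = config.rot_steps()
    for level, step in enumerate(config.shift_steps()):
        rot_step = rot_steps[min(level, len(rot_steps) - 1)]
        for _ in range(config.max_outer_iterations):
            before = (est.dx_mm, est.dy_mm, est.rot_deg)
            est = _climb_shift(ev, est, step)
            if config.rot_enabled:
                est = _climb_rotation(ev, est, rot_step)
            if (est.dx_mm, est.dy_mm, est.rot_deg) == before:
                break
    return OffsetEstimate(
        est.dx_mm,
        est.dy_mm,
        est.rot_deg,
        mi_score=ev.mi(est.dx_mm, est.dy_mm, est.rot_deg),
        n_evaluations=ev.n_evaluations,
    )


def exhaustive_grid_search(
    portal: ImageGrid,
    drr: ImageGrid,
    config: RegistrationConfig = RegistrationConfig(),
    half_range_mm: float = 10.0,
    step_mm: float = 1.0,
) -> OffsetEstimate:
    """Brute-force MI argmax over a square shift grid (oracle / fallback).

    Evaluates every candidate on the ±``half_range_mm`` grid at
    ``step_mm`` spacing (rotation fixed at 0) and returns the best; ties
    go to the earliest candidate in row-major (x fastest) order.
    """
    ev = MIEvaluator(portal, drr, config)
    n = int(round(half_range_mm / step_mm))
    grid = [i * step_mm for i in range(-n, n + 1)]
    best, best_score = (0.0, 0.0), -np.inf
    for dy in grid:
        for dx in grid:
            score = ev.mi(dx, dy)
            if score > best_score:
                best, best_score = (dx, dy), score
    return OffsetEstimate(best[0], best[1], 0.0, mi_score=best_score, n_evaluations=ev.n_evaluations)
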