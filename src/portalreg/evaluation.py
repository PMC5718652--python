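"""Scoring of estimated setup offsets against ground truth.

Implements the phantom-study statistics: Euclidean distance between
estimated and true offsets, per-case consistency (distance between two
repeats of the same case), mean ± SD summaries, the Good/Fair/Poor/
Terrible distance bins, the paired t-test between methods, and the
couch-shift conversion of a beam's-eye-view offset.

Also provides ``run_phantom_study``, the batch harness that chains
synthetic case generation → rendering → auto-registration → scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict

import numpy as np
from scipy import stats

__all__ = [
    "EvaluationRecord",
    "SummaryStats",
    "BinCounts",
    "DegenerateTestError",
    "offset_distance",
    "consistency",
    "summarize",
    "bin_distance",
    "bin_counts",
    "paired_t_test",
    "couch_correction",
    "run_phantom_study",
]

BIN_NAMES = ("Good", "Fair", "Poor", "Terrible")
_BIN_EDGES = (2.0, 5.0, 10.0)  # right-closed: d ≤ 2 Good, ≤ 5 Fair, ≤ 10 Poor, > 10 Terrible


class DegenerateTestError(ValueError):
    """The paired differences have zero variance; the t-test is undefined."""


def offset_distance(est: tuple[float, float], true: tuple[float, float]) -> float:
    """Euclidean distance √((x−x₀)² + (y−y₀)²) in mm."""
    return float(np.hypot(est[0] - true[0], est[1] - true[1]))


@dataclass(frozen=True)
class EvaluationRecord:
    """One scored trial: a case, its truth, and one method's estimate."""

    case_id: str
    true_offset: tuple[float, float]
    estimated_offset: tuple[float, float]
    repeat_index: int = 1
    method: str = "auto"
    distance: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "distance", offset_distance(self.estimated_offset, self.true_offset)
        )


def consistency(
    est1: EvaluationRecord | tuple[float, float], est2: EvaluationRecord | tuple[float, float]
) -> float:
    """Distance between two estimates of the same case (repeatability).

    Accepts raw offset tuples or records; records must share a case_id.
    """
    if isinstance(est1, EvaluationRecord) and isinstance(est2, EvaluationRecord):
        if est1.case_id != est2.case_id:
            raise ValueError(
                f"consistency needs two estimates of one case, got "
                f"{est1.case_id!r} and {est2.case_id!r}"
            )
        est1, est2 = est1.estimated_offset, est2.estimated_offset
    return offset_distance(est1, est2)  # type: ignore[arg-type]


@dataclass(frozen=True)
class SummaryStats:
    mean_distance: float
    sd_distance: float
    mean_consistency: float
    sd_consistency: float
    n: int


def _pairwise_consistencies(records: list[EvaluationRecord]) -> list[float]:
    by_case: dict[str, list[EvaluationRecord]] = defaultdict(list)
    for r in records:
        by_case[r.case_id].append(r)
    out = []
    for case_recs in by_case.values():
        case_recs = sorted(case_recs, key=lambda r: r.repeat_index)
        for a, b in zip(case_recs, case_recs[1:]):
            out.append(consistency(a, b))
    return out


def summarize(records: list[EvaluationRecord]) -> SummaryStats:
    """Sample mean and SD (n−1 denominator) of distances and per-case
    consistencies over a record set."""
    if len(records) < 2:
        raise ValueError(f"summarize needs at least 2 records, got {len(records)}")
    d = np.array([r.distance for r in records])
    cons = np.array(_pairwise_consistencies(records))
    return SummaryStats(
        mean_distance=float(d.mean()),
        sd_distance=float(d.std(ddof=1)),
        mean_consistency=float(cons.mean()) if cons.size else float("nan"),
        sd_consistency=float(cons.std(ddof=1)) if cons.size > 1 else 0.0,
        n=len(records),
    )


def bin_distance(d: float) -> str:
    """Classify a distance: ≤2 mm Good, ≤5 Fair, ≤10 Poor, >10 Terrible."""
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    for name, edge in zip(BIN_NAMES, _BIN_EDGES):
        if d <= edge:
            return name
    return BIN_NAMES[-1]


@dataclass(frozen=True)
class BinCounts:
    counts: dict[str, int]
    percentages: dict[str, float]
    n: int


def bin_counts(distances: list[float]) -> BinCounts:
    counts = {name: 0 for name in BIN_NAMES}
    for d in distances:
        counts[bin_distance(d)] += 1
    n = len(distances)
    pct = {k: (100.0 * v / n if n else 0.0) for k, v in counts.items()}
    return BinCounts(counts=counts, percentages=pct, n=n)


def paired_t_test(distances_a: np.ndarray, distances_b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test between two methods' distance vectors.

    Returns (t, p) with n−1 degrees of freedom.  Zero-variance paired
    differences make the statistic undefined and raise
    :class:`DegenerateTestError` rather than reporting p = 0.
    """
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1D vectors with n >= 2")
    if np.std(a - b, ddof=1) == 0:
        raise DegenerateTestError("paired differences have zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def couch_correction(offset, gantry_deg: float) -> tuple[float, float, float]:
    """Convert a BEV field shift to couch (lat, long, vert) movements, mm.

    Convention (collimator at 0, gantry rotating about the longitudinal
    axis): the BEV y axis stays longitudinal at every gantry angle, so
    long = −dy; the BEV x axis rotates between lateral and vertical,
    lat = −dx·cos g and vert = +dx·sin g.  Signs are the movements that
    *cancel* the measured offset.
    """
    dx = getattr(offset, "dx_mm", None)
    if dx is None:
        dx, dy = offset
    else:
        dy = offset.dy_mm
    g = np.deg2rad(gantry_deg)
    return (float(-dx * np.cos(g)), float(-dy), float(dx * np.sin(g)))


def run_phantom_study(
    kind: str = "chest",
    seed: int = 0,
    n_offsets: int = 5,
    shape: tuple[int, int] | None = None,
    pixel_spacing_mm: float | None = None,
    contrast: float | None = None,
    noise_sigma: float | None = None,
    config=None,
) -> tuple[list[EvaluationRecord], SummaryStats]:
    """Run the full synthetic phantom study for one phantom kind.

    Generates a seeded scene and case list (five offsets in ±10 mm, each
    twice), renders the DRR once and a portal per case, auto-registers
    each pair, and returns per-case records plus summary statistics.
    """
    from .registration import RegistrationConfig, auto_register
    from . import synthetic as syn

    shape = shape or syn.DEFAULT_SHAPE
    spacing = pixel_spacing_mm or syn.DEFAULT_SPACING_MM
    config = config or RegistrationConfig()
    scene = syn.make_scene(kind, seed=seed)
    kwargs = {} if noise_sigma is None else {"noise_sigma": noise_sigma}
    case_list = syn.make_case_list(kind, n_offsets=n_offsets, seed=seed, contrast=contrast, **kwargs)
    drr = syn.render_drr(scene, shape=shape, pixel_spacing_mm=spacing)
    records = []
    for case in case_list.cases:
        portal = syn.render_portal(scene, case, shape=shape, pixel_spacing_mm=spacing)
        est = auto_register(portal, drr, config)
        records.append(
            EvaluationRecord(
                case_id=case.case_id,
                true_offset=case.true_offset,
                estimated_offset=(est.dx_mm, est.dy_mm),
                repeat_index=case.repeat_index,
                method="auto",
            )
        )
    return records, summarize(records)
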