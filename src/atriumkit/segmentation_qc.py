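"""Segmentation quality control heuristics and mask-quality metrics.

QC flags (per study): more than one connected component in any frame; a
frame-to-frame jump in segmented pixel count beyond five population SDs
above the population mean of per-study maximum jumps; an empty frame; or a
frame count other than 50.  Mask-quality metrics: Sorensen-Dice overlap,
directed Hausdorff distance, and mean contour distance between perimeters,
in millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .plane_geometry import CineSegmentation, SegmentationMask, extract_perimeter

EIGHT_CONN = np.ones((3, 3), dtype=bool)
FOUR_CONN = ndimage.generate_binary_structure(2, 1)

EXPECTED_FRAMES = 50
JUMP_SD_MULTIPLIER = 5.0


@dataclass
class PopulationDeltaStats:
    """Cohort statistics of the per-study maximum frame-to-frame pixel jump."""

    mean_of_max_delta: float
    sd_of_max_delta: float
    n_studies: int

    def __post_init__(self):
        if self.sd_of_max_delta < 0:
            raise ValueError("sd must be non-negative")
        if self.n_studies < 2:
            raise ValueError("population stats need at least 2 studies")

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path) -> "PopulationDeltaStats":
        from pathlib import Path

        return cls(**json.loads(Path(path).read_text()))


@dataclass
class QCReport:
    flag_multi_component: bool
    flag_frame_jump: bool
    flag_empty_frame: bool
    flag_bad_frame_count: bool
    max_frame_delta_px: int
    component_counts: list[int]

    @property
    def any_flag(self) -> bool:
        return (
            self.flag_multi_component
            or self.flag_frame_jump
            or self.flag_empty_frame
            or self.flag_bad_frame_count
        )


def count_components(mask: SegmentationMask, connectivity: int = 8) -> int:
    structure = EIGHT_CONN if connectivity == 8 else FOUR_CONN
    _, n = ndimage.label(mask.pixels, structure=structure)
    return int(n)


def max_frame_delta(cine: CineSegmentation) -> int:
    """Largest |change| in segmented pixel count between consecutive frames."""
    counts = cine.frames.reshape(cine.n_frames, -1).sum(axis=1).astype(int)
    if len(counts) < 2:
        return 0
    return int(np.abs(np.diff(counts)).max())


def population_delta_stats(cines: list[CineSegmentation]) -> PopulationDeltaStats:
    deltas = np.array([max_frame_delta(c) for c in cines], float)
    return PopulationDeltaStats(
        mean_of_max_delta=float(deltas.mean()),
        sd_of_max_delta=float(deltas.std(ddof=1)),
        n_studies=len(deltas),
    )


def qc_flags(
    cine: CineSegmentation,
    pop: PopulationDeltaStats,
    expected_frames: int = EXPECTED_FRAMES,
    connectivity: int = 8,
) -> QCReport:
    comp = [
        count_components(cine.mask(t), connectivity=connectivity)
        for t in range(cine.n_frames)
    ]
    delta = max_frame_delta(cine)
    threshold = pop.mean_of_max_delta + JUMP_SD_MULTIPLIER * pop.sd_of_max_delta
    return QCReport(
        flag_multi_component=any(c > 1 for c in comp),
        flag_frame_jump=delta > threshold,
        flag_empty_frame=any(c == 0 for c in comp),
        flag_bad_frame_count=cine.n_frames != expected_frames,
        max_frame_delta_px=delta,
        component_counts=comp,
    )


def dice(a: SegmentationMask, b: SegmentationMask) -> float:
    """Sorensen-Dice coefficient 2|A.B| / (|A| + |B|); 1 when both empty."""
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("masks must share a shape")
    inter = int(np.sum(a.pixels & b.pixels))
    total = a.n_pixels + b.n_pixels
    if total == 0:
        return 1.0
    return 2.0 * inter / total


def _perimeter_points_mm(mask: SegmentationMask) -> np.ndarray:
    """Perimeter pixel centers in mm, in-plane (isotropic spacing assumed)."""
    perim = extract_perimeter(mask)
    rows, cols = np.nonzero(perim.pixels)
    if len(rows) == 0:
        raise ValueError("mask has an empty perimeter")
    d_row, d_col = mask.geometry.spacing_mm
    return np.column_stack([rows * d_row, cols * d_col])


def directed_hausdorff_mm(a: SegmentationMask, b: SegmentationMask) -> float:
    """Directed Hausdorff distance a -> b between mask perimeters, in mm."""
    pa = _perimeter_points_mm(a)
    pb = _perimeter_points_mm(b)
    d, _ = cKDTree(pb).query(pa)
    return float(d.max())


def symmetric_hausdorff_mm(a: SegmentationMask, b: SegmentationMask) -> float:
    return max(directed_hausdorff_mm(a, b), directed_hausdorff_mm(b, a))


def mean_contour_distance_mm(a: SegmentationMask, b: SegmentationMask) -> float:
    """Mean of nearest-perimeter distances a -> b, in mm (directed)."""
    pa = _perimeter_points_mm(a)
    pb = _perimeter_points_mm(b)
    d, _ = cKDTree(pb).query(pa)
    return float(d.mean())
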