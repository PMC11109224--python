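"""Mapping 2D CINE segmentation masks into the 3D patient coordinate system.

Cardiac MRI acquires each view on a fixed imaging plane whose placement in
the scanner's patient coordinate system is described by the DICOM Image
Position (Patient), Image Orientation (Patient), and Pixel Spacing
attributes.  This module carries that geometry alongside binary
segmentation masks, extracts mask perimeters, and turns them into oriented
point fragments: 3D perimeter points with unit normals that lie in the view
plane and point radially away from the mask's center of gravity.  Those
fragments are the raw material for surface reconstruction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: 3x3 cross (4-connectivity) structuring element used for perimeter erosion.
CROSS = ndimage.generate_binary_structure(2, 1)

VIEW_LABELS = ("lax_2ch", "lax_3ch", "lax_4ch")


@dataclass(frozen=True)
class PlaneGeometry:
    """Placement of one imaging plane in patient coordinates (mm).

    Follows the DICOM pixel-center convention: the patient coordinate of
    pixel (row, col) is

        P = origin + col * spacing_mm[1] * row_cosine
                   + row * spacing_mm[0] * col_cosine

    where ``row_cosine`` is the direction of increasing column index (the
    first Image Orientation triplet) and ``col_cosine`` the direction of
    increasing row index (the second triplet).
    """

    origin_mm: np.ndarray
    row_cosine: np.ndarray
    col_cosine: np.ndarray
    spacing_mm: tuple[float, float]
    thickness_mm: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "origin_mm", np.asarray(self.origin_mm, float))
        object.__setattr__(self, "row_cosine", np.asarray(self.row_cosine, float))
        object.__setattr__(self, "col_cosine", np.asarray(self.col_cosine, float))
        object.__setattr__(self, "spacing_mm", (float(self.spacing_mm[0]), float(self.spacing_mm[1])))
        if abs(np.linalg.norm(self.row_cosine) - 1.0) > 1e-9:
            raise ValueError("row_cosine must be a unit vector")
        if abs(np.linalg.norm(self.col_cosine) - 1.0) > 1e-9:
            raise ValueError("col_cosine must be a unit vector")
        if abs(float(self.row_cosine @ self.col_cosine)) > 1e-6:
            raise ValueError("row_cosine and col_cosine must be orthogonal")
        if self.spacing_mm[0] <= 0 or self.spacing_mm[1] <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.thickness_mm < 0:
            raise ValueError("slice thickness must be non-negative")

    @property
    def plane_normal(self) -> np.ndarray:
        """Unit normal of the imaging plane."""
        n = np.cross(self.row_cosine, self.col_cosine)
        return n / np.linalg.norm(n)

    def to_sidecar(self, view: str) -> dict:
        return {
            "image_position_patient": [float(v) for v in self.origin_mm],
            "image_orientation_patient": [float(v) for v in self.row_cosine]
            + [float(v) for v in self.col_cosine],
            "pixel_spacing": [self.spacing_mm[0], self.spacing_mm[1]],
            "slice_thickness": float(self.thickness_mm),
            "view": view,
        }

    @classmethod
    def from_sidecar(cls, sidecar: dict) -> "PlaneGeometry":
        iop = sidecar["image_orientation_patient"]
        return cls(
            origin_mm=sidecar["image_position_patient"],
            row_cosine=iop[:3],
            col_cosine=iop[3:],
            spacing_mm=tuple(sidecar["pixel_spacing"]),
            thickness_mm=sidecar.get("slice_thickness", 0.0),
        )


@dataclass
class SegmentationMask:
    """A binary H x W label map plus the geometry of its imaging plane."""

    pixels: np.ndarray
    geometry: PlaneGeometry

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a 2D H x W array")
        vals = np.unique(px)
        if not np.all(np.isin(vals, (0, 1, 255))):
            raise ValueError("mask values must be in {0, 1} (or {0, 255})")
        self.pixels = (px > 0).astype(np.uint8)

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


@dataclass
class OrientedPointFragment:
    """Perimeter points (mm) of one view's mask with in-plane radial normals."""

    points_mm: np.ndarray
    normals: np.ndarray
    source_view: str = ""

    def __len__(self) -> int:
        return len(self.points_mm)


@dataclass
class CineSegmentation:
    """One view's 50-frame CINE of binary masks sharing a single plane."""

    frames: np.ndarray  # T x H x W, values {0,1}
    geometry: PlaneGeometry
    view: str = ""

    def __post_init__(self):
        fr = np.asarray(self.frames)
        if fr.ndim != 3:
            raise ValueError("frames must be T x H x W")
        self.frames = (fr > 0).astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def mask(self, t: int) -> SegmentationMask:
        return SegmentationMask(self.frames[t], self.geometry)


def pixel_to_patient(row, col, geom: PlaneGeometry) -> np.ndarray:
    """Map pixel indices to patient coordinates (mm).

    Accepts scalars or equal-length arrays of row/col indices; returns an
    Nx3 (or 3-vector) array of mm coordinates.
    """
    row = np.asarray(row)
    col = np.asarray(col)
    d_row, d_col = geom.spacing_mm
    pts = (
        geom.origin_mm
        + np.multiply.outer(col * d_col, geom.row_cosine)
        + np.multiply.outer(row * d_row, geom.col_cosine)
    )
    return pts


def extract_perimeter(mask: SegmentationMask, structure: np.ndarray | None = None) -> SegmentationMask:
    """Perimeter of a binary mask: the mask minus its binary erosion.

    The default structuring element is the 3x3 cross (4-connectivity), i.e.
    the erosion default of scikit-image / scipy.ndimage.
    """
    if structure is None:
        structure = CROSS
    px = mask.pixels.astype(bool)
    eroded = ndimage.binary_erosion(px, structure=structure)
    return SegmentationMask((px & ~eroded).astype(np.uint8), mask.geometry)


def fragment_from_mask(
    mask: SegmentationMask,
    structure: np.ndarray | None = None,
    subpixel_offset_px: float = 0.5,
) -> OrientedPointFragment:
    """Oriented perimeter point fragment of one view's mask.

    Points are the patient coordinates of the perimeter pixels.  Each
    normal is the unit vector from the 3D centroid of *all* segmented
    pixels (the mask's center of gravity) to the point; by construction it
    lies in the view plane.  Perimeter points coinciding with the centroid
    have no defined direction and are dropped with a warning.

    A binary mask contains the pixels whose centers fall inside the
    structure, so the centers of its perimeter pixels sit on average half
    a pixel inside the true contour; ``subpixel_offset_px`` (default 0.5)
    pushes each point outward along its normal by that fraction of the
    in-plane pixel size to remove the quantization bias.  Set it to 0 to
    use raw pixel centers.
    """
    if mask.n_pixels == 0:
        raise ValueError("cannot build a point fragment from an empty mask")
    rows, cols = np.nonzero(mask.pixels)
    centroid = pixel_to_patient(rows, cols, mask.geometry).mean(axis=0)

    perim = extract_perimeter(mask, structure)
    prow, pcol = np.nonzero(perim.pixels)
    points = pixel_to_patient(prow, pcol, mask.geometry)

    vec = points - centroid
    norms = np.linalg.norm(vec, axis=1)
    keep = norms > 1e-12
    if not np.all(keep):
        logger.warning(
            "dropping %d perimeter point(s) coincident with the mask centroid",
            int((~keep).sum()),
        )
    points = points[keep]
    normals = vec[keep] / norms[keep, None]
    if subpixel_offset_px:
        points = points + subpixel_offset_px * np.mean(mask.geometry.spacing_mm) * normals
    return OrientedPointFragment(points_mm=points, normals=normals, source_view="")


# ---------------------------------------------------------------------------
# External interfaces: geometry sidecars and mask stacks


def write_sidecar(path, geom: PlaneGeometry, view: str) -> None:
    Path(path).write_text(json.dumps(geom.to_sidecar(view), indent=1))


def read_sidecar(path) -> tuple[PlaneGeometry, str]:
    sidecar = json.loads(Path(path).read_text())
    return PlaneGeometry.from_sidecar(sidecar), sidecar.get("view", "")


def write_cine_nifti(path, cine: CineSegmentation) -> None:
    import nibabel as nib

    # stored H x W x T so each NIfTI "slice" is one frame
    data = np.moveaxis(cine.frames, 0, -1).astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))


def read_cine_nifti(path, geometry: PlaneGeometry, view: str = "") -> CineSegmentation:
    import nibabel as nib

    data = np.asarray(nib.load(str(path)).dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected an H x W x T volume")
    frames = np.moveaxis(data, -1, 0)
    return CineSegmentation(frames=frames, geometry=geometry, view=view)


def read_view_dir(view_dir) -> CineSegmentation:
    """Read one view: a NIfTI (masks.nii[.gz]) or PNG stack plus geometry.json."""
    view_dir = Path(view_dir)
    geom, view = read_sidecar(view_dir / "geometry.json")
    nii = list(view_dir.glob("masks.nii*"))
    if nii:
        return read_cine_nifti(nii[0], geom, view)
    pngs = sorted(view_dir.glob("frame_*.png"))
    if not pngs:
        raise FileNotFoundError(f"no masks.nii* or frame_*.png under {view_dir}")
    import imageio.v3 as iio

    frames = np.stack([np.asarray(iio.imread(p)) for p in pngs])
    if frames.ndim == 4:  # RGB(A) PNGs: any nonzero channel counts
        frames = frames.max(axis=-1)
    return CineSegmentation(frames=frames, geometry=geom, view=view)


def write_view_dir(view_dir, cine: CineSegmentation) -> None:
    view_dir = Path(view_dir)
    view_dir.mkdir(parents=True, exist_ok=True)
    write_sidecar(view_dir / "geometry.json", cine.geometry, cine.view)
    write_cine_nifti(view_dir / "masks.nii.gz", cine)
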