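"""Reading, writing and calibration of PET volumes and region label maps.

Volumes are held voxel-major in a fixed ``(x, y, z)`` axis order with
physical voxel spacing and origin in millimetres.  All segmentation
products live on the PET grid; no resampling between mismatched grids is
performed — callers must check alignment first (:func:`check_alignment`).

SUV here is body-weight SUV: tissue activity concentration (Bq/mL)
normalised by injected activity (Bq) per body weight (g), which makes it
dimensionless.  Images are assumed already decay-corrected to scan start
by the scanner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "AlignmentError",
    "CalibrationError",
    "FormatError",
    "GridRef",
    "PETVolume",
    "ROISet",
    "SUVCalibration",
    "SegmentationMask",
    "check_alignment",
    "load_labels",
    "load_volume",
    "save_labels",
    "save_mask",
    "save_volume",
    "to_suv",
]

AXIS_ORDER = "xyz"


class FormatError(ValueError):
    """An input file violates the expected NIfTI layout."""


class CalibrationError(ValueError):
    """Invalid SUV calibration (non-positive weight or activity)."""


class AlignmentError(ValueError):
    """Two grids that must coincide do not."""


@dataclass(frozen=True)
class GridRef:
    """Geometry of a voxel grid: shape, spacing (mm) and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise FormatError(f"grid must be 3D, got shape {self.shape}")
        if any(s < 1 for s in self.shape):
            raise FormatError(f"grid axes must have length >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class PETVolume:
    """3D scalar grid of body-weight SUV values.

    Attributes
    ----------
    values : ndarray, shape (nx, ny, nz)
        Finite, non-negative SUV values.
    spacing, origin : tuple of float
        Physical voxel size and position of voxel (0, 0, 0), in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = AXIS_ORDER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise FormatError(f"PET volume must be 3D, got {self.values.ndim}D")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("PET volume contains non-finite SUV values")
        if np.any(self.values < 0):
            raise FormatError("PET volume contains negative SUV values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        # triggers GridRef validation of spacing/shape
        self.grid

    @property
    def grid(self) -> GridRef:
        return GridRef(tuple(self.values.shape), self.spacing, self.origin)


@dataclass(frozen=True)
class SUVCalibration:
    """Injected activity (MBq, decay-corrected to scan start) and body weight (kg)."""

    injected_activity_mbq: float
    body_weight_kg: float

    def __post_init__(self) -> None:
        if not self.injected_activity_mbq > 0:
            raise CalibrationError(
                f"injected activity must be > 0 MBq, got {self.injected_activity_mbq}"
            )
        if not self.body_weight_kg > 0:
            raise CalibrationError(
                f"body weight must be > 0 kg, got {self.body_weight_kg}"
            )


@dataclass
class ROISet:
    """Observer-drawn lesion-enclosing regions as one integer label map.

    Label 0 is background; positive labels must be the gapless set
    ``{1..K}``, each with at least one voxel.  ROIs cannot overlap by
    construction of the label-map representation.
    """

    labels: np.ndarray
    reference: GridRef

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != tuple(self.reference.shape):
            raise AlignmentError(
                f"label map shape {self.labels.shape} does not match "
                f"reference shape {self.reference.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.array_equal(self.labels, np.round(self.labels)):
                raise FormatError("ROI labels must be integers")
            self.labels = self.labels.astype(np.int32)
        if self.labels.min() < 0:
            raise FormatError("ROI labels must be non-negative")
        present = np.unique(self.labels)
        positive = present[present > 0]
        expected = np.arange(1, positive.size + 1)
        if not np.array_equal(positive, expected):
            raise FormatError(
                f"positive ROI labels must be gapless 1..K, got {positive.tolist()}"
            )

    @property
    def roi_labels(self) -> list[int]:
        present = np.unique(self.labels)
        return [int(v) for v in present if v > 0]

    def roi_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class SegmentationMask:
    """Binary lesion mask plus its decomposition into per-ROI sub-masks."""

    mask: np.ndarray
    method_id: str
    reference: GridRef
    per_roi_masks: dict[int, np.ndarray] = field(default_factory=dict)
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.reference.shape):
            raise AlignmentError(
                f"mask shape {self.mask.shape} does not match reference "
                f"shape {self.reference.shape}"
            )

    @classmethod
    def from_per_roi(
        cls,
        per_roi: dict[int, np.ndarray],
        method_id: str,
        reference: GridRef,
        info: dict | None = None,
    ) -> "SegmentationMask":
        union = np.zeros(reference.shape, dtype=bool)
        for sub in per_roi.values():
            union |= sub
        return cls(union, method_id, reference, dict(per_roi), info or {})


def _affine(grid: GridRef) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_img(img: nib.Nifti1Image) -> GridRef:
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return GridRef(tuple(img.shape[:3]), tuple(float(z) for z in zooms),
                   tuple(float(o) for o in origin))


def load_volume(path) -> PETVolume:
    """Load a 3D scalar NIfTI image as a :class:`PETVolume`.

    Raises :class:`FormatError` for unreadable files, non-3D images or
    non-scalar voxels.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3D scalar image, got {data.ndim} dimensions"
        )
    if not np.issubdtype(data.dtype, np.number):
        raise FormatError(f"{path}: voxels are not scalar numbers ({data.dtype})")
    grid = _grid_from_img(img)
    return PETVolume(data.astype(np.float64), grid.spacing, grid.origin)


def save_volume(volume: PETVolume, path) -> None:
    """Write a volume as float32 NIfTI; spacing/origin go into the header."""
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.grid))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def save_mask(mask: SegmentationMask, path) -> None:
    """Write a binary mask as uint8 NIfTI on its reference grid."""
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.reference))
    img.header.set_zooms(mask.reference.spacing)
    nib.save(img, str(path))


def save_labels(rois: ROISet, path) -> None:
    """Write an ROI/lesion label map as uint16 NIfTI."""
    img = nib.Nifti1Image(rois.labels.astype(np.uint16), _affine(rois.reference))
    img.header.set_zooms(rois.reference.spacing)
    nib.save(img, str(path))


def load_labels(path) -> ROISet:
    """Load an integer label map NIfTI as an :class:`ROISet`."""
    vol = load_volume(path)
    labels = vol.values
    if not np.array_equal(labels, np.round(labels)):
        raise FormatError(f"{path}: label map contains non-integer values")
    return ROISet(labels.astype(np.int32), vol.grid)


def to_suv(activity_volume: PETVolume, calib: SUVCalibration) -> PETVolume:
    """Convert an activity-concentration volume (Bq/mL) to body-weight SUV.

    SUV(v) = activity(v) [Bq/mL] x body_weight [g] / injected_activity [Bq].
    Grid metadata is preserved.
    """
    weight_g = calib.body_weight_kg * 1e3
    injected_bq = calib.injected_activity_mbq * 1e6
    suv = activity_volume.values * (weight_g / injected_bq)
    return PETVolume(suv, activity_volume.spacing, activity_volume.origin)


def check_alignment(a, b, tol_mm: float = 1e-3) -> bool:
    """True iff two grids share shape and agree on spacing/origin within ``tol_mm``.

    Accepts :class:`PETVolume`, :class:`ROISet`, :class:`SegmentationMask`
    or bare :class:`GridRef` arguments; symmetric in its two arguments.
    """
    ga, gb = _as_grid(a), _as_grid(b)
    if ga.shape != gb.shape:
        return False
    return (
        np.allclose(ga.spacing, gb.spacing, rtol=0.0, atol=tol_mm)
        and np.allclose(ga.origin, gb.origin, rtol=0.0, atol=tol_mm)
    )


def require_alignment(a, b, tol_mm: float = 1e-3) -> None:
    if not check_alignment(a, b, tol_mm):
        raise AlignmentError(
            f"grids are not aligned: {_as_grid(a)} vs {_as_grid(b)}"
        )


def _as_grid(obj) -> GridRef:
    if isinstance(obj, GridRef):
        return obj
    if isinstance(obj, PETVolume):
        return obj.grid
    if isinstance(obj, (ROISet, SegmentationMask)):
        return obj.reference
    raise TypeError(f"cannot extract a grid from {type(obj).__name__}")
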