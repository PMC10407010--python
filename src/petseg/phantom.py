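"""Digital PET phantoms with known lesion ground truth.

A phantom is a uniform-background SUV volume carrying FDG-avid
ellipsoidal lesions, degraded by a Gaussian point-spread blur (the
partial-volume effect of clinical scanners, FWHM ≈ 7 mm for the
time-of-flight class emulated here) and additive Gaussian noise, which
is a standard desk-scale approximation of post-reconstruction PET noise.
Each ground-truth lesion is wrapped in an enclosing ROI (the ground
truth dilated by a margin), mimicking the observer instruction to draw a
region containing the whole lesion plus surrounding background.
Observer variability is simulated by randomly dilating/eroding each ROI.

Cohort defaults emulate the lesion statistics of a staging-lymphoma
population: SUVmax ≈ 4.5–10 over background 1.0 and MTV ≈ 1.3–10 cm^3.
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .segmentation import LesionSet, label_lesions
from .suv_io import GridRef, PETVolume, ROISet

__all__ = [
    "CohortRanges",
    "Lesion",
    "PhantomPatient",
    "PhantomSpec",
    "SpecError",
    "cohort",
    "generate",
    "perturb_roi",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class SpecError(ValueError):
    """Invalid phantom specification (e.g. lesion outside the grid)."""


@dataclass(frozen=True)
class Lesion:
    """One ellipsoidal lesion: centre (mm), per-axis radii (mm), uptake (SUV)."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    suv: float


@dataclass
class PhantomSpec:
    """Recipe for one phantom volume.

    ``psf_fwhm_mm`` = 0 disables blurring, ``noise_sd`` = 0 disables
    noise; ``roi_margin_voxels`` controls how far the enclosing ROIs
    extend beyond the ground-truth lesions.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_suv: float = 1.0
    lesions: list[Lesion] = field(default_factory=list)
    psf_fwhm_mm: float = 7.0
    noise_sd: float = 0.1
    seed: int = 0
    roi_margin_voxels: int = 3

    def __post_init__(self) -> None:
        if not self.background_suv >= 0:
            raise SpecError("background SUV must be >= 0")
        for les in self.lesions:
            if any(r <= 0 for r in les.radii_mm):
                raise SpecError(f"lesion radii must be positive: {les}")
            if les.suv <= self.background_suv:
                raise SpecError(
                    f"lesion SUV {les.suv} must exceed background "
                    f"{self.background_suv} (FDG-avid premise)"
                )


@dataclass
class PhantomPatient:
    """One simulated patient: volume, ground truth and two observer ROI sets."""

    patient_id: str
    volume: PETVolume
    ground_truth: LesionSet
    rois: ROISet
    observer_rois: dict[str, ROISet]
    spec: PhantomSpec


def _ellipsoid_mask(grid: GridRef, lesion: Lesion) -> np.ndarray:
    sp = np.asarray(grid.spacing, float)
    coords = [np.arange(n) * s for n, s in zip(grid.shape, sp)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = lesion.center_mm
    rx, ry, rz = lesion.radii_mm
    return (
        ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2
    ) <= 1.0


def generate(spec: PhantomSpec) -> tuple[PETVolume, LesionSet, ROISet]:
    """Render a phantom: SUV volume, ground-truth lesions and enclosing ROIs.

    Voxels inside any lesion ellipsoid take that lesion's SUV (later
    lesions overwrite earlier on overlap), the rest the background SUV;
    then Gaussian blur of the stated FWHM, then additive zero-mean
    Gaussian noise clipped at 0.  ROI k is ground-truth lesion k dilated
    by the spec margin; on overlap, earlier ROIs keep their voxels.
    """
    grid = GridRef(tuple(spec.shape), tuple(spec.spacing), (0.0, 0.0, 0.0))
    values = np.full(grid.shape, float(spec.background_suv))
    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
    gt_union = np.zeros(grid.shape, dtype=bool)
    roi_labels = np.zeros(grid.shape, dtype=np.int32)
    for idx, les in enumerate(spec.lesions, start=1):
        lo = np.asarray(les.center_mm) - np.asarray(les.radii_mm)
        hi = np.asarray(les.center_mm) + np.asarray(les.radii_mm)
        if np.any(lo < 0) or np.any(hi > extent):
            raise SpecError(f"lesion {idx} extends outside the grid: {les}")
        mask = _ellipsoid_mask(grid, les)
        if not mask.any():
            raise SpecError(f"lesion {idx} covers no voxel centre: {les}")
        values[mask] = les.suv
        gt_union |= mask
        roi = ndimage.binary_dilation(mask, iterations=spec.roi_margin_voxels)
        roi_labels[roi & (roi_labels == 0)] = idx

    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm * FWHM_TO_SIGMA / np.asarray(grid.spacing)
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=grid.shape)
        values = np.clip(values, 0.0, None)

    volume = PETVolume(values, grid.spacing, grid.origin)
    ground_truth = label_lesions(gt_union)
    rois = ROISet(roi_labels, grid)
    return volume, ground_truth, rois


_JITTER_STRUCTURES = [
    ndimage.generate_binary_structure(3, r) for r in (1, 2, 3)
]


def perturb_roi(rois: ROISet, magnitude: int, seed: int) -> ROISet:
    """Simulate an independent observer by jittering each enclosing ROI.

    Each ROI is independently dilated or eroded by a seeded random
    number of steps in [-magnitude, +magnitude], with a randomly chosen
    structuring element (6/18/26-neighbourhood jitter).  An erosion is
    never allowed to empty a ROI; overlaps with other ROIs keep the
    earlier label.  ``magnitude`` = 0 returns an identical ROISet.
    """
    if magnitude < 0:
        raise ValueError("perturbation magnitude must be >= 0")
    if magnitude == 0:
        return ROISet(rois.labels.copy(), rois.reference)
    rng = np.random.default_rng(seed)
    out = np.zeros_like(rois.labels)
    for lab in rois.roi_labels:
        mask = rois.labels == lab
        steps = int(rng.integers(-magnitude, magnitude + 1))
        structure = _JITTER_STRUCTURES[int(rng.integers(0, 3))]
        if steps > 0:
            mask = ndimage.binary_dilation(mask, structure, iterations=steps)
        elif steps < 0:
            for _ in range(-steps):
                smaller = ndimage.binary_erosion(mask, structure)
                if not smaller.any():
                    break
                mask = smaller
        out[mask & (out == 0)] = lab
    return ROISet(out, rois.reference)


@dataclass
class CohortRanges:
    """Per-patient sampling ranges for :func:`cohort` (uniform draws)."""

    n_lesions: tuple[int, int] = (1, 3)
    radius_mm: tuple[float, float] = (7.0, 13.0)
    lesion_suv: tuple[float, float] = (4.5, 10.0)
    background_suv: float = 1.0
    psf_fwhm_mm: float = 7.0
    noise_sd: float = 0.1
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    axis_ratio: tuple[float, float] = (0.8, 1.25)
    observer_magnitude: int = 1

    @classmethod
    def low_contrast(cls, **overrides) -> "CohortRanges":
        """Lesions at 1.5-2.4:1 over background, the regime where a
        41%-of-SUVmax cut-off falls at or below the background level
        (contrast <= 1/0.41) and relative thresholding degenerates."""
        overrides.setdefault("lesion_suv", (1.5, 2.4))
        return cls(**overrides)


def cohort(
    n_patients: int, ranges: CohortRanges | None = None, seed: int = 0
) -> list[PhantomPatient]:
    """Sample a reproducible cohort of phantom patients.

    Per patient: lesion count, per-axis radii and uptake drawn uniformly
    from the stated ranges; lesion centres placed by rejection sampling
    so that lesions (plus ROI margin) stay inside the grid and do not
    collide.  Each patient gets the exact ROIs plus two perturbed
    variants ("Obs1", "Obs2") emulating independent observers.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    ranges = ranges or CohortRanges()
    rng = np.random.default_rng(seed)
    extent = np.asarray(ranges.shape) * np.asarray(ranges.spacing)
    margin_mm = 3 * max(ranges.spacing) + 4.0
    patients = []
    for p in range(n_patients):
        n_les = int(rng.integers(ranges.n_lesions[0], ranges.n_lesions[1] + 1))
        lesions: list[Lesion] = []
        placed: list[tuple[np.ndarray, float]] = []
        for _ in range(n_les):
            for _attempt in range(200):
                base_r = rng.uniform(*ranges.radius_mm)
                radii = base_r * rng.uniform(*ranges.axis_ratio, size=3)
                suv = rng.uniform(*ranges.lesion_suv)
                lo = radii + margin_mm
                hi = extent - radii - margin_mm
                if np.any(hi <= lo):
                    continue
                center = rng.uniform(lo, hi)
                rmax = float(radii.max())
                if all(
                    np.linalg.norm(center - c) > r + rmax + 2 * margin_mm
                    for c, r in placed
                ):
                    placed.append((center, rmax))
                    lesions.append(Lesion(tuple(center), tuple(radii), float(suv)))
                    break
        spec = PhantomSpec(
            shape=ranges.shape, spacing=ranges.spacing,
            background_suv=ranges.background_suv, lesions=lesions,
            psf_fwhm_mm=ranges.psf_fwhm_mm, noise_sd=ranges.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        volume, gt, rois = generate(spec)
        observers = {
            "Obs1": perturb_roi(rois, ranges.observer_magnitude,
                                int(rng.integers(0, 2**31 - 1))),
            "Obs2": perturb_roi(rois, ranges.observer_magnitude,
                                int(rng.integers(0, 2**31 - 1))),
        }
        patients.append(PhantomPatient(
            patient_id=f"phantom_{p:03d}", volume=volume, ground_truth=gt,
            rois=rois, observer_rois=observers, spec=spec,
        ))
    return patients


def spec_to_dict(spec: PhantomSpec) -> dict:
    return asdict(spec)
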