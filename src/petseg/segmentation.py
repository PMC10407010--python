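"""Per-ROI semiautomatic lesion segmentation.

Six methods, all operating on voxel intensities inside an observer-drawn
enclosing ROI:

``abs25``
    absolute SUV threshold (default 2.5, the common lymphoma baseline-MTV
    cut-off);
``rel41``
    relative threshold at a fraction of the ROI's SUVmax (default 41%,
    the EANM recommendation for solid tumours);
``kmeans`` / ``bayes``
    2-class 1D k-means, or maximum-a-posteriori classification under an
    EM-fitted univariate Gaussian mixture, lesion = highest-mean class;
``sac-kmeans`` / ``sac-bayes``
    the self-adaptive configuration: fit 3 intensity classes, compute the
    contrast coefficient coef = (m3 - m1)/(m3 + m1) from the lowest- and
    highest-mean class means, then either merge the two lower classes
    into background (coef < 0.90), merge the two higher classes into the
    lesion (coef >= 0.94), or refit with 2 classes (otherwise).

Everything is deterministic: k-means centroids are initialised from
fixed percentiles of the ROI intensity distribution and the mixture EM
starts from that k-means solution, so repeated runs are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .suv_io import PETVolume, ROISet, SegmentationMask, require_alignment

__all__ = [
    "ClusterModel",
    "DegenerateInputError",
    "LesionSet",
    "SACDecision",
    "fit_gmm_map",
    "kmeans_1d",
    "label_lesions",
    "sac_coefficient",
    "sac_decide",
    "segment",
    "segment_clustering",
    "segment_sac",
    "segment_threshold_abs",
    "segment_threshold_rel",
]

logger = logging.getLogger(__name__)

SAC_THRESHOLDS = (0.90, 0.94)

METHOD_IDS = ("abs25", "rel41", "kmeans", "bayes", "sac-kmeans", "sac-bayes")


class DegenerateInputError(ValueError):
    """The intensity sample cannot support the requested number of classes."""


@dataclass
class ClusterModel:
    """Summary of a 1D intensity clustering; classes ordered by ascending mean.

    ``variances``/``weights`` are present for the Gaussian mixture only.
    ``assignment`` gives the 0-based class index of every input value.
    """

    k: int
    means: np.ndarray
    assignment: np.ndarray
    variances: np.ndarray | None = None
    weights: np.ndarray | None = None
    converged: bool = True
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.assignment = np.asarray(self.assignment, dtype=np.intp)
        if self.means.size != self.k:
            raise ValueError("means length must equal k")
        if np.any(np.diff(self.means) <= 0):
            raise ValueError("class means must be strictly ascending")
        if self.weights is not None:
            w = np.asarray(self.weights, float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("weights must be non-negative and sum to 1")


@dataclass(frozen=True)
class SACDecision:
    """Outcome of the empirical contrast rule on a 3-class fit."""

    coef: float
    branch: str  # merge_two_lower | merge_two_higher | two_classes
    thresholds: tuple[float, float] = SAC_THRESHOLDS


@dataclass
class LesionSet:
    """Connected-component decomposition of a binary segmentation.

    Component labels are 1..n ordered by descending voxel count; label 0
    is background.  ``components`` maps label -> voxel index tuple.
    """

    labels: np.ndarray
    components: dict[int, tuple[np.ndarray, ...]]
    connectivity: int

    @property
    def n_lesions(self) -> int:
        return len(self.components)

    def lesion_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _relabel_ascending(means: np.ndarray, assignment: np.ndarray):
    order = np.argsort(means, kind="stable")
    inverse = np.empty_like(order)
    inverse[order] = np.arange(order.size)
    return means[order], inverse[assignment], order


def kmeans_1d(values, k: int, max_iter: int = 300) -> ClusterModel:
    """Lloyd's k-means on 1D intensities with percentile initialisation.

    Initial centroid i (1-based) is the 100*(2i-1)/(2k) percentile of the
    sample (linear-interpolation percentiles), which spreads the starting
    centroids over the intensity distribution and avoids empty classes.
    Iterates until no assignment changes or ``max_iter`` sweeps.

    If two fitted class means coincide the duplicates are merged and the
    fit is retried with k-1 classes; fewer distinct values than classes
    raises :class:`DegenerateInputError`.
    """
    v = np.asarray(values, dtype=float).ravel()
    if k < 2:
        raise DegenerateInputError(f"need at least 2 classes, got k={k}")
    if v.size < k:
        raise DegenerateInputError(f"need >= {k} values, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise DegenerateInputError("intensity sample contains non-finite values")
    if np.unique(v).size < k:
        raise DegenerateInputError(
            f"only {np.unique(v).size} distinct values for k={k} classes"
        )

    q = 100.0 * (2 * np.arange(1, k + 1) - 1) / (2 * k)
    centers = np.percentile(v, q, method="linear").astype(float)

    assignment = None
    for _ in range(max_iter):
        # nearest centroid; ties go to the lower class index
        new_assignment = np.argmin(np.abs(v[:, None] - centers[None, :]), axis=1)
        if assignment is not None and np.array_equal(new_assignment, assignment):
            break
        assignment = new_assignment
        for j in range(k):
            members = v[assignment == j]
            if members.size:
                centers[j] = members.mean()

    means, assignment, _ = _relabel_ascending(centers, assignment)
    occupied = np.unique(assignment)
    if occupied.size < k or np.any(np.diff(means) <= 0):
        return _merge_duplicates_and_refit(v, k, kmeans_1d, max_iter=max_iter)
    return ClusterModel(k=k, means=means, assignment=assignment)


def _merge_duplicates_and_refit(v, k, fitter, **kwargs):
    if k - 1 < 2:
        raise DegenerateInputError(
            "clustering degenerated to a single class; ROI intensities are "
            "effectively uniform"
        )
    model = fitter(v, k - 1, **kwargs)
    model.warnings.append(f"duplicate class means: refitted with k={k - 1}")
    return model


def fit_gmm_map(
    values,
    k: int,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ClusterModel:
    """EM fit of a k-component univariate Gaussian mixture + MAP labels.

    Initialised deterministically from :func:`kmeans_1d` (means, class
    proportions, within-class variances), so no randomness enters the
    fit.  Convergence: mean log-likelihood gain per sample < ``tol``.
    Variances are floored at 1e-8 times the overall sample variance to
    survive point-mass classes (a warning is recorded when the floor
    engages).  Each value is assigned to the class with maximum posterior
    probability; classes are relabelled ascending by mean.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 5 * k:
        raise DegenerateInputError(
            f"Gaussian mixture with k={k} needs >= {5 * k} values, got {v.size}"
        )
    init = kmeans_1d(v, k)
    k = init.k  # may have shrunk on duplicate means
    means = init.means.copy()
    weights = np.array(
        [max(np.mean(init.assignment == j), 1e-10) for j in range(k)]
    )
    weights /= weights.sum()
    overall_var = float(np.var(v))
    var_floor = max(1e-8 * overall_var, 1e-300)
    variances = np.empty(k)
    for j in range(k):
        members = v[init.assignment == j]
        variances[j] = np.var(members) if members.size else overall_var
    warn: list[str] = []
    if np.any(variances < var_floor):
        warn.append("variance collapse at initialisation: floored")
    variances = np.maximum(variances, var_floor)

    prev_ll = -np.inf
    converged = False
    log_resp = None
    for _ in range(max_iter):
        # E step, in the log domain for numerical safety
        log_comp = (
            -0.5 * (v[:, None] - means[None, :]) ** 2 / variances[None, :]
            - 0.5 * np.log(2.0 * np.pi * variances[None, :])
            + np.log(weights[None, :])
        )
        log_norm = np.logaddexp.reduce(log_comp, axis=1)
        ll = float(np.mean(log_norm))
        log_resp = log_comp - log_norm[:, None]
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
        # M step
        resp = np.exp(log_resp)
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-10)
        weights = nk / nk.sum()
        means = (resp * v[:, None]).sum(axis=0) / nk
        variances = (resp * (v[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        if np.any(variances < var_floor):
            if not any("variance collapse" in w for w in warn):
                warn.append("variance collapse during EM: floored")
            variances = np.maximum(variances, var_floor)

    if not converged:
        warn.append(f"EM did not converge in {max_iter} iterations")

    assignment = np.argmax(log_resp, axis=1)
    order = np.argsort(means, kind="stable")
    if np.any(np.diff(means[order]) <= 0):
        model = _merge_duplicates_and_refit(v, k, fit_gmm_map, tol=tol,
                                            max_iter=max_iter)
        model.warnings.extend(warn)
        return model
    means_s, assignment_s, order = _relabel_ascending(means, assignment)
    for w in warn:
        logger.warning(w)
    return ClusterModel(
        k=k,
        means=means_s,
        assignment=assignment_s,
        variances=variances[order],
        weights=weights[order],
        converged=converged,
        warnings=warn,
    )


def sac_coefficient(model: ClusterModel) -> float:
    """Contrast coefficient coef = (m3 - m1)/(m3 + m1) of a 3-class fit.

    m1 and m3 are the lowest and highest class mean SUVs; with SUV >= 0
    the coefficient lies in [0, 1] (an asymmetry index of the ROI's
    intensity extremes).
    """
    if model.k != 3:
        raise ValueError(f"SAC coefficient requires a 3-class model, got k={model.k}")
    m1, m3 = float(model.means[0]), float(model.means[-1])
    if m1 + m3 == 0.0:
        raise DegenerateInputError("all-zero ROI: contrast coefficient undefined")
    return (m3 - m1) / (m3 + m1)


def sac_decide(coef: float, thresholds: tuple[float, float] = SAC_THRESHOLDS) -> SACDecision:
    """Apply the empirical contrast rule to a coefficient in [0, 1].

    coef < low  -> merge the two lower classes (border joins background);
    coef >= high -> merge the two higher classes (border joins lesion);
    otherwise   -> redo the segmentation with just 2 classes.
    """
    low, high = thresholds
    if not 0.0 <= low < high <= 1.0:
        raise ValueError(f"thresholds must satisfy 0 <= low < high <= 1, got {thresholds}")
    if not 0.0 <= coef <= 1.0:
        raise ValueError(f"contrast coefficient must be in [0, 1], got {coef}")
    if coef < low:
        branch = "merge_two_lower"
    elif coef >= high:
        branch = "merge_two_higher"
    else:
        branch = "two_classes"
    return SACDecision(coef=float(coef), branch=branch, thresholds=(low, high))


def _per_roi_loop(volume: PETVolume, rois: ROISet):
    require_alignment(volume, rois)
    for lab in rois.roi_labels:
        sel = rois.labels == lab
        yield lab, sel, volume.values[sel]


def segment_threshold_abs(
    volume: PETVolume, rois: ROISet, threshold: float = 2.5
) -> SegmentationMask:
    """Per-ROI absolute SUV threshold: keep voxels with SUV >= threshold."""
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    per_roi: dict[int, np.ndarray] = {}
    info: dict = {"threshold": threshold, "warnings": []}
    for lab, sel, vals in _per_roi_loop(volume, rois):
        sub = np.zeros(volume.values.shape, dtype=bool)
        sub[sel] = vals >= threshold
        if not sub.any():
            info["warnings"].append(f"ROI {lab}: empty mask at threshold {threshold}")
            logger.warning(info["warnings"][-1])
        per_roi[lab] = sub
    return SegmentationMask.from_per_roi(per_roi, "abs25", volume.grid, info)


def segment_threshold_rel(
    volume: PETVolume, rois: ROISet, fraction: float = 0.41
) -> SegmentationMask:
    """Per-ROI relative threshold at ``fraction`` of that ROI's SUVmax."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    per_roi: dict[int, np.ndarray] = {}
    info: dict = {"fraction": fraction, "per_roi_threshold": {}, "warnings": []}
    for lab, sel, vals in _per_roi_loop(volume, rois):
        cut = fraction * float(vals.max())
        info["per_roi_threshold"][lab] = cut
        sub = np.zeros(volume.values.shape, dtype=bool)
        sub[sel] = vals >= cut
        if not sub.any():  # only possible for an all-zero ROI
            info["warnings"].append(f"ROI {lab}: empty mask at cut-off {cut}")
            logger.warning(info["warnings"][-1])
        per_roi[lab] = sub
    return SegmentationMask.from_per_roi(per_roi, "rel41", volume.grid, info)


def _fit(base: str, vals: np.ndarray, k: int) -> ClusterModel:
    if base == "kmeans":
        return kmeans_1d(vals, k)
    if base in ("bayes", "bayesian"):
        return fit_gmm_map(vals, k)
    raise ValueError(f"unknown base fitter {base!r}; use 'kmeans' or 'bayes'")


def segment_clustering(
    volume: PETVolume, rois: ROISet, base: str = "kmeans", k: int = 2
) -> SegmentationMask:
    """Per-ROI k-class clustering; the lesion is the highest-mean class."""
    per_roi: dict[int, np.ndarray] = {}
    method_id = "kmeans" if base == "kmeans" else "bayes"
    info: dict = {"k": k, "warnings": []}
    for lab, sel, vals in _per_roi_loop(volume, rois):
        model = _fit(base, vals, k)
        sub = np.zeros(volume.values.shape, dtype=bool)
        sub[sel] = model.assignment == model.k - 1
        per_roi[lab] = sub
        info["warnings"].extend(f"ROI {lab}: {w}" for w in model.warnings)
    return SegmentationMask.from_per_roi(per_roi, method_id, volume.grid, info)


def segment_sac(
    volume: PETVolume,
    rois: ROISet,
    base: str = "bayes",
    thresholds: tuple[float, float] = SAC_THRESHOLDS,
    fallback_fraction: float = 0.41,
) -> SegmentationMask:
    """Self-adaptive-configuration segmentation, per ROI independently.

    Fits 3 intensity classes with the base method, computes the contrast
    coefficient and merges classes according to :func:`sac_decide`:

    - ``merge_two_lower``: classes 1+2 become background, lesion = class 3;
    - ``merge_two_higher``: classes 2+3 become the lesion (class 1 =
      background), i.e. the lesion border joins the lesion;
    - ``two_classes``: refit with k = 2, lesion = the upper class.

    A degenerate ROI (too few voxels or distinct intensities for the fit)
    falls back to the relative threshold at ``fallback_fraction`` for
    that ROI, with a logged warning.
    """
    per_roi: dict[int, np.ndarray] = {}
    method_id = "sac-kmeans" if base == "kmeans" else "sac-bayes"
    info: dict = {"thresholds": thresholds, "per_roi": {}, "warnings": []}
    for lab, sel, vals in _per_roi_loop(volume, rois):
        sub = np.zeros(volume.values.shape, dtype=bool)
        try:
            model = _fit(base, vals, 3)
            if model.k != 3:
                raise DegenerateInputError(
                    f"3-class fit collapsed to k={model.k}"
                )
            coef = sac_coefficient(model)
            decision = sac_decide(coef, thresholds)
            if decision.branch == "merge_two_lower":
                lesion = model.assignment == 2
            elif decision.branch == "merge_two_higher":
                lesion = model.assignment >= 1
            else:  # two_classes: rerun the base method with 2 classes
                model2 = _fit(base, vals, 2)
                lesion = model2.assignment == model2.k - 1
            sub[sel] = lesion
            info["per_roi"][lab] = {"coef": coef, "branch": decision.branch}
        except DegenerateInputError as exc:
            cut = fallback_fraction * float(vals.max()) if vals.size else 0.0
            sub[sel] = vals >= cut if vals.size else False
            msg = (
                f"ROI {lab}: degenerate for SAC ({exc}); fell back to "
                f"{fallback_fraction:.0%} relative threshold"
            )
            info["per_roi"][lab] = {"coef": None, "branch": "fallback_rel"}
            info["warnings"].append(msg)
            logger.warning(msg)
        per_roi[lab] = sub
    return SegmentationMask.from_per_roi(per_roi, method_id, volume.grid, info)


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def label_lesions(mask: SegmentationMask | np.ndarray, connectivity: int = 26) -> LesionSet:
    """Split a binary segmentation into disconnected lesions.

    Components are found under the given 3D neighbourhood convention
    (6 = faces, 18 = faces+edges, 26 = faces+edges+corners, the default)
    and relabelled 1..n by descending voxel count (ties keep scan order).
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    arr = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    raw, n = ndimage.label(arr, structure=structure)
    if n == 0:
        return LesionSet(np.zeros_like(raw), {}, connectivity)
    sizes = ndimage.sum_labels(np.ones_like(raw), raw, index=np.arange(1, n + 1))
    order = np.argsort(-sizes, kind="stable")  # descending size, stable ties
    remap = np.zeros(n + 1, dtype=raw.dtype)
    remap[1:][order] = np.arange(1, n + 1)
    labels = remap[raw]
    components = {
        int(j): np.nonzero(labels == j) for j in range(1, n + 1)
    }
    return LesionSet(labels, components, connectivity)


def segment(
    volume: PETVolume,
    rois: ROISet,
    method: str,
    threshold: float = 2.5,
    fraction: float = 0.41,
    sac_thresholds: tuple[float, float] = SAC_THRESHOLDS,
) -> SegmentationMask:
    """Dispatch one of the six named methods by its method id."""
    if method == "abs25":
        return segment_threshold_abs(volume, rois, threshold)
    if method == "rel41":
        return segment_threshold_rel(volume, rois, fraction)
    if method == "kmeans":
        return segment_clustering(volume, rois, "kmeans", 2)
    if method == "bayes":
        return segment_clustering(volume, rois, "bayes", 2)
    if method == "sac-kmeans":
        return segment_sac(volume, rois, "kmeans", sac_thresholds, fraction)
    if method == "sac-bayes":
        return segment_sac(volume, rois, "bayes", sac_thresholds, fraction)
    raise ValueError(f"unknown method {method!r}; choose from {METHOD_IDS}")
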