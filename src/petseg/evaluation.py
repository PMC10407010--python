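"""Agreement between segmentations (Dice) and between feature sets (ICC).

The Dice coefficient 2|A∩B|/(|A|+|B|) is computed on a patient basis,
i.e. on the union of all per-ROI lesion masks (total tumour burden).
Feature agreement uses the two-way random-effects, single-measure,
absolute-agreement intraclass correlation ICC(2,1), which penalises
systematic offsets between raters — the appropriate form when two
observers or methods are meant to report the *same* number.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import extract_features, select_representative
from .suv_io import AlignmentError, PETVolume, SegmentationMask

__all__ = [
    "AgreementReport",
    "agreement_suite",
    "dice",
    "dice_patient_basis",
    "icc_absolute",
    "summarize_dice",
]

AGREEMENT_FEATURES = ("suv_max", "suv_peak", "suv_mean", "mtv_cm3", "tlg_cm3")
SCOPES = ("total_burden", "highest_TLG", "highest_SUVmax")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient of two aligned binary masks.

    Two empty masks agree on absence and score 1.0 (with a warning);
    exactly one empty mask scores 0.
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise AlignmentError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("Dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def dice_patient_basis(seg_a: SegmentationMask, seg_b: SegmentationMask) -> float:
    """Dice between the unions of all per-ROI masks (total tumour burden)."""
    if seg_a.reference.shape != seg_b.reference.shape:
        raise AlignmentError("segmentations live on different grids")
    return dice(seg_a.mask, seg_b.mask)


def icc_absolute(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, single measure, absolute agreement.

    ``ratings`` is an n-targets x m-raters matrix with no missing cells,
    n >= 3 and m >= 2.  Computed from the two-way ANOVA decomposition:

        ICC = (MSR - MSE) / (MSR + (m-1) MSE + m (MSC - MSE) / n)

    with MSR the between-target, MSC the between-rater and MSE the
    residual mean squares.  A matrix with zero total variance has no
    defined ICC and returns NaN with a warning.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D targets x raters matrix")
    n, m = x.shape
    if n < 3 or m < 2:
        raise ValueError(f"need >= 3 targets and >= 2 raters, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings contain missing or non-finite cells")
    grand = x.mean()
    if np.allclose(x, grand):
        warnings.warn("zero total variance: ICC undefined", stacklevel=2)
        return float("nan")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = m * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (m - 1)
    mse = sse / ((n - 1) * (m - 1))
    return float((msr - mse) / (msr + (m - 1) * mse + m * (msc - mse) / n))


def summarize_dice(values) -> dict[str, float]:
    """Median / IQR / max / min summary of a collection of Dice values."""
    v = np.asarray(list(values), float)
    if v.size == 0:
        raise ValueError("no Dice values to summarize")
    q1, q3 = np.percentile(v, [25, 75])
    return {
        "median": float(np.median(v)),
        "iqr": float(q3 - q1),
        "maximum": float(v.max()),
        "minimum": float(v.min()),
    }


@dataclass
class AgreementReport:
    """Pairwise Dice and per-feature ICC between segmentation sources."""

    sources: list[str]
    dice_per_patient: pd.DataFrame  # columns: patient_id, source_a, source_b, dice
    dice_summary: dict[tuple[str, str], dict[str, float]]
    icc_per_feature: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: source_a, source_b, scope, feature, icc

    def to_dict(self) -> dict:
        return {
            "sources": self.sources,
            "dice_per_patient": self.dice_per_patient.to_dict(orient="records"),
            "dice_summary": {
                f"{a}|{b}": s for (a, b), s in self.dice_summary.items()
            },
            "icc_per_feature": self.icc_per_feature.to_dict(orient="records"),
        }


def agreement_suite(
    patients: list[dict],
    compute_icc: bool = True,
    connectivity: int = 26,
) -> AgreementReport:
    """All pairwise patient-basis Dice and per-feature ICC between sources.

    ``patients`` is a list of dicts, one per phantom/patient, with keys
    ``patient_id``, ``volume`` (:class:`PETVolume`) and ``masks``, a
    mapping source-name -> :class:`SegmentationMask`.  Every patient
    must provide the same set of >= 2 sources.

    ICC is reported per feature for the total tumour burden and for the
    representative lesion under both criteria (highest TLG, highest
    SUVmax); it needs >= 3 patients and is skipped otherwise.
    """
    if not patients:
        raise ValueError("no patients supplied")
    sources = sorted(patients[0]["masks"])
    if len(sources) < 2:
        raise ValueError("agreement needs >= 2 segmentation sources")
    pairs = list(itertools.combinations(sources, 2))

    dice_rows = []
    for patient in patients:
        masks = patient["masks"]
        if sorted(masks) != sources:
            raise ValueError("all patients must share the same sources")
        for a, b in pairs:
            dice_rows.append({
                "patient_id": patient["patient_id"],
                "source_a": a,
                "source_b": b,
                "dice": dice_patient_basis(masks[a], masks[b]),
            })
    dice_df = pd.DataFrame(dice_rows)
    summary = {
        (a, b): summarize_dice(
            dice_df.query("source_a == @a and source_b == @b")["dice"]
        )
        for a, b in pairs
    }

    icc_df = pd.DataFrame()
    if compute_icc and len(patients) >= 3:
        icc_df = _feature_icc(patients, sources, pairs, connectivity)
    return AgreementReport(sources, dice_df, summary, icc_df)


def _feature_icc(patients, sources, pairs, connectivity) -> pd.DataFrame:
    # per patient and source: burden row + representative-lesion rows
    values: dict[tuple[str, str, str], dict[str, float]] = {}
    for patient in patients:
        volume: PETVolume = patient["volume"]
        for src in sources:
            table = extract_features(
                volume, patient["masks"][src],
                patient_id=str(patient["patient_id"]),
                observer_id=src, connectivity=connectivity,
            )
            burden = table[table["scope"] == "total_burden"].iloc[0]
            values[(patient["patient_id"], src, "total_burden")] = burden
            for crit in ("highest_TLG", "highest_SUVmax"):
                rep = select_representative(table, crit)
                row = table[table["scope"] == rep].iloc[0]
                values[(patient["patient_id"], src, crit)] = row

    rows = []
    ids = [p["patient_id"] for p in patients]
    for a, b in pairs:
        for scope in SCOPES:
            for feat in AGREEMENT_FEATURES:
                matrix = np.array([
                    [values[(pid, a, scope)][feat], values[(pid, b, scope)][feat]]
                    for pid in ids
                ])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    icc = icc_absolute(matrix)
                rows.append({
                    "source_a": a, "source_b": b, "scope": scope,
                    "feature": feat, "icc": icc,
                })
    return pd.DataFrame(rows)
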