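"""Pixel-level evaluation: confusion counts, metrics, strata, thickness.

All bookkeeping is restricted to valid pixels inside the pathologically
evaluated area. Tumor is the positive class:

    specificity (%) = TN / (FP + TN) * 100
    sensitivity (%) = TP / (TP + FN) * 100
    accuracy    (%) = (TP + TN) / (TP + TN + FP + FN) * 100

Counts can be stratified by exposure: the ``exposed`` stratum covers tumor
pixels inside the yellow line, ``unexposed`` the tumor pixels between the
yellow and white lines. Those strata contain no negatives, so only
sensitivity is defined for them. Cohort summaries report the unweighted
mean +/- population standard deviation of per-specimen metric values
(pooled-count metrics are available separately); undefined metrics
propagate as missing and are excluded from means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .containers import (
    PRED_NORMAL,
    PRED_TUMOR,
    AnnotationMap,
    HSICube,
    Label,
    PredictionMap,
    UsageError,
    ValidityMask,
)

__all__ = [
    "ConfusionCounts",
    "MetricsRow",
    "CohortSummary",
    "DifferenceSpectrum",
    "ThicknessReport",
    "confusion_counts",
    "metrics",
    "region_sensitivity",
    "summarize_cohort",
    "pooled_metrics",
    "difference_spectrum",
    "thickness_analysis",
    "round_half_up",
]

STRATA = ("all", "exposed", "unexposed")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (report display rule)."""
    factor = 10.0**decimals
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/FP/TN pixel counts for one specimen and stratum."""

    tp: int
    fn: int
    fp: int
    tn: int
    specimen_id: str = ""
    stratum: str = "all"

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise UsageError("confusion counts must be non-negative")
        if self.stratum not in STRATA:
            raise UsageError(f"unknown stratum {self.stratum!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsRow:
    """Eq-style percentages for one specimen; None where undefined."""

    counts: ConfusionCounts
    specificity: Optional[float]
    sensitivity: Optional[float]
    accuracy: Optional[float]


@dataclass
class CohortSummary:
    """Unweighted per-specimen mean +/- population SD for each metric."""

    mean: Dict[str, Optional[float]]
    sd: Dict[str, Optional[float]]
    n_specimens: Dict[str, int]
    stratum: str = "all"


@dataclass
class DifferenceSpectrum:
    """Mean tumor-region SNV spectrum minus the training normal mean."""

    wavelengths: np.ndarray
    delta: Optional[np.ndarray]
    region: str
    specimen_id: str = ""

    @property
    def applicable(self) -> bool:
        return self.delta is not None


@dataclass
class ThicknessReport:
    """Tumor-thickness ranges over identified (TP) and missed (FN) pixels.

    ``rule`` records which ranges the >80%-sensitivity convention selects
    for histological measurement: ``identified_only`` above 80%, ``both``
    otherwise. Both ranges are always computed when the pixels exist.
    """

    specimen_id: str
    identified_range_mm: Optional[tuple]
    unidentified_range_mm: Optional[tuple]
    rule: str


def confusion_counts(
    pred: PredictionMap,
    annotation: AnnotationMap,
    mask: ValidityMask,
    stratum: str = "all",
) -> ConfusionCounts:
    """Tally TP/FN/FP/TN over valid pixels.

    ``all``: tumor (exposed + unexposed) vs normal. ``exposed`` /
    ``unexposed``: TP and FN within that tumor region only (no negatives by
    construction).
    """
    if stratum not in STRATA:
        raise UsageError(f"unknown stratum {stratum!r}")
    if pred.shape != annotation.shape or mask.shape != annotation.shape:
        raise UsageError("prediction, annotation and mask shapes differ")
    valid = mask.valid
    pred_tumor = pred.classes == PRED_TUMOR
    pred_normal = pred.classes == PRED_NORMAL
    if stratum == "all":
        tumor_true = annotation.tumor_mask & valid
        normal_true = (annotation.labels == Label.NORMAL) & valid
        return ConfusionCounts(
            tp=int(np.sum(tumor_true & pred_tumor)),
            fn=int(np.sum(tumor_true & pred_normal)),
            fp=int(np.sum(normal_true & pred_tumor)),
            tn=int(np.sum(normal_true & pred_normal)),
            specimen_id=pred.specimen_id,
            stratum=stratum,
        )
    label = Label.EXPOSED_TUMOR if stratum == "exposed" else Label.UNEXPOSED_TUMOR
    region = (annotation.labels == label) & valid
    return ConfusionCounts(
        tp=int(np.sum(region & pred_tumor)),
        fn=int(np.sum(region & pred_normal)),
        fp=0,
        tn=0,
        specimen_id=pred.specimen_id,
        stratum=stratum,
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def metrics(counts: ConfusionCounts) -> MetricsRow:
    """Specificity/sensitivity/accuracy percentages from counts.

    Zero-denominator metrics are reported as None (missing), never as 0.
    For exposure strata only sensitivity is meaningful; specificity and
    accuracy come out None because those strata hold no negatives.
    """
    sensitivity = _ratio(counts.tp, counts.tp + counts.fn)
    if counts.stratum == "all":
        specificity = _ratio(counts.tn, counts.fp + counts.tn)
        accuracy = _ratio(counts.tp + counts.tn, counts.total)
    else:
        specificity = None
        accuracy = None
    return MetricsRow(counts=counts, specificity=specificity,
                      sensitivity=sensitivity, accuracy=accuracy)


def region_sensitivity(
    counts_exposed: ConfusionCounts, counts_unexposed: ConfusionCounts
) -> Dict[str, Optional[float]]:
    """Per-region sensitivity; None for a region with no tumor pixels."""
    return {
        "exposed": _ratio(counts_exposed.tp, counts_exposed.tp + counts_exposed.fn),
        "unexposed": _ratio(counts_unexposed.tp, counts_unexposed.tp + counts_unexposed.fn),
    }


def summarize_cohort(rows: Sequence[MetricsRow], stratum: str = "all") -> CohortSummary:
    """Unweighted mean +/- population SD (ddof=0) of per-specimen metrics.

    Specimens where a metric is undefined are excluded from that metric's
    mean, matching how absent regions are reported as not applicable.
    """
    mean: Dict[str, Optional[float]] = {}
    sd: Dict[str, Optional[float]] = {}
    n: Dict[str, int] = {}
    for name in ("specificity", "sensitivity", "accuracy"):
        values = [getattr(r, name) for r in rows if getattr(r, name) is not None]
        n[name] = len(values)
        if values:
            arr = np.asarray(values, dtype=float)
            mean[name] = float(arr.mean())
            sd[name] = float(arr.std(ddof=0))
        else:
            mean[name] = None
            sd[name] = None
    return CohortSummary(mean=mean, sd=sd, n_specimens=n, stratum=stratum)


def pooled_metrics(rows: Sequence[MetricsRow]) -> MetricsRow:
    """Metrics on the summed counts (secondary view; differs from the
    per-specimen means whenever specimen sizes differ)."""
    if not rows:
        raise UsageError("no rows to pool")
    stratum = rows[0].counts.stratum
    total = ConfusionCounts(
        tp=sum(r.counts.tp for r in rows),
        fn=sum(r.counts.fn for r in rows),
        fp=sum(r.counts.fp for r in rows),
        tn=sum(r.counts.tn for r in rows),
        specimen_id="pooled",
        stratum=stratum,
    )
    return metrics(total)


def difference_spectrum(
    test_snv: HSICube,
    annotation: AnnotationMap,
    mask: ValidityMask,
    region: str,
    normal_training_mean: np.ndarray,
    specimen_id: str = "",
) -> DifferenceSpectrum:
    """Mean SNV spectrum of a tumor region minus the training normal mean.

    Visualises which bands drive the classification; computed on the
    trimmed analysis window. An absent region yields a not-applicable
    result (``delta=None``).
    """
    if region not in ("exposed", "unexposed"):
        raise UsageError(f"unknown region {region!r}")
    normal_training_mean = np.asarray(normal_training_mean, dtype=float)
    if len(normal_training_mean) != test_snv.n_bands:
        raise UsageError("normal mean length does not match cube bands")
    label = Label.EXPOSED_TUMOR if region == "exposed" else Label.UNEXPOSED_TUMOR
    pixels = (annotation.labels == label) & mask.valid
    if not np.any(pixels):
        return DifferenceSpectrum(wavelengths=test_snv.wavelengths, delta=None,
                                  region=region, specimen_id=specimen_id)
    region_mean = test_snv.data[pixels].mean(axis=0)
    return DifferenceSpectrum(
        wavelengths=test_snv.wavelengths,
        delta=region_mean - normal_training_mean,
        region=region,
        specimen_id=specimen_id,
    )


def thickness_analysis(
    pred: PredictionMap,
    annotation: AnnotationMap,
    mask: ValidityMask,
    row: MetricsRow,
) -> ThicknessReport:
    """(min, max) tumor thickness over identified (TP) and missed (FN) pixels.

    The >80%-sensitivity rule decides which ranges a histological reader
    would measure; both ranges are reported here whenever the pixel sets
    are non-empty, with the rule's selection recorded in ``rule``.
    """
    valid_tumor = annotation.tumor_mask & mask.valid
    tp = valid_tumor & (pred.classes == PRED_TUMOR)
    fn = valid_tumor & (pred.classes == PRED_NORMAL)

    def rng(sel):
        if not np.any(sel):
            return None
        vals = annotation.thickness_mm[sel]
        return (float(vals.min()), float(vals.max()))

    sens = row.sensitivity
    rule = "identified_only" if (sens is not None and sens > 80.0) else "both"
    return ThicknessReport(
        specimen_id=pred.specimen_id,
        identified_range_mm=rng(tp),
        unidentified_range_mm=rng(fn),
        rule=rule,
    )
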