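"""Confusion bookkeeping, metric formulas, strata, difference spectra,
thickness ranges."""

import numpy as np
import pytest

from nirhsi.containers import (
    PRED_NORMAL,
    PRED_NOT_EVALUATED,
    PRED_TUMOR,
    AnnotationMap,
    HSICube,
    Label,
    PredictionMap,
    ValidityMask,
)
from nirhsi.evaluate import (
    ConfusionCounts,
    confusion_counts,
    difference_spectrum,
    metrics,
    pooled_metrics,
    region_sensitivity,
    round_half_up,
    summarize_cohort,
    thickness_analysis,
)


def _toy_scene():
    """4x4 scene with hand-placed labels and predictions."""
    labels = np.array(
        [
            [Label.NORMAL, Label.NORMAL, Label.EXPOSED_TUMOR, Label.EXPOSED_TUMOR],
            [Label.NORMAL, Label.NECROSIS, Label.UNEXPOSED_TUMOR, Label.EXPOSED_TUMOR],
            [Label.NORMAL, Label.NORMAL, Label.UNEXPOSED_TUMOR, Label.OUTSIDE_EVALUATED],
            [Label.OUTSIDE_EVALUATED, Label.NORMAL, Label.NORMAL, Label.NORMAL],
        ],
        dtype=int,
    )
    thickness = np.where(np.isin(labels, [int(Label.EXPOSED_TUMOR), int(Label.UNEXPOSED_TUMOR)]), 2.0, 0.0)
    ann = AnnotationMap(labels=labels, thickness_mm=thickness)
    reason = np.zeros((4, 4), np.uint8)
    reason[labels == int(Label.OUTSIDE_EVALUATED)] = 5
    reason[labels == int(Label.NECROSIS)] = 3
    mask = ValidityMask(valid=reason == 0, exclusion_reason=reason)
    pred = np.full((4, 4), PRED_NOT_EVALUATED, np.uint8)
    pred[mask.valid] = PRED_NORMAL
    # predictions: both exposed in row 0 tumor, one unexposed missed, one
    # normal false positive
    pred[0, 2] = PRED_TUMOR
    pred[0, 3] = PRED_TUMOR
    pred[1, 2] = PRED_TUMOR
    pred[1, 3] = PRED_NORMAL   # exposed FN
    pred[2, 2] = PRED_NORMAL   # unexposed FN
    pred[0, 1] = PRED_TUMOR    # normal FP
    return ann, mask, PredictionMap(classes=pred, specimen_id="toy")


class TestConfusionCounts:
    def test_toy_counts_match_exhaustive_tally(self):
        ann, mask, pred = _toy_scene()
        # Oracle: per-pixel tally over the 16 cells.
        tp = fn = fp = tn = 0
        for r in range(4):
            for c in range(4):
                if not mask.valid[r, c]:
                    continue
                truth_tumor = ann.labels[r, c] in (int(Label.EXPOSED_TUMOR), int(Label.UNEXPOSED_TUMOR))
                predicted_tumor = pred.classes[r, c] == PRED_TUMOR
                if truth_tumor and predicted_tumor:
                    tp += 1
                elif truth_tumor:
                    fn += 1
                elif predicted_tumor:
                    fp += 1
                else:
                    tn += 1
        counts = confusion_counts(pred, ann, mask, "all")
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (tp, fn, fp, tn) == (3, 2, 1, 7)

    def test_strata_partition_the_tumor_counts(self):
        ann, mask, pred = _toy_scene()
        whole = confusion_counts(pred, ann, mask, "all")
        exp = confusion_counts(pred, ann, mask, "exposed")
        unx = confusion_counts(pred, ann, mask, "unexposed")
        assert exp.tp + unx.tp == whole.tp
        assert exp.fn + unx.fn == whole.fn
        assert exp.fp == exp.tn == unx.fp == unx.tn == 0

    def test_perfect_prediction(self):
        ann, mask, _ = _toy_scene()
        classes = np.full(ann.shape, PRED_NOT_EVALUATED, np.uint8)
        classes[mask.valid] = np.where(ann.tumor_mask, PRED_TUMOR, PRED_NORMAL)[mask.valid]
        counts = confusion_counts(PredictionMap(classes=classes), ann, mask)
        assert counts.fn == counts.fp == 0
        assert counts.total == mask.valid.sum()

    def test_absent_region_gives_zero_counts(self):
        ann, mask, pred = _toy_scene()
        no_unx = ann.labels.copy()
        no_unx[no_unx == int(Label.UNEXPOSED_TUMOR)] = int(Label.EXPOSED_TUMOR)
        ann2 = AnnotationMap(labels=no_unx, thickness_mm=ann.thickness_mm)
        counts = confusion_counts(pred, ann2, mask, "unexposed")
        assert counts.tp == counts.fn == 0
        assert metrics(counts).sensitivity is None


class TestMetrics:
    def test_formulas(self):
        row = metrics(ConfusionCounts(tp=40, fn=10, fp=20, tn=80))
        assert row.sensitivity == pytest.approx(80.0)
        assert row.specificity == pytest.approx(80.0)
        assert row.accuracy == pytest.approx(120 / 150 * 100)

    def test_zero_denominators_are_missing_not_zero(self):
        row = metrics(ConfusionCounts(tp=0, fn=0, fp=0, tn=5))
        assert row.specificity == pytest.approx(100.0)
        assert row.sensitivity is None

    def test_region_sensitivity(self):
        out = region_sensitivity(
            ConfusionCounts(10, 0, 0, 0, stratum="exposed"),
            ConfusionCounts(1, 3, 0, 0, stratum="unexposed"),
        )
        assert out["exposed"] == pytest.approx(100.0)
        assert out["unexposed"] == pytest.approx(25.0)


class TestSummaries:
    def test_single_row_sd_zero(self):
        s = summarize_cohort([metrics(ConfusionCounts(5, 5, 5, 5))])
        assert s.sd["sensitivity"] == 0.0
        assert s.n_specimens["sensitivity"] == 1

    def test_undefined_rows_excluded(self):
        rows = [
            metrics(ConfusionCounts(8, 2, 1, 9)),
            metrics(ConfusionCounts(0, 0, 2, 8)),  # sensitivity undefined
        ]
        s = summarize_cohort(rows)
        assert s.n_specimens["sensitivity"] == 1
        assert s.mean["sensitivity"] == pytest.approx(80.0)
        assert s.n_specimens["specificity"] == 2

    def test_pooled_differs_from_mean_for_unequal_sizes(self):
        rows = [
            metrics(ConfusionCounts(90, 10, 0, 0)),   # sens 90 on 100 px
            metrics(ConfusionCounts(1, 9, 0, 0)),     # sens 10 on 10 px
        ]
        assert summarize_cohort(rows).mean["sensitivity"] == pytest.approx(50.0)
        assert pooled_metrics(rows).sensitivity == pytest.approx(91 / 110 * 100)

    def test_round_half_up(self):
        assert round_half_up(74.75) == 74.8
        assert round_half_up(74.849) == 74.8
        assert round_half_up(25.65) == 25.7


class TestDifferenceSpectrum:
    def test_zero_when_region_equals_reference(self):
        wl = 1000.0 + 6.3 * np.arange(8)
        data = np.tile(np.linspace(-1, 1, 8), (3, 3, 1))
        cube = HSICube(data, wl, value_kind="snv")
        labels = np.full((3, 3), int(Label.EXPOSED_TUMOR))
        thick = np.ones((3, 3))
        ann = AnnotationMap(labels=labels, thickness_mm=thick)
        mask = ValidityMask(np.ones((3, 3), bool), np.zeros((3, 3), np.uint8))
        d = difference_spectrum(cube, ann, mask, "exposed", np.linspace(-1, 1, 8))
        np.testing.assert_allclose(d.delta, 0.0, atol=1e-12)

    def test_absent_region_not_applicable(self):
        wl = 1000.0 + 6.3 * np.arange(4)
        cube = HSICube(np.zeros((2, 2, 4)), wl, value_kind="snv")
        ann = AnnotationMap(labels=np.full((2, 2), int(Label.NORMAL)))
        mask = ValidityMask(np.ones((2, 2), bool), np.zeros((2, 2), np.uint8))
        d = difference_spectrum(cube, ann, mask, "unexposed", np.zeros(4))
        assert not d.applicable


class TestThickness:
    def test_three_pixel_toy(self):
        """Thicknesses 1, 3, 5 mm with the middle pixel missed: identified
        range (1, 5), unidentified range (3, 3)."""
        labels = np.full((1, 3), int(Label.EXPOSED_TUMOR))
        thick = np.array([[1.0, 3.0, 5.0]])
        ann = AnnotationMap(labels=labels, thickness_mm=thick)
        mask = ValidityMask(np.ones((1, 3), bool), np.zeros((1, 3), np.uint8))
        pred = PredictionMap(classes=np.array([[PRED_TUMOR, PRED_NORMAL, PRED_TUMOR]], dtype=np.uint8))
        row = metrics(confusion_counts(pred, ann, mask))
        report = thickness_analysis(pred, ann, mask, row)
        assert report.identified_range_mm == (1.0, 5.0)
        assert report.unidentified_range_mm == (3.0, 3.0)
        assert report.rule == "both"  # sensitivity 66.7 < 80

    def test_full_sensitivity_leaves_unidentified_empty(self):
        labels = np.full((1, 2), int(Label.EXPOSED_TUMOR))
        ann = AnnotationMap(labels=labels, thickness_mm=np.array([[2.0, 4.0]]))
        mask = ValidityMask(np.ones((1, 2), bool), np.zeros((1, 2), np.uint8))
        pred = PredictionMap(classes=np.full((1, 2), PRED_TUMOR, np.uint8))
        row = metrics(confusion_counts(pred, ann, mask))
        report = thickness_analysis(pred, ann, mask, row)
        assert report.unidentified_range_mm is None
        assert report.rule == "identified_only"
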