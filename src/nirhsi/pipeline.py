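"""End-to-end orchestration: simulate -> preprocess -> classify -> evaluate.

``run_all`` drives the whole analysis under a single config and master seed
and returns (and optionally writes) the report bundle: per-specimen metric
rows, exposure-stratified sensitivities, cohort summaries, difference
spectra and thickness reports. Re-running with an identical config is
bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as hsio
from .classify import LOOCVFold, PixelClassifier, run_loocv
from .containers import UsageError
from .evaluate import (
    CohortSummary,
    ConfusionCounts,
    DifferenceSpectrum,
    MetricsRow,
    ThicknessReport,
    confusion_counts,
    difference_spectrum,
    metrics,
    pooled_metrics,
    summarize_cohort,
    thickness_analysis,
)
from .preprocess import PreprocessedSpecimen, PreprocessParams, preprocess_specimen
from .synth import (
    SpecimenConfig,
    SyntheticSpecimen,
    make_probe_calibration,
    simulate_cohort,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_all",
    "preprocess_cohort",
    "evaluate_folds",
    "detection_transition",
]

log = logging.getLogger("nirhsi")


@dataclass
class PipelineConfig:
    """Configuration for one full pipeline run."""

    n_specimens: int = 10
    unexposed_fraction: float = 0.6
    specimen: SpecimenConfig = field(default_factory=SpecimenConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    n_per_class: int = 200
    C: float = 1.0
    seed: int = 0
    out_dir: Optional[str] = None
    write_predictions: bool = False


@dataclass
class SpecimenReport:
    """Per-specimen evaluation bundle."""

    specimen_id: str
    row: MetricsRow
    exposed: ConfusionCounts
    unexposed: ConfusionCounts
    exposed_sensitivity: Optional[float]
    unexposed_sensitivity: Optional[float]
    thickness: ThicknessReport
    differences: List[DifferenceSpectrum]


@dataclass
class PipelineResult:
    """Everything one run produces, in memory."""

    config: PipelineConfig
    specimens: List[str]
    folds: List[LOOCVFold]
    reports: List[SpecimenReport]
    summary: CohortSummary
    exposed_summary: CohortSummary
    unexposed_summary: CohortSummary
    pooled: MetricsRow

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            c = r.row.counts
            rows.append(
                {
                    "specimen": r.specimen_id,
                    "tp": c.tp, "fn": c.fn, "fp": c.fp, "tn": c.tn,
                    "specificity": r.row.specificity,
                    "sensitivity": r.row.sensitivity,
                    "accuracy": r.row.accuracy,
                    "exposed_sensitivity": r.exposed_sensitivity,
                    "unexposed_sensitivity": r.unexposed_sensitivity,
                }
            )
        return pd.DataFrame(rows)

    def thickness_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            t = r.thickness
            rows.append(
                {
                    "specimen": r.specimen_id,
                    "identified_min_mm": None if t.identified_range_mm is None else t.identified_range_mm[0],
                    "identified_max_mm": None if t.identified_range_mm is None else t.identified_range_mm[1],
                    "unidentified_min_mm": None if t.unidentified_range_mm is None else t.unidentified_range_mm[0],
                    "unidentified_max_mm": None if t.unidentified_range_mm is None else t.unidentified_range_mm[1],
                    "rule": t.rule,
                }
            )
        return pd.DataFrame(rows)


def preprocess_cohort(
    specimens: Sequence[SyntheticSpecimen], params: PreprocessParams
) -> List[PreprocessedSpecimen]:
    out = []
    for sp in specimens:
        try:
            pre = preprocess_specimen(sp.specimen_id, sp.calibration, sp.annotation, params)
        except UsageError as exc:
            raise UsageError(f"preprocess stage failed for {sp.specimen_id}: {exc}") from exc
        counts = pre.mask.reason_counts()
        log.info("preprocess %s: excluded %s", sp.specimen_id, counts)
        out.append(pre)
    return out


def evaluate_folds(
    folds: Sequence[LOOCVFold], cohort: Sequence[PreprocessedSpecimen]
) -> List[SpecimenReport]:
    by_id = {p.specimen_id: p for p in cohort}
    reports = []
    for fold in folds:
        pre = by_id[fold.specimen_id]
        counts_all = confusion_counts(fold.prediction, pre.annotation, pre.mask, "all")
        counts_exp = confusion_counts(fold.prediction, pre.annotation, pre.mask, "exposed")
        counts_unx = confusion_counts(fold.prediction, pre.annotation, pre.mask, "unexposed")
        row = metrics(counts_all)
        diffs = [
            difference_spectrum(pre.snv, pre.annotation, pre.mask, region,
                                fold.normal_training_mean, fold.specimen_id)
            for region in ("exposed", "unexposed")
        ]
        thick = thickness_analysis(fold.prediction, pre.annotation, pre.mask, row)
        exp_row = metrics(counts_exp)
        unx_row = metrics(counts_unx)
        log.info(
            "evaluate %s: sens=%s spec=%s sigma2=%.4g",
            fold.specimen_id, row.sensitivity, row.specificity, fold.model.sigma2,
        )
        reports.append(
            SpecimenReport(
                specimen_id=fold.specimen_id,
                row=row,
                exposed=counts_exp,
                unexposed=counts_unx,
                exposed_sensitivity=exp_row.sensitivity,
                unexposed_sensitivity=unx_row.sensitivity,
                thickness=thick,
                differences=diffs,
            )
        )
    return reports


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline on a synthetic cohort under one master seed."""
    log.info("simulate: n=%d seed=%d", config.n_specimens, config.seed)
    specimens = simulate_cohort(
        config.n_specimens,
        template=config.specimen,
        seed=config.seed,
        unexposed_fraction=config.unexposed_fraction,
    )
    cohort = preprocess_cohort(specimens, config.preprocess)
    try:
        folds = run_loocv(cohort, n_per_class=config.n_per_class, C=config.C, seed=config.seed)
    except UsageError as exc:
        raise UsageError(f"classify stage failed: {exc}") from exc
    reports = evaluate_folds(folds, cohort)

    rows = [r.row for r in reports]
    summary = summarize_cohort(rows, "all")
    exposed_rows = [metrics(r.exposed) for r in reports]
    unexposed_rows = [metrics(r.unexposed) for r in reports if r.unexposed.tp + r.unexposed.fn > 0]
    result = PipelineResult(
        config=config,
        specimens=[s.specimen_id for s in specimens],
        folds=list(folds),
        reports=reports,
        summary=summary,
        exposed_summary=summarize_cohort(exposed_rows, "exposed"),
        unexposed_summary=summarize_cohort(unexposed_rows, "unexposed"),
        pooled=pooled_metrics(rows),
    )
    if config.out_dir is not None:
        _write_bundle(result, specimens, cohort)
    return result


def _write_bundle(result, specimens, cohort) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.metrics_frame().to_csv(out / "metrics.csv", index=False)
    result.thickness_frame().to_csv(out / "thickness.csv", index=False)
    diff_rows = []
    for r in result.reports:
        for d in r.differences:
            if d.delta is None:
                continue
            for wl, delta in zip(d.wavelengths, d.delta):
                diff_rows.append(
                    {"specimen": r.specimen_id, "region": d.region,
                     "wavelength_nm": wl, "delta_snv": delta}
                )
    pd.DataFrame(diff_rows).to_csv(out / "difference_spectra.csv", index=False)
    summary = {
        "seed": result.config.seed,
        "n_specimens": len(result.specimens),
        "mean": result.summary.mean,
        "sd": result.summary.sd,
        "exposed_mean_sensitivity": result.exposed_summary.mean["sensitivity"],
        "unexposed_mean_sensitivity": result.unexposed_summary.mean["sensitivity"],
        "pooled": {
            "specificity": result.pooled.specificity,
            "sensitivity": result.pooled.sensitivity,
            "accuracy": result.pooled.accuracy,
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    if result.config.write_predictions:
        pred_dir = out / "predictions"
        pred_dir.mkdir(exist_ok=True)
        for fold in result.folds:
            hsio.write_prediction(fold.prediction, pred_dir / f"{fold.specimen_id}.npz")


def detection_transition(
    model: PixelClassifier,
    template: SpecimenConfig,
    params: PreprocessParams,
    t_grid: Optional[np.ndarray] = None,
) -> float:
    """Locate the generator's detection transition for a trained model.

    Sweeps noiseless single-pixel probes of increasing tumor thickness
    (exposed, no covering mucosa) through the preprocessing chain and the
    classifier, and returns the smallest probed thickness above which every
    thicker probe is called tumor. Returns ``inf`` if no probe is detected.
    """
    from .preprocess import (  # local import to avoid cycle at module load
        absorbance_from_reflectance,
        compute_reflectance,
        snv_transform,
        trim_wavelengths,
    )

    if t_grid is None:
        t_grid = np.arange(0.1, 6.01, 0.1)
    t_grid = np.asarray(t_grid, dtype=float)
    cal = make_probe_calibration(template, t_grid)
    refl = trim_wavelengths(compute_reflectance(cal, params.epsilon), params.keep_window)
    snv = snv_transform(absorbance_from_reflectance(refl, params.epsilon), params.snv_ddof)
    preds = model.predict(snv.data[0])
    if not preds[-1]:
        return float("inf")
    # Last thickness still missed; the transition is the next grid point.
    missed = np.nonzero(preds == 0)[0]
    if len(missed) == 0:
        return float(t_grid[0])
    return float(t_grid[missed[-1] + 1])
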