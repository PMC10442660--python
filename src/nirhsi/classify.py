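"""Pixel classification: balanced sampling, RBF-SVM, leave-one-specimen-out.

Each pixel's SNV spectrum is classified as tumor or normal by a two-class
soft-margin SVM with an RBF kernel

    K(xi, xj) = exp(-||xi - xj||^2 / sigma^2),

cost C = 1, and the kernel bandwidth set by the median heuristic: sigma^2 is
the median of all pairwise squared Euclidean distances among the training
spectra. Training pixels are drawn balanced — the same number per class per
specimen, uniformly at random without replacement among valid pixels — and
generalisation is assessed by leave-one-specimen-out cross-validation: each
specimen is predicted by a model trained only on the other specimens'
samples.

The underlying quadratic program is solved by scikit-learn's SVC; the
decision rule is sign-based with ties (decision value exactly 0) resolved
to normal, favouring specificity.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.svm import SVC

from .containers import (
    PRED_NORMAL,
    PRED_NOT_EVALUATED,
    PRED_TUMOR,
    AnnotationMap,
    HSICube,
    Label,
    PredictionMap,
    UsageError,
    ValidityMask,
)
from .preprocess import PreprocessedSpecimen

__all__ = [
    "TrainingSet",
    "PixelClassifier",
    "LOOCVFold",
    "sample_training_pixels",
    "median_heuristic_sigma2",
    "rbf_kernel",
    "train_classifier",
    "predict_map",
    "run_loocv",
]

LABEL_NORMAL = 0
LABEL_TUMOR = 1


@dataclass
class TrainingSet:
    """Balanced training spectra with per-row provenance.

    ``labels`` uses 0 = normal, 1 = tumor. ``provenance`` records
    (specimen_id, (row, col)) per training row so fold isolation can be
    audited structurally.
    """

    spectra: np.ndarray
    labels: np.ndarray
    provenance: List[tuple]
    seed: int = 0

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.spectra.ndim != 2 or len(self.labels) != len(self.spectra):
            raise UsageError("spectra must be 2-D with one label per row")
        if len(self.provenance) != len(self.spectra):
            raise UsageError("one provenance entry per row required")
        if len(set(self.provenance)) != len(self.provenance):
            raise UsageError("duplicate (specimen, coordinate) training rows")

    def __len__(self) -> int:
        return len(self.spectra)

    @staticmethod
    def concatenate(parts: Sequence["TrainingSet"]) -> "TrainingSet":
        return TrainingSet(
            spectra=np.vstack([p.spectra for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            provenance=[pv for p in parts for pv in p.provenance],
            seed=parts[0].seed if parts else 0,
        )


def sample_training_pixels(
    snv: HSICube,
    annotation: AnnotationMap,
    mask: ValidityMask,
    n_per_class: int = 200,
    seed: int = 0,
    specimen_id: str = "",
) -> TrainingSet:
    """Draw ``n_per_class`` valid pixels per class, without replacement.

    The tumor class pools exposed and unexposed tumor pixels. Sampling is
    uniform among valid pixels and deterministic under ``seed``.
    """
    if snv.data.shape[:2] != annotation.shape or mask.shape != annotation.shape:
        raise UsageError("cube, annotation and mask shapes differ")
    pools = {
        LABEL_NORMAL: np.argwhere(mask.valid & (annotation.labels == Label.NORMAL)),
        LABEL_TUMOR: np.argwhere(mask.valid & annotation.tumor_mask),
    }
    names = {LABEL_NORMAL: "normal", LABEL_TUMOR: "tumor"}
    for cls, pool in pools.items():
        if len(pool) < n_per_class:
            raise UsageError(
                f"specimen {specimen_id or '?'}: class {names[cls]} has only "
                f"{len(pool)} valid pixels, {n_per_class} requested"
            )
    rng = np.random.default_rng(seed)
    rows, labels, provenance = [], [], []
    for cls in (LABEL_NORMAL, LABEL_TUMOR):
        pool = pools[cls]
        pick = rng.choice(len(pool), size=n_per_class, replace=False)
        for r, c in pool[pick]:
            rows.append(snv.data[r, c, :])
            labels.append(cls)
            provenance.append((specimen_id, (int(r), int(c))))
    return TrainingSet(spectra=np.array(rows), labels=np.array(labels),
                       provenance=provenance, seed=seed)


def median_heuristic_sigma2(spectra: np.ndarray) -> float:
    """Median of all pairwise squared Euclidean distances (i < j)."""
    spectra = np.asarray(spectra, dtype=np.float64)
    if spectra.ndim != 2 or len(spectra) < 2:
        raise UsageError("need at least 2 rows for the median heuristic")
    d2 = pdist(spectra, metric="sqeuclidean")
    sigma2 = float(np.median(d2))
    if sigma2 <= 0:
        raise UsageError("degenerate bandwidth: median pairwise distance is 0")
    return sigma2


def rbf_kernel(xi: np.ndarray, xj: np.ndarray, sigma2: float) -> float:
    """exp(-||xi - xj||^2 / sigma2); symmetric, in (0, 1]."""
    if sigma2 <= 0:
        raise UsageError("sigma2 must be positive")
    diff = np.asarray(xi, dtype=float) - np.asarray(xj, dtype=float)
    return float(np.exp(-np.dot(diff, diff) / sigma2))


@dataclass
class PixelClassifier:
    """Trained two-class RBF-SVM over SNV spectra (tumor = positive class)."""

    svc: SVC
    sigma2: float
    C: float
    n_bands: int
    n_train: int

    def decision_values(self, spectra: np.ndarray) -> np.ndarray:
        """Signed decision values; positive favours tumor."""
        spectra = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
        if spectra.shape[1] != self.n_bands:
            raise UsageError(
                f"spectra have {spectra.shape[1]} bands, model expects {self.n_bands}"
            )
        return self.svc.decision_function(spectra)

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        """0 = normal, 1 = tumor; a decision value of exactly 0 -> normal."""
        return (self.decision_values(spectra) > 0).astype(int)


def train_classifier(ts: TrainingSet, C: float = 1.0) -> PixelClassifier:
    """Fit the soft-margin RBF-SVM with median-heuristic bandwidth.

    The bandwidth sigma^2 is computed on the training spectra themselves
    (exact median over all pairs). C defaults to 1.
    """
    classes = np.unique(ts.labels)
    if len(classes) < 2:
        raise UsageError("training set contains a single class")
    sigma2 = median_heuristic_sigma2(ts.spectra)
    svc = SVC(C=C, kernel="rbf", gamma=1.0 / sigma2, tol=1e-6, cache_size=500)
    svc.fit(ts.spectra, ts.labels)
    return PixelClassifier(svc=svc, sigma2=sigma2, C=C,
                           n_bands=ts.spectra.shape[1], n_train=len(ts))


def predict_map(
    model: PixelClassifier,
    snv: HSICube,
    mask: ValidityMask,
    specimen_id: str = "",
    provenance: Optional[dict] = None,
) -> PredictionMap:
    """Classify every valid pixel; excluded pixels become not_evaluated."""
    if snv.data.shape[:2] != mask.shape:
        raise UsageError("cube and mask shapes differ")
    if snv.n_bands != model.n_bands:
        raise UsageError(f"cube has {snv.n_bands} bands, model expects {model.n_bands}")
    classes = np.full(mask.shape, PRED_NOT_EVALUATED, dtype=np.uint8)
    coords = np.argwhere(mask.valid)
    if len(coords):
        spectra = snv.data[coords[:, 0], coords[:, 1], :]
        pred = model.predict(spectra)
        classes[coords[:, 0], coords[:, 1]] = np.where(pred == 1, PRED_TUMOR, PRED_NORMAL)
    prov = dict(provenance or {})
    prov.setdefault("sigma2", model.sigma2)
    prov.setdefault("C", model.C)
    prov.setdefault("n_train", model.n_train)
    return PredictionMap(classes=classes, specimen_id=specimen_id, provenance=prov)


@dataclass
class LOOCVFold:
    """Result of one leave-one-specimen-out fold."""

    specimen_id: str
    prediction: PredictionMap
    model: PixelClassifier
    training: TrainingSet
    normal_training_mean: np.ndarray = field(default=None)


def _specimen_seed(master_seed: int, specimen_id: str) -> int:
    """Per-specimen sampling seed: deterministic and order-invariant."""
    return (zlib.crc32(specimen_id.encode()) ^ (master_seed & 0x7FFFFFFF)) % 2**31


def run_loocv(
    cohort: Sequence[PreprocessedSpecimen],
    n_per_class: int = 200,
    C: float = 1.0,
    seed: int = 0,
) -> List[LOOCVFold]:
    """Leave-one-specimen-out cross-validation over a preprocessed cohort.

    For each specimen, the model is trained on the pooled balanced samples
    of all *other* specimens (kernel bandwidth recomputed per fold on that
    fold's training matrix) and predicts every valid pixel of the held-out
    specimen. With 10 specimens and 200 px/class each fold trains on 3600
    spectra. Sampling seeds derive from the master seed and the specimen id,
    so maps do not depend on cohort ordering.
    """
    if len(cohort) < 2:
        raise UsageError("LOOCV needs at least 2 specimens")
    ids = [s.specimen_id for s in cohort]
    if len(set(ids)) != len(ids):
        raise UsageError("specimen ids must be unique")
    samples = {}
    for s in cohort:
        try:
            samples[s.specimen_id] = sample_training_pixels(
                s.snv, s.annotation, s.mask, n_per_class=n_per_class,
                seed=_specimen_seed(seed, s.specimen_id), specimen_id=s.specimen_id,
            )
        except UsageError as exc:
            raise UsageError(f"sampling failed for specimen {s.specimen_id}: {exc}") from exc

    folds = []
    for s in cohort:
        train = TrainingSet.concatenate(
            [samples[other] for other in ids if other != s.specimen_id]
        )
        model = train_classifier(train, C=C)
        prediction = predict_map(
            model, s.snv, s.mask, specimen_id=s.specimen_id,
            provenance={"fold": s.specimen_id, "seed": seed, "n_per_class": n_per_class},
        )
        normal_mean = train.spectra[train.labels == LABEL_NORMAL].mean(axis=0)
        folds.append(
            LOOCVFold(
                specimen_id=s.specimen_id,
                prediction=prediction,
                model=model,
                training=train,
                normal_training_mean=normal_mean,
            )
        )
    return folds
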