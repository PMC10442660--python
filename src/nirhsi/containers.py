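"""In-memory containers for hyperspectral cubes, annotations and masks.

A hyperspectral cube is a (rows, cols, bands) array with one wavelength per
band. The annotation raster carries the pathologist-style ground truth:
per-pixel tissue category, the tumor-extent boundary ("white line"), the
exposed/unexposed borderline ("yellow line"), and a per-pixel tumor
thickness map in millimetres.

Conventions shared by every module: row-major 0-based (row, col) indexing,
band axis last, wavelengths in nanometres and strictly increasing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Label",
    "Reason",
    "PRED_NORMAL",
    "PRED_TUMOR",
    "PRED_NOT_EVALUATED",
    "FormatError",
    "UsageError",
    "HSICube",
    "CalibrationSet",
    "AnnotationMap",
    "ValidityMask",
    "PredictionMap",
]


class FormatError(ValueError):
    """A file or array does not conform to the expected on-disk format."""


class UsageError(ValueError):
    """An operation was called with arguments that violate its contract."""


class Label(enum.IntEnum):
    """Per-pixel tissue category of the annotation raster."""

    OUTSIDE_EVALUATED = 0
    NORMAL = 1
    EXPOSED_TUMOR = 2
    UNEXPOSED_TUMOR = 3
    NECROSIS = 4


TUMOR_LABELS = (Label.EXPOSED_TUMOR, Label.UNEXPOSED_TUMOR)


class Reason(enum.IntEnum):
    """Why a pixel was excluded from analysis (0 = not excluded)."""

    NONE = 0
    HIGHLIGHT = 1
    SHADOW = 2
    NECROSIS = 3
    BOUNDARY_MARGIN = 4
    OUTSIDE_EVALUATED = 5


# Prediction raster codes.
PRED_NORMAL = 0
PRED_TUMOR = 1
PRED_NOT_EVALUATED = 255

VALUE_KINDS = ("raw", "reflectance", "absorbance", "snv")


@dataclass
class HSICube:
    """A hyperspectral data cube: one spectrum per spatial pixel.

    Parameters
    ----------
    data:
        Array of shape (rows, cols, bands). Raw cubes hold sensor counts
        (non-negative); derived cubes hold reflectance, absorbance or
        SNV-normalised values.
    wavelengths:
        Band-centre wavelengths in nm, strictly increasing, one per band.
    value_kind:
        One of ``raw``, ``reflectance``, ``absorbance``, ``snv``.
    bit_depth:
        Sensor depth metadata (e.g. 14); informational only.
    invalid_pixels:
        Optional (rows, cols) boolean raster marking pixels where a derived
        value is undefined (zero calibration span, constant spectrum, ...).
        Carried forward so downstream masking can record the exclusion
        instead of propagating non-finite values.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    value_kind: str = "raw"
    bit_depth: Optional[int] = None
    invalid_pixels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise FormatError(
                f"{len(self.wavelengths)} wavelengths for {self.data.shape[2]} bands"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise FormatError("wavelengths must be strictly increasing")
        if self.value_kind not in VALUE_KINDS:
            raise FormatError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind == "raw" and self.data.size and self.data.min() < 0:
            raise FormatError("raw cube contains negative intensities")
        if self.invalid_pixels is not None:
            self.invalid_pixels = np.asarray(self.invalid_pixels, dtype=bool)
            if self.invalid_pixels.shape != self.data.shape[:2]:
                raise FormatError("invalid_pixels shape does not match cube")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band nearest ``wavelength_nm`` (ties -> lower band)."""
        # argmin returns the first minimum; wavelengths increase, so a tie
        # resolves to the lower wavelength as required.
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass
class CalibrationSet:
    """Raw specimen frame plus white-standard and dark-noise frames."""

    raw: HSICube
    white: HSICube
    dark: HSICube

    def __post_init__(self) -> None:
        for name, cube in (("white", self.white), ("dark", self.dark)):
            if cube.data.shape != self.raw.data.shape:
                raise FormatError(f"{name} cube shape differs from raw cube")
            if not np.array_equal(cube.wavelengths, self.raw.wavelengths):
                raise FormatError(f"{name} cube wavelengths differ from raw cube")

    @property
    def shape(self) -> tuple:
        return self.raw.data.shape

    @property
    def wavelengths(self) -> np.ndarray:
        return self.raw.wavelengths


@dataclass
class AnnotationMap:
    """Ground-truth raster for one specimen.

    ``labels`` uses the :class:`Label` vocabulary. ``tumor_boundary`` is the
    white line (extent of the tumor) and ``exposure_boundary`` the yellow
    line (border between exposed and unexposed tumor), both as (n, 2) arrays
    of (row, col) pixel coordinates. ``thickness_mm`` is the histological
    tumor thickness, strictly positive exactly on tumor-labelled pixels.
    """

    labels: np.ndarray
    tumor_boundary: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    exposure_boundary: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    thickness_mm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("labels raster must be 2-D")
        valid_codes = {int(l) for l in Label}
        present = set(np.unique(self.labels).tolist())
        unknown = present - valid_codes
        if unknown:
            raise FormatError(f"unknown label codes {sorted(unknown)}")
        self.tumor_boundary = np.asarray(self.tumor_boundary, dtype=int).reshape(-1, 2)
        self.exposure_boundary = np.asarray(self.exposure_boundary, dtype=int).reshape(-1, 2)
        if self.thickness_mm is None:
            self.thickness_mm = np.zeros(self.labels.shape, dtype=float)
        self.thickness_mm = np.asarray(self.thickness_mm, dtype=float)
        if self.thickness_mm.shape != self.labels.shape:
            raise FormatError("thickness raster shape does not match labels")
        tumor = self.tumor_mask
        if np.any(self.thickness_mm[tumor] <= 0):
            raise FormatError("tumor-labelled pixel with non-positive thickness")
        if np.any(self.thickness_mm[~tumor] != 0):
            raise FormatError("non-tumor pixel with non-zero thickness")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def evaluated_mask(self) -> np.ndarray:
        return self.labels != Label.OUTSIDE_EVALUATED

    @property
    def tumor_mask(self) -> np.ndarray:
        return np.isin(self.labels, TUMOR_LABELS)


@dataclass
class ValidityMask:
    """Boolean validity raster with a per-pixel exclusion reason."""

    valid: np.ndarray
    exclusion_reason: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        self.exclusion_reason = np.asarray(self.exclusion_reason, dtype=np.uint8)
        if self.valid.shape != self.exclusion_reason.shape:
            raise FormatError("mask rasters have mismatched shapes")
        if np.any(self.exclusion_reason[self.valid] != Reason.NONE):
            raise FormatError("valid pixel carries an exclusion reason")
        if np.any(self.exclusion_reason[~self.valid] == Reason.NONE):
            raise FormatError("excluded pixel lacks an exclusion reason")

    @property
    def shape(self) -> tuple:
        return self.valid.shape

    def reason_counts(self) -> dict:
        """Number of excluded pixels per reason (for stage logging)."""
        out = {}
        for reason in Reason:
            if reason is Reason.NONE:
                continue
            out[reason.name.lower()] = int(np.sum(self.exclusion_reason == reason))
        return out


@dataclass
class PredictionMap:
    """Per-pixel predicted class for one specimen.

    ``classes`` holds 0 (normal), 1 (tumor) or 255 (not evaluated); 255
    appears exactly on pixels the validity mask excluded.
    """

    classes: np.ndarray
    specimen_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        if self.classes.ndim != 2:
            raise FormatError("prediction raster must be 2-D")
        allowed = {PRED_NORMAL, PRED_TUMOR, PRED_NOT_EVALUATED}
        present = set(np.unique(self.classes).tolist())
        if present - allowed:
            raise FormatError(f"unknown prediction codes {sorted(present - allowed)}")

    @property
    def shape(self) -> tuple:
        return self.classes.shape
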