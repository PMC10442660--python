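"""Calibration, SNV normalisation, wavelength trimming and validity masking.

The raw sensor frames are converted to reflectance against the white
standard and dark noise,

    R = (Ir - Id) / (Iw - Id),

then to absorbance A = -log10(R), trimmed to the analysis window (bands
above 1400 nm are dominated by water absorption and low detector
sensitivity), and each pixel's spectrum is normalised to zero mean and unit
standard deviation (standard normal variate, SNV) to remove baseline and
scatter variation. A per-pixel validity mask excludes specular highlights
(reflectance above 70% at the 1300 nm reference band), shadows (below 10%),
necrosis, a safety margin around the freehand boundary lines, and pixels
outside the pathologically evaluated area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import (
    AnnotationMap,
    CalibrationSet,
    HSICube,
    Label,
    Reason,
    UsageError,
    ValidityMask,
)

__all__ = [
    "PreprocessParams",
    "compute_reflectance",
    "compute_absorbance",
    "absorbance_from_reflectance",
    "snv_transform",
    "trim_wavelengths",
    "build_validity_mask",
    "PreprocessedSpecimen",
    "preprocess_specimen",
]


@dataclass
class PreprocessParams:
    """Tunable preprocessing thresholds.

    Defaults follow the standard protocol for this assay: analysis window
    1000-1400 nm, highlight/shadow cut-offs 70%/10% reflectance at the band
    nearest 1300 nm, and a 5-pixel exclusion margin around boundary lines.
    """

    keep_window: tuple = (1000.0, 1400.0)
    highlight_threshold: float = 0.70
    shadow_threshold: float = 0.10
    reference_wavelength: float = 1300.0
    margin_px: int = 5
    epsilon: float = 1e-9
    snv_ddof: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.shadow_threshold < self.highlight_threshold <= 1.0):
            raise UsageError("need 0 <= shadow < highlight <= 1")
        if self.margin_px < 0:
            raise UsageError("margin_px must be >= 0")
        if self.epsilon <= 0:
            raise UsageError("epsilon must be positive")


def compute_reflectance(cal: CalibrationSet, epsilon: float = 1e-9) -> HSICube:
    """Per-pixel, per-band reflectance (Ir - Id) / (Iw - Id).

    Pixels whose calibration span Iw - Id is not positive in some band are
    flagged on ``invalid_pixels`` (downstream reason: shadow) instead of
    producing non-finite values; their reflectance is set to 0.
    """
    raw = cal.raw.data.astype(np.float64)
    white = cal.white.data.astype(np.float64)
    dark = cal.dark.data.astype(np.float64)
    span = white - dark
    bad = np.any(span <= epsilon, axis=2)
    refl = np.zeros_like(raw)
    ok = ~bad
    refl[ok] = (raw[ok] - dark[ok]) / span[ok]
    return HSICube(
        data=refl,
        wavelengths=cal.wavelengths,
        value_kind="reflectance",
        bit_depth=cal.raw.bit_depth,
        invalid_pixels=bad,
    )


def absorbance_from_reflectance(reflectance: HSICube, epsilon: float = 1e-9) -> HSICube:
    """A = -log10(max(R, epsilon)); epsilon guards non-positive reflectance."""
    if reflectance.value_kind != "reflectance":
        raise UsageError(f"expected a reflectance cube, got {reflectance.value_kind!r}")
    absorb = -np.log10(np.clip(reflectance.data, epsilon, None))
    return HSICube(
        data=absorb,
        wavelengths=reflectance.wavelengths,
        value_kind="absorbance",
        bit_depth=reflectance.bit_depth,
        invalid_pixels=reflectance.invalid_pixels,
    )


def compute_absorbance(cal: CalibrationSet, epsilon: float = 1e-9) -> HSICube:
    """Absorbance straight from the calibration frames."""
    return absorbance_from_reflectance(compute_reflectance(cal, epsilon), epsilon)


def snv_transform(cube: HSICube, ddof: int = 1) -> HSICube:
    """Standard-normal-variate normalisation of each pixel spectrum.

    Z(x) = (x - mean(x)) / std(x) along the band axis. ``ddof=1`` (sample
    standard deviation) is the convention adopted here; for a fixed band
    count the alternative ddof=0 rescales every pixel by the same factor and
    leaves the classification geometry unchanged. Pixels with a constant
    spectrum (zero std) are flagged invalid rather than raising.
    """
    if cube.n_bands < 2:
        raise UsageError("SNV needs at least 2 bands")
    x = cube.data.astype(np.float64)
    mean = x.mean(axis=2, keepdims=True)
    std = x.std(axis=2, ddof=ddof, keepdims=True)
    flat = std[:, :, 0] <= 0
    safe = np.where(std > 0, std, 1.0)
    z = (x - mean) / safe
    z[flat] = 0.0
    invalid = flat
    if cube.invalid_pixels is not None:
        invalid = invalid | cube.invalid_pixels
    return HSICube(
        data=z,
        wavelengths=cube.wavelengths,
        value_kind="snv",
        bit_depth=cube.bit_depth,
        invalid_pixels=invalid,
    )


def trim_wavelengths(cube: HSICube, window: tuple = (1000.0, 1400.0)) -> HSICube:
    """Retain exactly the bands with window[0] <= wavelength <= window[1]."""
    lo, hi = float(window[0]), float(window[1])
    keep = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
    if not np.any(keep):
        raise UsageError(f"no bands inside window [{lo}, {hi}] nm")
    return HSICube(
        data=cube.data[:, :, keep],
        wavelengths=cube.wavelengths[keep],
        value_kind=cube.value_kind,
        bit_depth=cube.bit_depth,
        invalid_pixels=cube.invalid_pixels,
    )


def _dilate_coords(coords: np.ndarray, shape: tuple, radius: int) -> np.ndarray:
    """Chebyshev dilation of a coordinate set: the (2r+1)^2 square around
    each listed pixel, clipped to the raster."""
    mask = np.zeros(shape, dtype=bool)
    coords = np.asarray(coords, dtype=int).reshape(-1, 2)
    if len(coords) == 0:
        return mask
    mask[coords[:, 0], coords[:, 1]] = True
    if radius > 0:
        mask = ndimage.binary_dilation(mask, structure=np.ones((2 * radius + 1,) * 2))
    return mask


def build_validity_mask(
    reflectance: HSICube, annotation: AnnotationMap, params: PreprocessParams
) -> ValidityMask:
    """Per-pixel validity with recorded exclusion reasons.

    A pixel is excluded if it lies outside the evaluated area, is necrotic,
    is a highlight (R > highlight_threshold at the reference band) or shadow
    (R < shadow_threshold), or falls within ``margin_px`` Chebyshev distance
    of a boundary line. When several apply, the recorded reason follows the
    precedence outside > necrosis > highlight/shadow > margin.
    """
    if reflectance.value_kind != "reflectance":
        raise UsageError(f"expected a reflectance cube, got {reflectance.value_kind!r}")
    if reflectance.data.shape[:2] != annotation.shape:
        raise UsageError("reflectance cube and annotation shapes differ")
    shape = annotation.shape
    band = reflectance.band_index(params.reference_wavelength)
    r_ref = reflectance.data[:, :, band]

    reason = np.zeros(shape, dtype=np.uint8)
    # Lowest precedence first; later assignments overwrite.
    margin = _dilate_coords(annotation.tumor_boundary, shape, params.margin_px) | _dilate_coords(
        annotation.exposure_boundary, shape, params.margin_px
    )
    reason[margin] = Reason.BOUNDARY_MARGIN
    reason[r_ref > params.highlight_threshold] = Reason.HIGHLIGHT
    shadow = r_ref < params.shadow_threshold
    if reflectance.invalid_pixels is not None:
        shadow = shadow | reflectance.invalid_pixels
    reason[shadow] = Reason.SHADOW
    reason[annotation.labels == Label.NECROSIS] = Reason.NECROSIS
    reason[annotation.labels == Label.OUTSIDE_EVALUATED] = Reason.OUTSIDE_EVALUATED

    return ValidityMask(valid=reason == Reason.NONE, exclusion_reason=reason)


@dataclass
class PreprocessedSpecimen:
    """One specimen after calibration, trimming, SNV and masking."""

    specimen_id: str
    snv: HSICube
    mask: ValidityMask
    annotation: AnnotationMap


def preprocess_specimen(
    specimen_id: str,
    cal: CalibrationSet,
    annotation: AnnotationMap,
    params: PreprocessParams = None,
) -> PreprocessedSpecimen:
    """Full preprocessing chain for one specimen.

    reflectance -> trim to window -> absorbance -> SNV, plus the validity
    mask built from the trimmed reflectance at the reference band. Pixels
    flagged during calibration or SNV are folded into the mask (as shadow),
    so degenerate pixels never abort a specimen.
    """
    params = params if params is not None else PreprocessParams()
    reflectance = trim_wavelengths(compute_reflectance(cal, params.epsilon), params.keep_window)
    snv = snv_transform(absorbance_from_reflectance(reflectance, params.epsilon), params.snv_ddof)
    mask = build_validity_mask(reflectance, annotation, params)
    if snv.invalid_pixels is not None:
        extra = snv.invalid_pixels & mask.valid
        reason = mask.exclusion_reason.copy()
        reason[extra] = Reason.SHADOW
        mask = ValidityMask(valid=reason == Reason.NONE, exclusion_reason=reason)
    return PreprocessedSpecimen(specimen_id=specimen_id, snv=snv, mask=mask, annotation=annotation)
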