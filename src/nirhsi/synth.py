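"""Synthetic NIR hyperspectral specimen generator.

Real resected-stomach recordings carry protected patient information and are
not redistributable, so the pipeline is exercised on synthetic specimens that
reproduce the statistical structure the analysis relies on:

* two tissue classes (normal mucosa, carcinoma) with distinct smooth
  absorbance signatures in the 1000-1400 nm window;
* a two-layer Beer-Lambert-style mixing rule in absorbance space — the tumor
  signature saturates with tumor thickness and is exponentially attenuated
  by the thickness of normal mucosa covering it:

      w = (1 - exp(-k_t * t_tumor)) * exp(-k_cover * t_cover)
      A(lambda) = A_normal(lambda) + w * (A_tumor(lambda) - A_normal(lambda))

* raw sensor frames produced by inverting the reflectance calibration,
      Ir = Id + (Iw - Id) * 10**(-A) + noise,
  with a halogen-like lamp profile, a spatial vignette, additive Gaussian
  sensor noise, and specular-highlight / shadow / necrosis artifacts;
* an elliptical tumor with an exposed core, an optional unexposed rim
  covered by normal mucosa, boundary polylines (white line = tumor extent,
  yellow line = exposure border), and a per-pixel thickness map.

The forward model deliberately makes "thin tumor is hard to detect" an
emergent property: whether a pixel is classifiable depends on its tumor
weight ``w`` relative to the sensor noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .containers import AnnotationMap, CalibrationSet, HSICube, Label, UsageError

__all__ = [
    "SpecimenConfig",
    "SyntheticSpecimen",
    "default_wavelength_grid",
    "make_endmembers",
    "tumor_weight",
    "simulate_specimen",
    "simulate_cohort",
    "make_probe_calibration",
]


def default_wavelength_grid(start: float = 1000.0, stop: float = 2350.0, step: float = 6.3) -> np.ndarray:
    """Camera wavelength grid: start + k*step for all grid points <= stop."""
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return start + step * np.arange(n)


def _gauss(grid: np.ndarray, center: float, amplitude: float, width: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((grid - center) / width) ** 2)


def make_endmembers(grid: np.ndarray, seed: int = 0) -> tuple:
    """Absorbance signatures (normal, tumor) as sums of Gaussian bands.

    The shapes are fixed apart from a small seeded jitter on the band
    amplitudes; they are built so that after SNV normalisation on the
    1000-1400 nm analysis window the tumor-minus-normal difference is
    negative around 1050-1100 nm and 1380-1400 nm and positive around
    1250-1350 nm — the qualitative contrast the classifier exploits.
    Both classes share the strong water bands beyond 1400 nm, which the
    analysis window removes.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() > 1000.0 or grid.max() < 1400.0:
        raise UsageError("wavelength grid must cover the 1000-1400 nm window")
    rng = np.random.default_rng(seed)
    # Small multiplicative amplitude jitter; keeps the sign pattern intact.
    j = 1.0 + 0.03 * rng.standard_normal(8)

    shared = (
        _gauss(grid, 1450.0, 1.0 * j[0], 70.0)
        + _gauss(grid, 1940.0, 1.5 * j[1], 90.0)
        + 0.00015 * (grid - 1000.0)  # gentle scattering slope
    )
    normal = (
        0.35
        + _gauss(grid, 1075.0, 0.30 * j[2], 45.0)
        + _gauss(grid, 1390.0, 0.45 * j[3], 55.0)
        + shared
    )
    tumor = (
        0.35
        + _gauss(grid, 1075.0, 0.16 * j[4], 45.0)
        + _gauss(grid, 1300.0, 0.26 * j[5], 55.0)
        + _gauss(grid, 1390.0, 0.33 * j[6], 55.0)
        + shared
    )
    return normal, tumor


def tumor_weight(t_tumor, t_cover, k_t: float, k_cover: float):
    """Mixing weight of the tumor endmember at a pixel.

    Saturates with tumor thickness (finite optical sampling depth) and
    decays exponentially with the thickness of covering normal mucosa.
    """
    t_tumor = np.asarray(t_tumor, dtype=float)
    t_cover = np.asarray(t_cover, dtype=float)
    return (1.0 - np.exp(-k_t * t_tumor)) * np.exp(-k_cover * t_cover)


@dataclass
class SpecimenConfig:
    """Parameters of one synthetic specimen.

    Geometry is an ellipse (the tumor, bounded by the white line) with an
    inner concentric ellipse (the exposed core, bounded by the yellow line)
    at relative radius ``core_fraction``; ``core_fraction = 1`` yields a
    fully exposed tumor with no unexposed rim. Thickness follows an
    elliptical dome, ``t = t_max * sqrt(1 - rho**2)``, so thin tumor is
    confined to a narrow marginal rim; covering mucosa over the unexposed
    rim ramps linearly from 0 at the yellow line to ``cover_max_mm`` at the
    white line.
    """

    shape: tuple = (96, 128)
    wavelengths: np.ndarray = field(default_factory=default_wavelength_grid)
    endmember_seed: int = 0
    # Optical mixing parameters (1/mm).
    k_t: float = 0.45
    attenuation_k: float = 0.9
    # Geometry (pixels / fractions).
    center: Optional[tuple] = None
    semi_axes: tuple = (30.0, 40.0)
    core_fraction: float = 0.5
    evaluated_scale: float = 1.35
    # Thickness profile (mm).
    t_max_mm: float = 8.0
    min_thickness_mm: float = 0.15
    cover_max_mm: float = 1.5
    # Thin invasion lobe: within an angular wedge the dome is replaced by a
    # linear taper t_max*(1-rho), putting thin tumor well inside the
    # boundary margin so the detection limit is observable.
    wedge_angle_deg: float = 40.0
    # Tissue heterogeneity: per-pixel Gaussian jitter on the tumor weight
    # (composition variability along the tumor-normal contrast axis). This
    # is what makes thin tumor genuinely ambiguous rather than merely faint.
    bio_sd: float = 0.12
    # Sensor model.
    white_level: float = 14800.0
    dark_level: float = 600.0
    bit_depth: int = 14
    noise_sd: float = 60.0
    # Artifact blob counts (radius drawn 2-4 px).
    n_highlight: int = 2
    n_shadow: int = 2
    n_necrosis: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.k_t <= 0 or self.attenuation_k <= 0:
            raise UsageError("k_t and attenuation_k must be positive")
        if not (0.0 < self.core_fraction <= 1.0):
            raise UsageError("core_fraction must lie in (0, 1]")
        if self.t_max_mm <= 0 or self.cover_max_mm < 0:
            raise UsageError("thickness parameters must be non-negative")
        if self.noise_sd < 0:
            raise UsageError("noise_sd must be >= 0")


@dataclass
class SyntheticSpecimen:
    """One generated specimen: calibration frames + ground truth + config."""

    specimen_id: str
    calibration: CalibrationSet
    annotation: AnnotationMap
    config: SpecimenConfig


def _ellipse_rho(shape: tuple, center: tuple, semi_axes: tuple) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.sqrt(
        ((rr - center[0]) / semi_axes[0]) ** 2 + ((cc - center[1]) / semi_axes[1]) ** 2
    )


def _mask_boundary(mask: np.ndarray) -> np.ndarray:
    """Inner 8-connected boundary pixels of a binary mask, as (n, 2) coords."""
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    return np.argwhere(mask & ~eroded)


def _lamp_profile(wavelengths: np.ndarray) -> np.ndarray:
    """Halogen-like relative spectral output, peaking mid-NIR."""
    wl = np.asarray(wavelengths, dtype=float)
    return 0.75 + 0.25 * np.exp(-0.5 * ((wl - 1400.0) / 600.0) ** 2)


def _blob_mask(shape, centers, radii) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (r0, c0), rad in zip(centers, radii):
        out |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
    return out


def _sensor_frames(config: SpecimenConfig):
    """Deterministic white and dark frames (lamp profile x vignette)."""
    rows, cols = config.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    vignette = 1.0 - 0.06 * (
        ((rr - rows / 2) / (rows / 2)) ** 2 + ((cc - cols / 2) / (cols / 2)) ** 2
    )
    lamp = _lamp_profile(config.wavelengths)
    white = config.dark_level + (config.white_level - config.dark_level) * (
        vignette[:, :, None] * lamp[None, None, :]
    )
    dark = np.full(white.shape, config.dark_level)
    return white, dark


def simulate_specimen(config: SpecimenConfig, specimen_id: str = "specimen") -> SyntheticSpecimen:
    """Generate one specimen (raw/white/dark cubes + annotation).

    Deterministic for a fixed config (including its seed). Noise is applied
    only to the raw frame, so with ``noise_sd = 0`` and no artifacts the
    reflectance calibration inverts the generator exactly.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.shape
    center = config.center if config.center is not None else (rows / 2.0, cols / 2.0)

    rho = _ellipse_rho(config.shape, center, config.semi_axes)
    tumor = rho <= 1.0
    core = rho <= config.core_fraction
    evaluated = rho <= config.evaluated_scale

    # Thickness dome; strictly positive on tumor pixels.
    t_tumor = np.zeros(config.shape)
    t_tumor[tumor] = np.maximum(
        config.t_max_mm * np.sqrt(np.clip(1.0 - rho[tumor] ** 2, 0.0, None)),
        config.min_thickness_mm,
    )
    # Thin invasion lobe: linear taper inside a random angular wedge.
    if config.wedge_angle_deg > 0:
        rr, cc = np.mgrid[0:rows, 0:cols]
        phi = np.arctan2(
            (rr - center[0]) / config.semi_axes[0], (cc - center[1]) / config.semi_axes[1]
        )
        wedge_dir = rng.uniform(0.0, 2.0 * np.pi)
        half = np.deg2rad(config.wedge_angle_deg) / 2.0
        ang = np.abs((phi - wedge_dir + np.pi) % (2.0 * np.pi) - np.pi)
        wedge = tumor & (ang <= half)
        # Taper reaches the thickness floor at rho = 0.85, i.e. inside the
        # boundary-margin exclusion zone, so valid pixels span the full
        # thin-thickness continuum.
        t_tumor[wedge] = np.maximum(
            config.t_max_mm * (1.0 - rho[wedge] / 0.85), config.min_thickness_mm
        )
    # Covering mucosa ramps across the unexposed rim.
    t_cover = np.zeros(config.shape)
    if config.core_fraction < 1.0:
        rim = tumor & ~core
        frac = (rho[rim] - config.core_fraction) / (1.0 - config.core_fraction)
        t_cover[rim] = config.cover_max_mm * frac

    labels = np.full(config.shape, int(Label.OUTSIDE_EVALUATED), dtype=np.int64)
    labels[evaluated & ~tumor] = Label.NORMAL
    labels[tumor & core] = Label.EXPOSED_TUMOR
    labels[tumor & ~core] = Label.UNEXPOSED_TUMOR

    # Necrosis blobs inside the exposed core.
    necrosis = np.zeros(config.shape, dtype=bool)
    if config.n_necrosis > 0 and np.any(core):
        core_px = np.argwhere(core & (rho <= 0.7 * config.core_fraction))
        if len(core_px):
            idx = rng.integers(0, len(core_px), size=config.n_necrosis)
            radii = rng.integers(2, 5, size=config.n_necrosis)
            necrosis = _blob_mask(config.shape, core_px[idx], radii) & tumor
    labels[necrosis] = Label.NECROSIS
    t_tumor[necrosis] = 0.0
    t_cover[necrosis] = 0.0

    tumor_boundary = _mask_boundary(tumor)
    exposure_boundary = (
        _mask_boundary(core) if config.core_fraction < 1.0 else np.empty((0, 2), int)
    )

    annotation = AnnotationMap(
        labels=labels,
        tumor_boundary=tumor_boundary,
        exposure_boundary=exposure_boundary,
        thickness_mm=t_tumor,
    )

    # Absorbance field from the two-layer mixing rule.
    em_normal, em_tumor = make_endmembers(config.wavelengths, config.endmember_seed)
    w = tumor_weight(t_tumor, t_cover, config.k_t, config.attenuation_k)
    if config.bio_sd > 0:
        w = np.clip(w + config.bio_sd * rng.standard_normal(config.shape), 0.0, 1.0)
    w[necrosis] = 0.0  # necrotic tissue rendered as baseline
    absorbance = em_normal[None, None, :] + w[:, :, None] * (em_tumor - em_normal)[None, None, :]

    white, dark = _sensor_frames(config)
    raw = dark + (white - dark) * np.power(10.0, -absorbance)

    # Specular highlights / shadows override the tissue signal.
    n_art = config.n_highlight + config.n_shadow
    if n_art > 0:
        eval_px = np.argwhere(evaluated)
        idx = rng.integers(0, len(eval_px), size=n_art)
        radii = rng.integers(2, 5, size=n_art)
        highlight = _blob_mask(config.shape, eval_px[idx[: config.n_highlight]], radii[: config.n_highlight])
        shadow = _blob_mask(config.shape, eval_px[idx[config.n_highlight :]], radii[config.n_highlight :])
        shadow &= ~highlight
        raw[highlight] = (dark + 0.92 * (white - dark))[highlight]
        raw[shadow] = (dark + 0.04 * (white - dark))[shadow]

    if config.noise_sd > 0:
        raw = raw + rng.normal(0.0, config.noise_sd, size=raw.shape)
    raw = np.clip(raw, 0.0, None)

    def cube(data):
        return HSICube(
            data=data.astype(np.float32),
            wavelengths=config.wavelengths,
            value_kind="raw",
            bit_depth=config.bit_depth,
        )

    calibration = CalibrationSet(raw=cube(raw), white=cube(white), dark=cube(dark))
    return SyntheticSpecimen(
        specimen_id=specimen_id, calibration=calibration, annotation=annotation, config=config
    )


def simulate_cohort(
    n: int,
    template: Optional[SpecimenConfig] = None,
    seed: int = 0,
    unexposed_fraction: float = 0.6,
) -> list:
    """Generate a cohort of ``n`` specimens with varied geometry.

    By default 6 of 10 specimens carry an unexposed rim (tumor under intact
    mucosa) and the rest are fully exposed, mirroring the clinical mix the
    pipeline is meant to handle. Per-specimen seeds derive deterministically
    from ``seed``, so the cohort is reproducible bit-for-bit.
    """
    if n < 2:
        raise UsageError("a cohort needs at least 2 specimens (LOOCV requirement)")
    template = template if template is not None else SpecimenConfig()
    rng = np.random.default_rng(seed)
    n_rim = int(round(unexposed_fraction * n))
    has_rim = np.zeros(n, dtype=bool)
    has_rim[rng.permutation(n)[:n_rim]] = True

    specimens = []
    for i in range(n):
        jitter = rng.uniform(0.9, 1.1, size=2)
        cfg = replace(
            template,
            semi_axes=(template.semi_axes[0] * jitter[0], template.semi_axes[1] * jitter[1]),
            center=(
                template.shape[0] / 2.0 + rng.uniform(-4, 4),
                template.shape[1] / 2.0 + rng.uniform(-4, 4),
            ),
            t_max_mm=float(rng.uniform(5.0, 12.0)),
            cover_max_mm=float(rng.uniform(0.8, 1.8)),
            core_fraction=template.core_fraction if has_rim[i] else 1.0,
            seed=int((seed * 1_000_003 + i) % 2**31),
        )
        specimens.append(simulate_specimen(cfg, specimen_id=f"s{i:02d}"))
    return specimens


def make_probe_calibration(
    config: SpecimenConfig,
    t_tumor: Sequence[float],
    t_cover: Optional[Sequence[float]] = None,
) -> CalibrationSet:
    """Noiseless single-row calibration frames probing given thicknesses.

    Pixel ``(0, i)`` carries a tumor of thickness ``t_tumor[i]`` under
    ``t_cover[i]`` mm of normal mucosa (default 0: exposed), with no sensor
    noise or artifacts. Used to locate the generator's detection transition
    by sweeping thickness past a trained classifier.
    """
    t_tumor = np.asarray(t_tumor, dtype=float)
    t_cover = np.zeros_like(t_tumor) if t_cover is None else np.asarray(t_cover, dtype=float)
    if t_tumor.shape != t_cover.shape:
        raise UsageError("t_tumor and t_cover must have the same length")
    em_normal, em_tumor = make_endmembers(config.wavelengths, config.endmember_seed)
    w = tumor_weight(t_tumor, t_cover, config.k_t, config.attenuation_k)
    absorbance = em_normal[None, None, :] + w[None, :, None] * (em_tumor - em_normal)[None, None, :]
    lamp = _lamp_profile(config.wavelengths)
    white = config.dark_level + (config.white_level - config.dark_level) * lamp[None, None, :]
    white = np.broadcast_to(white, absorbance.shape).copy()
    dark = np.full(absorbance.shape, config.dark_level)
    raw = dark + (white - dark) * np.power(10.0, -absorbance)

    def cube(data):
        return HSICube(data=data, wavelengths=config.wavelengths, value_kind="raw",
                       bit_depth=config.bit_depth)

    return CalibrationSet(raw=cube(raw), white=cube(white), dark=cube(dark))
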