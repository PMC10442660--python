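"""File I/O: ENVI cubes, portable array containers, annotation sidecars.

Cubes interchange as ENVI ``.hdr``/``.img`` pairs (band-sequential layout,
wavelength list in the header, ``wavelength units = nm``) — the de-facto
standard for hyperspectral data — or as compressed ``.npz`` containers for
compact fixtures. Annotations, validity masks and prediction maps are
``.npz`` rasters with a YAML sidecar recording the label vocabulary and
provenance.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import yaml

from .containers import (
    PRED_NORMAL,
    PRED_NOT_EVALUATED,
    PRED_TUMOR,
    AnnotationMap,
    FormatError,
    HSICube,
    Label,
    PredictionMap,
    UsageError,
    ValidityMask,
)

__all__ = [
    "read_cube",
    "write_cube",
    "read_annotation",
    "write_annotation",
    "read_mask",
    "write_mask",
    "read_prediction",
    "write_prediction",
]

# ENVI numeric "data type" codes <-> numpy dtypes (subset in common use).
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
    14: np.int64,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _envi_paths(path) -> tuple:
    p = Path(path)
    if p.suffix in (".hdr", ".img"):
        p = p.with_suffix("")
    return p.with_suffix(".hdr"), p.with_suffix(".img")


def _parse_envi_header(text: str) -> dict:
    """Parse 'key = value' ENVI header lines, honouring {...} blocks."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing ENVI magic)")
    fields = {}
    body = text.split("\n", 1)[1] if "\n" in text else ""
    i = 0
    while i < len(body):
        line_end = body.find("\n", i)
        if line_end == -1:
            line_end = len(body)
        line = body[i:line_end]
        if "=" in line:
            key, _, value = line.partition("=")
            key = key.strip().lower()
            value = value.strip()
            if value.startswith("{"):
                close = body.find("}", i)
                if close == -1:
                    raise FormatError(f"unterminated {{ block for field {key!r}")
                value = body[body.find("{", i) + 1 : close]
                line_end = body.find("\n", close)
                if line_end == -1:
                    line_end = len(body)
            if key in fields:
                raise FormatError(f"duplicate header field {key!r}")
            fields[key] = value
        i = line_end + 1
    return fields


def _write_envi(cube: HSICube, path) -> None:
    hdr_path, img_path = _envi_paths(path)
    rows, cols, bands = cube.data.shape
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_CODES:
        dtype = np.dtype(np.float64)
    code = _DTYPE_CODES[dtype]
    wl = ", ".join(f"{w:.17g}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        "description = {nirhsi hyperspectral cube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {code}",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = nm",
        f"value kind = {cube.value_kind}",
    ]
    if cube.bit_depth is not None:
        lines.append(f"bit depth = {cube.bit_depth}")
    lines.append("wavelength = {" + wl + "}")
    hdr_path.write_text("\n".join(lines) + "\n")
    # BSQ: band-major on disk.
    arr = np.ascontiguousarray(np.moveaxis(cube.data.astype(dtype, copy=False), 2, 0))
    if os.sys.byteorder != "little":  # pragma: no cover - LE platforms only in practice
        arr = arr.astype(arr.dtype.newbyteorder("<"))
    arr.tofile(img_path)


def _read_envi(path) -> HSICube:
    hdr_path, img_path = _envi_paths(path)
    if not hdr_path.exists() or not img_path.exists():
        raise FormatError(f"missing ENVI pair for {path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing field {exc}") from exc
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise FormatError("only BSQ interleave is supported")
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {code}")
    if "wavelength" not in fields:
        raise FormatError("ENVI header lacks wavelength metadata")
    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].replace("\n", " ").split(",") if tok.strip()]
    )
    if len(wavelengths) != bands:
        raise FormatError(f"{len(wavelengths)} wavelengths listed for {bands} bands")
    dtype = np.dtype(_ENVI_DTYPES[code]).newbyteorder("<")
    raw = np.fromfile(img_path, dtype=dtype)
    if raw.size != rows * cols * bands:
        raise FormatError("ENVI binary size does not match header dimensions")
    data = np.moveaxis(raw.reshape(bands, rows, cols), 0, 2)
    bit_depth = int(fields["bit depth"]) if "bit depth" in fields else None
    return HSICube(
        data=data.astype(dtype.newbyteorder("=")),
        wavelengths=wavelengths,
        value_kind=fields.get("value kind", "raw").strip(),
        bit_depth=bit_depth,
    )


def write_cube(cube: HSICube, path, format: str = "envi") -> None:
    """Write a cube as an ENVI pair or a compressed portable array."""
    if format == "envi":
        _write_envi(cube, path)
    elif format == "portable_array":
        np.savez_compressed(
            Path(path),
            data=cube.data,
            wavelengths=cube.wavelengths,
            value_kind=np.asarray(cube.value_kind),
            bit_depth=np.asarray(-1 if cube.bit_depth is None else cube.bit_depth),
        )
    else:
        raise UsageError(f"unknown cube format {format!r}")


def read_cube(path, format: str = "envi") -> HSICube:
    """Read a cube written by :func:`write_cube`."""
    if format == "envi":
        return _read_envi(path)
    if format == "portable_array":
        p = Path(path)
        if p.suffix != ".npz":
            p = p.with_suffix(".npz")
        with np.load(p, allow_pickle=False) as z:
            bit_depth = int(z["bit_depth"])
            return HSICube(
                data=z["data"],
                wavelengths=z["wavelengths"],
                value_kind=str(z["value_kind"]),
                bit_depth=None if bit_depth < 0 else bit_depth,
            )
    raise UsageError(f"unknown cube format {format!r}")


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".yaml")


def write_annotation(annotation: AnnotationMap, path) -> None:
    """Write labels/thickness rasters (.npz) plus a YAML vocabulary sidecar."""
    p = Path(path)
    if p.suffix != ".npz":
        p = p.with_suffix(".npz")
    np.savez_compressed(
        p,
        labels=annotation.labels.astype(np.uint8),
        thickness_mm=annotation.thickness_mm,
        tumor_boundary=annotation.tumor_boundary,
        exposure_boundary=annotation.exposure_boundary,
    )
    sidecar = {
        "kind": "annotation",
        "raster": p.name,
        "shape": [int(s) for s in annotation.shape],
        "label_vocabulary": {l.name.lower(): int(l) for l in Label},
        "thickness_units": "mm",
    }
    _sidecar(p).write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_annotation(path) -> AnnotationMap:
    p = Path(path)
    if p.suffix != ".npz":
        p = p.with_suffix(".npz")
    with np.load(p, allow_pickle=False) as z:
        return AnnotationMap(
            labels=z["labels"].astype(np.int64),
            tumor_boundary=z["tumor_boundary"],
            exposure_boundary=z["exposure_boundary"],
            thickness_mm=z["thickness_mm"],
        )


def write_mask(mask: ValidityMask, path) -> None:
    p = Path(path)
    if p.suffix != ".npz":
        p = p.with_suffix(".npz")
    np.savez_compressed(p, valid=mask.valid, exclusion_reason=mask.exclusion_reason)


def read_mask(path) -> ValidityMask:
    p = Path(path)
    if p.suffix != ".npz":
        p = p.with_suffix(".npz")
    with np.load(p, allow_pickle=False) as z:
        return ValidityMask(valid=z["valid"], exclusion_reason=z["exclusion_reason"])


def write_prediction(pred: PredictionMap, path) -> None:
    """Prediction raster (0 normal / 1 tumor / 255 not evaluated) + sidecar."""
    p = Path(path)
    if p.suffix != ".npz":
        p = p.with_suffix(".npz")
    np.savez_compressed(p, classes=pred.classes)
    sidecar = {
        "kind": "prediction",
        "raster": p.name,
        "specimen_id": pred.specimen_id,
        "codes": {"normal": PRED_NORMAL, "tumor": PRED_TUMOR, "not_evaluated": PRED_NOT_EVALUATED},
        "provenance": {k: _plain(v) for k, v in pred.provenance.items()},
    }
    _sidecar(p).write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_prediction(path) -> PredictionMap:
    p = Path(path)
    if p.suffix != ".npz":
        p = p.with_suffix(".npz")
    with np.load(p, allow_pickle=False) as z:
        classes = z["classes"]
    specimen_id = ""
    provenance = {}
    sc = _sidecar(p)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text())
        specimen_id = meta.get("specimen_id", "")
        provenance = meta.get("provenance", {}) or {}
    return PredictionMap(classes=classes, specimen_id=specimen_id, provenance=provenance)


def _plain(value):
    """Coerce numpy scalars to YAML-friendly python scalars."""
    if isinstance(value, np.generic):
        return value.item()
    return value
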