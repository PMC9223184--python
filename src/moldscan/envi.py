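"""Minimal ENVI-format hypercube I/O (text header + flat binary).

ENVI is the de facto hyperspectral interchange format: a small ASCII header
(``samples``/``lines``/``bands``, data type, interleave, wavelength list)
next to a raw binary block.  Cubes are written band-sequential (BSQ) as
float64 for lossless round-trips; BIL and BIP files are converted to the
package's (lines, samples, bands) layout on read.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .imaging import Hypercube

_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def write_cube(cube: Hypercube, path: str | Path) -> Path:
    """Write a cube as ``<path>.hdr`` + ``<path>.img`` (BSQ, float64)."""
    path = Path(path)
    path = path.with_suffix("") if path.suffix in {".img", ".hdr"} else path
    img = path.with_suffix(".img")
    hdr = path.with_suffix(".hdr")
    h, w, b = cube.shape
    lam = ", ".join(f"{x:.6f}" for x in cube.wavelengths)
    hdr.write_text(
        "ENVI\n"
        f"description = {{moldscan hypercube, sensor {cube.sensor}, "
        f"calibrated {int(cube.calibrated)}}}\n"
        f"samples = {w}\nlines = {h}\nbands = {b}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        "data type = 5\ninterleave = bsq\nbyte order = 0\n"
        f"sensor type = {cube.sensor}\n"
        f"wavelength units = Nanometers\nwavelength = {{{lam}}}\n"
    )
    np.ascontiguousarray(cube.values.transpose(2, 0, 1)).tofile(img)
    return img


def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic)")
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values, then split on key = value
    for m in re.finditer(r"^([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", text, re.MULTILINE | re.DOTALL):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def read_cube(path: str | Path) -> Hypercube:
    """Read an ENVI header + binary pair back into a Hypercube."""
    path = Path(path)
    stem = path.with_suffix("") if path.suffix in {".img", ".hdr"} else path
    hdr, img = stem.with_suffix(".hdr"), stem.with_suffix(".img")
    if not hdr.exists():
        raise FileNotFoundError(hdr)
    fields = _parse_header(hdr.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise ValueError(f"malformed ENVI header: missing {exc}") from exc
    if "wavelength" not in fields:
        raise ValueError("malformed ENVI header: missing wavelength block")
    lam = np.array(
        [float(x) for x in fields["wavelength"].strip("{}").replace("\n", " ").split(",") if x.strip()]
    )
    if lam.size != bands:
        raise ValueError(f"wavelength count {lam.size} does not match bands {bands}")
    if dtype_code not in _DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    offset = int(fields.get("header offset", "0"))
    data = np.fromfile(img, dtype=_DTYPES[dtype_code], offset=offset)
    if data.size != samples * lines * bands:
        raise ValueError("binary size does not match header dimensions")
    interleave = fields.get("interleave", "bsq").lower()
    if interleave == "bsq":
        values = data.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        values = data.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        values = data.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    desc = fields.get("description", "")
    calibrated = "calibrated 1" in desc
    sensor = fields.get("sensor type", "unknown")
    return Hypercube(values.astype(np.float64), lam, sensor, calibrated=calibrated)
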