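"""Minimal ENVI raster I/O for hyperspectral cubes.

ENVI stores a cube as a raw binary array plus a plain-text ``.hdr`` file of
``key = value`` pairs (lists in braces).  Only the subset needed here is
supported: BIL/BSQ/BIP interleaves, little/big endian, float32/float64 and
the common integer types, and the ``wavelength`` list in nm.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .radiometrics import HyperCube

# ENVI "data type" codes -> numpy dtypes
_DTYPES = {1: "u1", 2: "i2", 3: "i4", 4: "f4", 5: "f8", 12: "u2", 13: "u4"}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def _parse_header(text: str) -> dict:
    """Parse an ENVI header into a dict of strings / lists of strings."""
    lines = text.splitlines()
    if not lines or lines[0].strip().upper() != "ENVI":
        raise ValueError("not an ENVI header (missing ENVI magic line)")
    fields: dict = {}
    i = 1
    while i < len(lines):
        line = lines[i]
        i += 1
        if "=" not in line:
            continue
        key, _, rest = line.partition("=")
        key = key.strip().lower()
        rest = rest.strip()
        if rest.startswith("{"):
            while "}" not in rest:
                if i >= len(lines):
                    raise ValueError(f"unterminated list for header field '{key}'")
                rest += " " + lines[i].strip()
                i += 1
            inner = rest[1 : rest.index("}")]
            fields[key] = [v.strip() for v in inner.split(",") if v.strip()]
        else:
            fields[key] = rest
    return fields


def read_envi(path: str | os.PathLike) -> HyperCube:
    """Read an ENVI cube; ``path`` may point at the header or the data file."""
    path = Path(path)
    hdr = path if path.suffix == ".hdr" else path.with_suffix(path.suffix + ".hdr")
    if not hdr.exists():
        raise FileNotFoundError(f"ENVI header not found: {hdr}")
    data_file = hdr.with_suffix("") if path.suffix == ".hdr" else path
    if not data_file.exists():
        raise FileNotFoundError(f"ENVI data file not found: {data_file}")

    fields = _parse_header(hdr.read_text())
    lines = int(fields["lines"])
    samples = int(fields["samples"])
    bands = int(fields["bands"])
    interleave = str(fields.get("interleave", "bsq")).lower()
    offset = int(fields.get("header offset", 0))
    code = int(fields.get("data type", 4))
    if code not in _DTYPES:
        raise ValueError(f"unsupported ENVI data type code {code}")
    byte_order = int(fields.get("byte order", 0))
    dtype = np.dtype(("<" if byte_order == 0 else ">") + _DTYPES[code])

    raw = np.fromfile(data_file, dtype=dtype, offset=offset, count=lines * samples * bands)
    if raw.size != lines * samples * bands:
        raise ValueError("ENVI data file shorter than header dimensions imply")
    if interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    elif interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        raise ValueError(f"unsupported interleave '{interleave}'")

    wavelengths = fields.get("wavelength")
    if wavelengths is not None:
        grid = np.array([float(w) for w in wavelengths])
    else:
        grid = np.arange(bands, dtype=float)
    kind = str(fields.get("cube kind", "raw"))
    camera = str(fields.get("camera", ""))
    return HyperCube(cube.astype(float), grid, kind=kind, camera=camera)


def write_envi(
    cube: HyperCube,
    path: str | os.PathLike,
    interleave: str = "bil",
    dtype: str = "f4",
) -> Path:
    """Write a cube as ENVI binary + text header; returns the data-file path.

    The wavelength grid goes into the header's ``wavelength`` list (nm), and
    the cube ``kind``/``camera`` tags are stored as custom header fields so a
    round trip preserves them.
    """
    path = Path(path)
    interleave = interleave.lower()
    dt = np.dtype("<" + dtype)
    if dt not in _DTYPE_CODES:
        raise ValueError(f"unsupported dtype '{dtype}'")
    lines, samples, bands = cube.shape
    if interleave == "bil":
        arr = cube.data.transpose(0, 2, 1)
    elif interleave == "bip":
        arr = cube.data
    elif interleave == "bsq":
        arr = cube.data.transpose(2, 0, 1)
    else:
        raise ValueError(f"unsupported interleave '{interleave}'")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.ascontiguousarray(arr, dtype=dt).tofile(path)

    wl = ", ".join(f"{w:.6g}" for w in cube.grid)
    header = (
        "ENVI\n"
        "description = {hypertrait cube}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dt]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"cube kind = {cube.kind}\n"
        f"camera = {cube.camera}\n"
        f"wavelength = {{{wl}}}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(header)
    return path
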