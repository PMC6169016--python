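"""Minimal ENVI header/binary reader and writer.

Cubes are stored as a plain-text ``.hdr`` header next to a raw binary file.
Axis convention throughout the package: ``data[row, col, band]`` with
row = along-scan (y), col = across-track (x), all indices 0-based.
ENVI terms map as lines = rows, samples = cols.
"""

from __future__ import annotations

import os
import re

import numpy as np

__all__ = ["read_envi", "write_envi"]

# ENVI "data type" codes <-> numpy dtypes (little-endian assumed, byte order 0)
_DTYPE_FROM_CODE = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_CODE_FROM_DTYPE = {np.dtype(v): k for k, v in _DTYPE_FROM_CODE.items()}

_INTERLEAVES = ("bil", "bip", "bsq")


class EnviError(ValueError):
    """Malformed ENVI header or inconsistent header/binary pair."""


def _parse_header(text: str) -> dict:
    # Collapse { ... } blocks (possibly multi-line) into single values.
    text = text.strip()
    if not text.lower().startswith("envi"):
        raise EnviError("not an ENVI header (missing 'ENVI' magic)")
    fields: dict[str, str] = {}
    # join braces across newlines
    pattern = re.compile(r"^([^=\n{}]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(text):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1].strip()
        fields[key] = val
    return fields


def _hdr_path(path: str) -> str:
    if path.endswith(".hdr"):
        return path
    return path + ".hdr"


def _bin_path(path: str) -> str:
    if path.endswith(".hdr"):
        return path[: -len(".hdr")]
    return path


def read_envi(path: str) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read an ENVI cube.

    Parameters
    ----------
    path:
        Path to either the binary file or its ``.hdr`` header.

    Returns
    -------
    data : ndarray, shape (rows, cols, bands)
    wavelengths : ndarray, shape (bands,), nm
    meta : dict of remaining header fields
    """
    hdr, binf = _hdr_path(path), _bin_path(path)
    if not os.path.exists(hdr):
        raise EnviError(f"missing header: {hdr}")
    if not os.path.exists(binf):
        raise EnviError(f"missing binary: {binf}")
    with open(hdr) as fh:
        fields = _parse_header(fh.read())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise EnviError(f"header missing required key: {exc}") from exc
    if interleave not in _INTERLEAVES:
        raise EnviError(f"unsupported interleave {interleave!r}")
    if "wavelength" not in fields:
        raise EnviError("header has no wavelength list")
    wavelengths = np.array(
        [float(w) for w in fields["wavelength"].replace("\n", " ").split(",") if w.strip()],
        dtype=np.float64,
    )
    if wavelengths.size != bands:
        raise EnviError(
            f"wavelength list length {wavelengths.size} != bands {bands}"
        )
    dtype = np.dtype(_DTYPE_FROM_CODE[code])
    offset = int(fields.get("header offset", 0))

    expected = samples * lines * bands * dtype.itemsize
    actual = os.path.getsize(binf) - offset
    if actual != expected:
        raise EnviError(
            f"binary size {actual} B does not match header "
            f"({lines}x{samples}x{bands} {dtype.name} = {expected} B)"
        )
    flat = np.fromfile(binf, dtype=dtype, offset=offset)
    if interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = flat.reshape(lines, samples, bands)

    meta = {
        k: v
        for k, v in fields.items()
        if k not in ("samples", "lines", "bands", "data type", "interleave", "wavelength")
    }
    meta["interleave"] = interleave
    return np.ascontiguousarray(data), wavelengths, meta


def write_envi(
    path: str,
    data: np.ndarray,
    wavelengths: np.ndarray,
    interleave: str = "bil",
    meta: dict | None = None,
) -> str:
    """Write ``data[row, col, band]`` as ENVI binary + header; returns binary path."""
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise EnviError(f"unsupported interleave {interleave!r}")
    data = np.asarray(data)
    if data.ndim != 3:
        raise EnviError("cube must be 3-D (rows, cols, bands)")
    if data.dtype not in _CODE_FROM_DTYPE:
        data = data.astype(np.float32)
    rows, cols, bands = data.shape
    if len(wavelengths) != bands:
        raise EnviError("wavelength list length != number of bands")

    if interleave == "bsq":
        ordered = data.transpose(2, 0, 1)
    elif interleave == "bil":
        ordered = data.transpose(0, 2, 1)
    else:
        ordered = data
    binf = _bin_path(path)
    ordered.astype(data.dtype).tofile(binf)

    wl = ", ".join(f"{w:.6f}" for w in np.asarray(wavelengths, dtype=float))
    extra = ""
    for k, v in (meta or {}).items():
        if k in ("interleave",):
            continue
        extra += f"{k} = {v}\n"
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_CODE_FROM_DTYPE[data.dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n" + extra
    )
    with open(_hdr_path(path), "w") as fh:
        fh.write(header)
    return binf
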