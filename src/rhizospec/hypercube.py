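"""Hypercube container, calibration, normalization, band trimming, dead-pixel masking.

The central object is :class:`HyperCube`: a ``(rows, cols, bands)`` float
reflectance array with a strictly increasing wavelength axis and a spatial
validity mask.  Masked ("black-masked") pixels hold exactly zero at all
wavelengths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import envi

log = logging.getLogger(__name__)

__all__ = [
    "HyperCube",
    "CalibrationFrames",
    "read_envi_cube",
    "write_envi_cube",
    "normalize",
    "trim_bands",
    "mask_dead_pixels",
]


@dataclass
class HyperCube:
    """Reflectance cube ``data[row, col, band]`` with wavelength axis in nm.

    Invariants
    ----------
    * ``wavelengths`` strictly increasing, one entry per band.
    * ``data`` is finite wherever ``valid_mask`` is true.
    * black-masked pixels (``valid_mask == False``) are exactly 0 at all bands.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    valid_mask: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("cube data must be (rows, cols, bands)")
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.wavelengths.size != self.data.shape[2]:
            raise ValueError("wavelength axis length != number of bands")
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.data.shape[:2]:
                raise ValueError("valid_mask shape != spatial shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band whose center wavelength is nearest ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))

    def copy(self) -> "HyperCube":
        return HyperCube(
            self.data.copy(), self.wavelengths.copy(), self.valid_mask.copy(), dict(self.meta)
        )


@dataclass
class CalibrationFrames:
    """White (Spectralon) and dark frames, ``(rows', cols, bands)`` counts.

    White/dark standards are short scans recorded before each stride; they are
    averaged over their scan lines to a single ``(cols, bands)`` profile before
    use, per push-broom convention.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.atleast_3d(np.asarray(self.white, dtype=np.float64))
        self.dark = np.atleast_3d(np.asarray(self.dark, dtype=np.float64))
        if self.white.shape[1:] != self.dark.shape[1:]:
            raise ValueError("white/dark frames not conformable")

    def averaged(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-column, per-band mean profiles: ``(cols, bands)`` each."""
        return self.white.mean(axis=0), self.dark.mean(axis=0)


def read_envi_cube(path: str) -> HyperCube:
    """Read a cube from an ENVI header/binary pair; dtype promoted to float32."""
    data, wavelengths, meta = envi.read_envi(path)
    meta = dict(meta)
    meta["source_path"] = str(path)
    return HyperCube(data.astype(np.float32), wavelengths, meta=meta)


def write_envi_cube(cube: HyperCube, path: str, interleave: str = "bil") -> str:
    """Write a cube as float32 ENVI; returns binary path."""
    return envi.write_envi(
        path, cube.data.astype(np.float32), cube.wavelengths, interleave=interleave
    )


def normalize(raw: HyperCube | np.ndarray, cal: CalibrationFrames) -> HyperCube:
    """Normalize raw counts to reflectance with white/dark standards.

    Per pixel i and band λ: ``N = (R − D) / (W − D)`` with W and D the
    per-column averaged white/dark profiles.  Values are not clipped to [0, 1]
    (specular pixels may exceed 1).  Any (col, band) where W == D is set to 0
    and recorded in ``meta['degenerate_cal_bands']``.
    """
    if isinstance(raw, HyperCube):
        data, wavelengths, vmask, meta = raw.data, raw.wavelengths, raw.valid_mask, dict(raw.meta)
    else:
        data = np.atleast_3d(np.asarray(raw, dtype=np.float64))
        wavelengths = np.arange(data.shape[2], dtype=float)
        vmask = np.ones(data.shape[:2], dtype=bool)
        meta = {}
    white, dark = cal.averaged()
    if white.shape != data.shape[1:]:
        raise ValueError(
            f"calibration profile shape {white.shape} not conformable with raw {data.shape[1:]}"
        )
    denom = white - dark
    bad = denom <= 0
    n = np.empty(data.shape, dtype=np.float32)
    with np.errstate(divide="ignore", invalid="ignore"):
        n[:] = (data - dark[None]) / np.where(bad, 1.0, denom)[None]
    if bad.any():
        bad_bands = sorted(int(b) for b in np.unique(np.nonzero(bad)[1]))
        warnings.warn(
            f"white == dark at {int(bad.sum())} (col, band) cells; "
            f"affected bands flagged invalid: {bad_bands}",
            stacklevel=2,
        )
        n[:, bad] = 0.0
        meta["degenerate_cal_bands"] = bad_bands
    n[~vmask] = 0.0
    return HyperCube(n, wavelengths, vmask.copy(), meta)


def trim_bands(cube: HyperCube, lo: float, hi: float) -> HyperCube:
    """Retain bands with center wavelength in ``[lo, hi]`` nm."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    keep = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
    if not keep.any():
        raise ValueError(f"no bands in [{lo}, {hi}] nm")
    return HyperCube(
        cube.data[:, :, keep], cube.wavelengths[keep], cube.valid_mask.copy(), dict(cube.meta)
    )


def mask_dead_pixels(
    cube: HyperCube, k_mad: float = 20.0, abs_threshold: float | None = None
) -> tuple[HyperCube, int]:
    """Black-mask dead pixels and spikes.

    Per-pixel score: standard deviation over λ of the difference spectrum
    ``N[λ] − N[λ+1]``.  Pixels scoring above
    ``median + k_mad · max(MAD, median)`` (statistics over currently valid
    pixels) are masked; ``abs_threshold``, when given, replaces the robust
    rule.  Already-masked pixels stay masked.

    The median acts as a floor for the spread estimate: on near-uniform
    backgrounds the raw MAD is so small that genuine absorption features
    would be flagged, while true spikes sit orders of magnitude above the
    median regardless.

    Returns the new cube and the number of newly flagged pixels.
    """
    if cube.n_bands < 3:
        raise ValueError("need at least 3 bands")
    diffs = np.diff(cube.data.astype(np.float64), axis=2)
    score = diffs.std(axis=2)
    valid = cube.valid_mask
    if abs_threshold is not None:
        thr = float(abs_threshold)
    else:
        s = score[valid]
        med = float(np.median(s))
        mad = float(np.median(np.abs(s - med)))
        thr = med + k_mad * max(mad, med)
    flag = valid & (score > thr)
    out = cube.copy()
    out.valid_mask[flag] = False
    out.data[~out.valid_mask] = 0.0
    n_flagged = int(flag.sum())
    if n_flagged:
        log.info("mask_dead_pixels: flagged %d pixels (threshold %.4g)", n_flagged, thr)
    out.meta["dead_pixels_flagged"] = out.meta.get("dead_pixels_flagged", 0) + n_flagged
    return out, n_flagged
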