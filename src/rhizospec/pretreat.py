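"""Factorial spectral pre-treatment bank.

Each pre-treatment is one cell of the linearization × de-trending ×
multiplicative-correction factorial (2 × 4 × 2 = 16 combinations), applied
per pixel along the spectral axis in that fixed order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .hypercube import HyperCube

log = logging.getLogger(__name__)

__all__ = [
    "PretreatmentSpec",
    "enumerate_specs",
    "log_linearize",
    "detrend_poly2",
    "sg_first_derivative",
    "als_baseline",
    "snv",
    "msc",
    "apply_pretreatment",
]

LINEARIZATIONS = ("none", "log_inv")
DETRENDS = ("none", "poly2", "sg_deriv1", "als")
MULTIPLICATIVES = ("none", "snv")

DEFAULT_PARAMS = {
    "als_lambda": 1e4,
    "als_p": 1e-3,
    "als_n_iter": 10,
    "sg_window": 7,
    "sg_polyorder": 2,
    "poly_degree": 2,
}

_LOG_FLOOR = 1e-6  # floor for non-positive reflectance before log10(1/R)


@dataclass(frozen=True)
class PretreatmentSpec:
    """One cell of the pre-treatment factorial."""

    linearization: str = "none"
    detrend: str = "none"
    multiplicative: str = "none"
    params: tuple = field(default_factory=tuple)  # sorted (key, value) pairs

    def __post_init__(self) -> None:
        if self.linearization not in LINEARIZATIONS:
            raise ValueError(f"unknown linearization {self.linearization!r}")
        if self.detrend not in DETRENDS:
            raise ValueError(f"unknown detrend {self.detrend!r}")
        if self.multiplicative not in MULTIPLICATIVES:
            raise ValueError(f"unknown multiplicative {self.multiplicative!r}")

    @property
    def param_dict(self) -> dict:
        out = dict(DEFAULT_PARAMS)
        out.update(dict(self.params))
        return out

    @property
    def label(self) -> str:
        return f"{self.linearization}+{self.detrend}+{self.multiplicative}"

    @classmethod
    def from_dict(cls, d: dict) -> "PretreatmentSpec":
        params = d.get("params", {})
        return cls(
            d.get("linearization", "none"),
            d.get("detrend", "none"),
            d.get("multiplicative", "none"),
            tuple(sorted(params.items())),
        )


def enumerate_specs() -> list[PretreatmentSpec]:
    """All 16 factorial combinations in canonical row order.

    Linearization varies slowest, then multiplicative correction, then
    de-trending: row 1 = (none, none, none), row 12 = (log_inv, als, none),
    row 16 = (log_inv, als, snv).
    """
    specs = []
    for lin in LINEARIZATIONS:
        for mult in MULTIPLICATIVES:
            for det in DETRENDS:
                specs.append(PretreatmentSpec(lin, det, mult))
    return specs


def log_linearize(spectrum: np.ndarray) -> np.ndarray:
    """Absorbance transform A = log10(1/R); non-positive R floored to 1e-6."""
    r = np.asarray(spectrum, dtype=np.float64)
    n_floored = int(np.sum(r <= 0))
    if n_floored:
        log.warning("log_linearize: floored %d non-positive values", n_floored)
    r = np.maximum(r, _LOG_FLOOR)
    return -np.log10(r)


def detrend_poly2(spectrum: np.ndarray, wavelengths: np.ndarray, degree: int = 2) -> np.ndarray:
    """Residual of a least-squares polynomial fit in wavelength.

    Works on a single spectrum (1-D) or a stack (..., bands).
    """
    x = np.asarray(wavelengths, dtype=np.float64)
    # center/scale for conditioning
    xs = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    v = np.vander(xs, degree + 1)
    y = np.asarray(spectrum, dtype=np.float64)
    flat = y.reshape(-1, y.shape[-1]).T  # (bands, n)
    coef, *_ = np.linalg.lstsq(v, flat, rcond=None)
    resid = flat - v @ coef
    return resid.T.reshape(y.shape)


def sg_first_derivative(
    spectrum: np.ndarray, window: int = 7, polyorder: int = 2
) -> np.ndarray:
    """Savitzky–Golay first derivative along the spectral axis (per-band units)."""
    if window % 2 == 0 or window < polyorder + 1:
        raise ValueError("sg window must be odd and > polyorder")
    y = np.asarray(spectrum, dtype=np.float64)
    if y.shape[-1] < window:
        raise ValueError("fewer bands than the SG window")
    return savgol_filter(y, window, polyorder, deriv=1, axis=-1, mode="interp")


def _second_diff_banded(n: int, lam: float) -> np.ndarray:
    """Upper-banded form of lam * D2.T @ D2 for solveh_banded (bandwidth 2)."""
    if n < 3:
        raise ValueError("ALS needs at least 3 bands")
    if n < 6:  # closed-form fill below assumes non-overlapping edges
        d2 = np.diff(np.eye(n), n=2, axis=0)
        full = lam * d2.T @ d2
        ab = np.zeros((3, n))
        for j in range(n):
            for i in range(max(0, j - 2), j + 1):
                ab[2 + i - j, j] = full[i, j]
        return ab
    d = np.zeros(n)
    d[0] = d[-1] = 1.0
    d[1] = d[-2] = 5.0
    d[2:-2] = 6.0
    e1 = np.zeros(n)
    e1[1] = e1[-1] = -2.0
    e1[2:-1] = -4.0
    e2 = np.ones(n)
    ab = np.zeros((3, n))
    ab[0, 2:] = lam * e2[2:]
    ab[1, 1:] = lam * e1[1:]
    ab[2] = lam * d
    return ab


def als_baseline(
    spectrum: np.ndarray,
    lam: float = 1e4,
    p: float = 1e-3,
    n_iter: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Asymmetric-least-squares baseline estimate.

    Iteratively solves ``(W + lam D2'D2) z = W y`` where W holds asymmetric
    weights (p above the baseline, 1−p below) and D2 is the second-difference
    operator; runs a fixed ``n_iter`` iterations.

    Returns ``(baseline, corrected)`` with ``corrected = spectrum − baseline``.
    Accepts a single spectrum or a stack (..., bands); the solve is banded.
    """
    if lam <= 0 or not 0 < p < 1:
        raise ValueError("require lam > 0 and 0 < p < 1")
    y = np.asarray(spectrum, dtype=np.float64)
    single = y.ndim == 1
    flat = np.atleast_2d(y.reshape(-1, y.shape[-1]))
    n = flat.shape[-1]
    penalty = _second_diff_banded(n, lam)
    base = np.empty_like(flat)
    for i, yi in enumerate(flat):
        w = np.ones(n)
        z = yi
        for _ in range(n_iter):
            ab = penalty.copy()
            ab[2] += w
            z = solveh_banded(ab, w * yi)
            w = np.where(yi > z, p, 1.0 - p)
        base[i] = z
    base = base.reshape(y.shape)
    if single:
        base = base.reshape(-1)
    return base, y - base


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum (x − mean) / population std.

    Zero-variance spectra are returned as zeros.
    """
    y = np.asarray(spectrum, dtype=np.float64)
    mean = y.mean(axis=-1, keepdims=True)
    std = y.std(axis=-1, keepdims=True)
    out = np.where(std > 0, (y - mean) / np.where(std > 0, std, 1.0), 0.0)
    return out


def msc(spectra: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Optional, non-default method: each spectrum is regressed on the reference
    (default: mean spectrum of the stack) and corrected as (x − a) / b.
    """
    y = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    ref = y.mean(axis=0) if reference is None else np.asarray(reference, dtype=np.float64)
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    b = (y - y.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = y.mean(axis=1) - b * ref.mean()
    b = np.where(np.abs(b) < 1e-12, 1.0, b)
    out = (y - a[:, None]) / b[:, None]
    return out.reshape(np.asarray(spectra).shape)


def apply_pretreatment(cube: HyperCube, spec: PretreatmentSpec) -> HyperCube:
    """Apply one factorial cell to every valid pixel of a cube.

    Order of composition is fixed: linearization → de-trending →
    multiplicative correction.  Black-masked pixels remain exactly 0.
    """
    params = spec.param_dict
    flat = cube.data.reshape(-1, cube.n_bands).astype(np.float64)
    vflat = cube.valid_mask.reshape(-1)
    x = flat[vflat]

    if spec.linearization == "log_inv":
        x = log_linearize(x)

    if spec.detrend == "poly2":
        x = detrend_poly2(x, cube.wavelengths, degree=int(params["poly_degree"]))
    elif spec.detrend == "sg_deriv1":
        x = sg_first_derivative(
            x, window=int(params["sg_window"]), polyorder=int(params["sg_polyorder"])
        )
    elif spec.detrend == "als":
        _, x = als_baseline(
            x,
            lam=float(params["als_lambda"]),
            p=float(params["als_p"]),
            n_iter=int(params["als_n_iter"]),
        )

    if spec.multiplicative == "snv":
        x = snv(x)

    out = np.zeros_like(flat, dtype=np.float32)
    out[vflat] = x.astype(np.float32)
    meta = dict(cube.meta)
    meta["pretreatment"] = spec.label
    return HyperCube(
        out.reshape(cube.shape), cube.wavelengths.copy(), cube.valid_mask.copy(), meta
    )
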