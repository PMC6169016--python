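"""Stitching of scan strides, noise-object removal and root-length estimation.

Stitching uses phase correlation (normalized cross-power spectrum in the
Fourier domain) seeded by the nominal stride overlap; overlap pixels are
fused by logical OR for binary masks (preserves thin axes crossing seams)
and by mean for grayscale images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.morphology import skeletonize

log = logging.getLogger(__name__)

__all__ = [
    "StitchLayout",
    "RootMask",
    "register_pair",
    "stitch_strides",
    "remove_noise_objects",
    "estimate_root_length",
    "skeleton_length_px",
]

MIN_PEAK_SCORE = 0.05  # registration confidence floor


@dataclass
class StitchLayout:
    offsets: list[tuple[int, int]]  # (row, col) of each stride's origin
    nominal_overlap: float
    peak_scores: list[float] = field(default_factory=list)


@dataclass
class RootMask:
    mask: np.ndarray
    mm_per_px: float = 0.1
    length_cm: float | None = None
    component_stats: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def register_pair(img_a: np.ndarray, img_b: np.ndarray) -> tuple[int, int, float]:
    """Integer shift (dy, dx) such that img_b ≈ img_a translated by (dy, dx).

    Phase correlation: inverse FFT of the normalized cross-power spectrum;
    the peak location is the shift, the peak height the confidence score.
    Flat images return (0, 0) with score 0.
    """
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must share a shape for registration")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0, 0, 0.0
    fa = np.fft.fft2(a - a.mean())
    fb = np.fft.fft2(b - b.mean())
    cross = fb * np.conj(fa)
    mag = np.abs(cross)
    r = np.fft.ifft2(cross / np.maximum(mag, 1e-12)).real
    peak = np.unravel_index(np.argmax(r), r.shape)
    score = float(r[peak])
    dy, dx = (int(p) for p in peak)
    if dy > a.shape[0] // 2:
        dy -= a.shape[0]
    if dx > a.shape[1] // 2:
        dx -= a.shape[1]
    return dy, dx, score


def stitch_strides(
    strides: list[np.ndarray],
    nominal_overlap: float = 0.1,
    binary: bool | None = None,
) -> tuple[np.ndarray, StitchLayout]:
    """Compose left-to-right strides into one image.

    Pairwise registration runs on the nominally overlapping strips; when the
    registration peak is below the confidence floor the nominal offset is
    used instead (warned).  Overlap fusion: OR for binary, mean for
    grayscale.
    """
    if len(strides) < 1:
        raise ValueError("need at least one stride")
    if not 0 < nominal_overlap < 0.5:
        raise ValueError("overlap fraction must be in (0, 0.5)")
    strides = [np.asarray(s) for s in strides]
    if binary is None:
        binary = strides[0].dtype == bool
    if len(strides) == 1:
        return strides[0].copy(), StitchLayout([(0, 0)], nominal_overlap, [1.0])

    offsets = [(0, 0)]
    scores: list[float] = []
    for a, b in zip(strides[:-1], strides[1:]):
        w = a.shape[1]
        step = int(round(w * (1 - nominal_overlap)))
        # strip of a expected to coincide with the left strip of b
        h = min(a.shape[0], b.shape[0])
        strip_a = np.asarray(a[:h, step:], dtype=np.float64)
        strip_b = np.asarray(b[:h, : strip_a.shape[1]], dtype=np.float64)
        dy, dx, score = register_pair(strip_b, strip_a)
        scores.append(score)
        if score < MIN_PEAK_SCORE:
            log.warning(
                "stitch: weak registration peak (%.3f); falling back to nominal offset", score
            )
            dy, dx = 0, 0
        oy, ox = offsets[-1]
        offsets.append((oy + dy, ox + step + dx))

    rows = max(o[0] + s.shape[0] for o, s in zip(offsets, strides)) - min(
        min(o[0] for o in offsets), 0
    )
    row0 = -min(min(o[0] for o in offsets), 0)
    cols = max(o[1] + s.shape[1] for o, s in zip(offsets, strides))
    if binary:
        canvas = np.zeros((rows, cols), dtype=bool)
        for (oy, ox), s in zip(offsets, strides):
            canvas[row0 + oy : row0 + oy + s.shape[0], ox : ox + s.shape[1]] |= s.astype(bool)
    else:
        acc = np.zeros((rows, cols))
        cnt = np.zeros((rows, cols))
        for (oy, ox), s in zip(offsets, strides):
            acc[row0 + oy : row0 + oy + s.shape[0], ox : ox + s.shape[1]] += s
            cnt[row0 + oy : row0 + oy + s.shape[0], ox : ox + s.shape[1]] += 1
        canvas = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    layout = StitchLayout([(row0 + oy, ox) for oy, ox in offsets], nominal_overlap, scores)
    return canvas, layout


def remove_noise_objects(
    mask: np.ndarray,
    min_extent_px: float = 10.0,
    min_area_px: int = 20,
    mm_per_px: float = 0.1,
) -> RootMask:
    """Drop small compact components; keep elongated ones regardless of area.

    A component is removed only when its major-axis length is below
    ``min_extent_px`` AND its area below ``min_area_px`` (8-connectivity).
    """
    m = np.asarray(mask, dtype=bool)
    labels = measure.label(m, connectivity=2)
    out = np.zeros_like(m)
    stats = []
    for region in measure.regionprops(labels):
        keep = not (
            region.axis_major_length < min_extent_px and region.area < min_area_px
        )
        stats.append(
            {
                "area": int(region.area),
                "major_axis": float(region.axis_major_length),
                "kept": keep,
            }
        )
        if keep:
            out[labels == region.label] = True
    return RootMask(out, mm_per_px=mm_per_px, component_stats=stats)


def skeleton_length_px(skeleton: np.ndarray) -> float:
    """Length of a 1-px skeleton in pixel units: orthogonal steps count 1,
    diagonal steps √2; each adjacent pixel pair counted once."""
    s = np.asarray(skeleton, dtype=bool)
    n_orth = int((s[:, :-1] & s[:, 1:]).sum() + (s[:-1, :] & s[1:, :]).sum())
    n_diag = int((s[:-1, :-1] & s[1:, 1:]).sum() + (s[:-1, 1:] & s[1:, :-1]).sum())
    return n_orth + np.sqrt(2.0) * n_diag


def estimate_root_length(mask: RootMask | np.ndarray, mm_per_px: float | None = None) -> float:
    """Skeleton-based root length in cm.

    The mask is skeletonized to its medial axis; length sums orthogonal and
    √2-weighted diagonal adjacency steps, scaled by the pixel pitch.
    """
    if isinstance(mask, RootMask):
        m = mask.mask
        scale = mask.mm_per_px if mm_per_px is None else mm_per_px
    else:
        m = np.asarray(mask, dtype=bool)
        scale = 0.1 if mm_per_px is None else mm_per_px
    if not m.any():
        if isinstance(mask, RootMask):
            mask.length_cm = 0.0
        return 0.0
    skel = skeletonize(m)
    length_cm = skeleton_length_px(skel) * scale / 10.0
    if isinstance(mask, RootMask):
        mask.length_cm = float(length_cm)
    return float(length_cm)
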