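"""Root/soil segmentation on dimensionality-reduced images.

Four algorithms: multilevel Otsu thresholding, k-means, fuzzy c-means and a
two-class SVM trained on ROI pixels.  All unsupervised variants identify the
root class by the "most mode-distant cluster mean" rule: roots are sparse and
contrast-extreme, soil dominates the intensity mode.  Results below a
skewness of 2.5 on the binary mask are flagged as failed (noise-dominated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.filters import threshold_multiotsu
from sklearn.cluster import KMeans
from sklearn.svm import SVC

from .bandselect import ROISet

log = logging.getLogger(__name__)

__all__ = [
    "SegmentationResult",
    "binary_skewness",
    "segment_threshold",
    "segment_kmeans",
    "segment_fuzzy_cmeans",
    "segment_svm",
    "evaluate_segmentation",
    "SKEWNESS_FAIL_THRESHOLD",
]

SKEWNESS_FAIL_THRESHOLD = 2.5


@dataclass
class SegmentationResult:
    mask: np.ndarray  # bool (rows, cols)
    algorithm: str
    spec_id: str = ""
    skewness: float = np.nan
    root_length_cm: float | None = None
    failed: bool = False
    meta: dict = field(default_factory=dict)


def binary_skewness(mask: np.ndarray) -> float:
    """Population skewness of the 0/1 mask; equals (1−2p)/√(p(1−p))."""
    m = np.asarray(mask, dtype=np.float64).ravel()
    if m.size == 0:
        return np.nan
    p = m.mean()
    if p in (0.0, 1.0):
        return np.nan
    return float(stats.skew(m, bias=True))


def _features_to_matrix(features: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    f = np.asarray(features, dtype=np.float64)
    if f.ndim == 2:
        f = f[:, :, None]
    rows, cols, d = f.shape
    return f.reshape(-1, d), (rows, cols)


def _image_mode(values: np.ndarray, n_bins: int = 128) -> float:
    """Center of the fullest histogram bin — the dominant (soil) intensity."""
    v = values[np.isfinite(values)]
    counts, edges = np.histogram(v, bins=n_bins)
    i = int(np.argmax(counts))
    return 0.5 * (edges[i] + edges[i + 1])


def _pick_root_label(labels: np.ndarray, scalar: np.ndarray, n_classes: int) -> int:
    """Most mode-distant class mean wins; ties go to the smaller class."""
    mode = _image_mode(scalar)
    best, best_key = 0, None
    for c in range(n_classes):
        sel = labels == c
        if not sel.any():
            continue
        dist = abs(float(scalar[sel].mean()) - mode)
        key = (dist, -int(sel.sum()))
        if best_key is None or key > best_key:
            best, best_key = c, key
    return best


def _finish(
    mask: np.ndarray, algorithm: str, spec_id: str, meta: dict | None = None
) -> SegmentationResult:
    res = SegmentationResult(
        mask=mask.astype(bool), algorithm=algorithm, spec_id=spec_id, meta=meta or {}
    )
    res.skewness = binary_skewness(res.mask)
    frac = res.mask.mean()
    res.failed = (
        frac in (0.0, 1.0)
        or not np.isfinite(res.skewness)
        or res.skewness < SKEWNESS_FAIL_THRESHOLD
    )
    return res


def segment_threshold(
    image: np.ndarray, n_classes: int = 3, spec_id: str = ""
) -> SegmentationResult:
    """Multilevel Otsu thresholding (maximum between-class variance)."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("thresholding expects a 2-D reduced image")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    finite = img[np.isfinite(img)]
    if finite.size == 0 or np.ptp(finite) == 0 or np.unique(finite).size < n_classes:
        res = SegmentationResult(
            np.zeros(img.shape, bool), "threshold", spec_id, failed=True
        )
        res.meta["reason"] = "degenerate image"
        return res
    thresholds = threshold_multiotsu(img, classes=n_classes)
    labels = np.digitize(img, thresholds)
    root = _pick_root_label(labels.ravel(), img.ravel(), n_classes)
    return _finish(labels == root, "threshold", spec_id, {"thresholds": list(map(float, thresholds))})


def segment_kmeans(
    features: np.ndarray, k: int = 3, seed: int = 0, spec_id: str = ""
) -> SegmentationResult:
    """k-means clustering (k-means++ init, Euclidean, 300 iters, tol 1e-4)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    x, shape = _features_to_matrix(features)
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=10, max_iter=300, tol=1e-4,
        random_state=seed,
    ).fit(x)
    labels = km.labels_
    scalar = x[:, 0] if x.shape[1] > 1 else x.ravel()
    root = _pick_root_label(labels, scalar, k)
    return _finish(
        (labels == root).reshape(shape), "kmeans", spec_id,
        {"centroids": km.cluster_centers_.tolist(), "seed": seed},
    )


def fuzzy_cmeans(
    x: np.ndarray,
    c: int,
    m: float = 2.0,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Standard fuzzy c-means on a (n, d) matrix.

    Returns (memberships (n, c), centroids (c, d), objective trace).
    Memberships follow u_ij ∝ d_ij^(−2/(m−1)) normalized per point; centroids
    are u^m-weighted means.  Points coinciding with a centroid get membership
    1 there.  Converges when max |Δu| < tol.
    """
    if c < 2 or m <= 1:
        raise ValueError("require c >= 2 and fuzzifier m > 1")
    rng = np.random.default_rng(seed)
    n = len(x)
    # init from random distinct data points
    centroids = x[rng.choice(n, size=c, replace=False)].astype(np.float64)
    u = np.full((n, c), 1.0 / c)
    trace: list[float] = []
    power = 2.0 / (m - 1.0)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-(power / 2.0))  # d^(−2/(m−1)) from squared distances
            u_new = inv / inv.sum(axis=1, keepdims=True)
        hit = zero.any(axis=1)
        if hit.any():
            u_new[hit] = 0.0
            u_new[hit, np.argmax(zero[hit], axis=1)] = 1.0
        um = u_new**m
        centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centroids[None]) ** 2).sum(axis=2)
        trace.append(float((um * d2).sum()))
        delta = float(np.abs(u_new - u).max())
        u = u_new
        if delta < tol:
            break
    return u, centroids, trace


def segment_fuzzy_cmeans(
    features: np.ndarray, c: int = 3, m: float = 2.0, seed: int = 0, spec_id: str = ""
) -> SegmentationResult:
    """Fuzzy c-means segmentation; hard mask by maximum membership."""
    x, shape = _features_to_matrix(features)
    u, centroids, trace = fuzzy_cmeans(x, c=c, m=m, seed=seed)
    labels = np.argmax(u, axis=1)
    scalar = x[:, 0] if x.shape[1] > 1 else x.ravel()
    root = _pick_root_label(labels, scalar, c)
    return _finish(
        (labels == root).reshape(shape), "fcm", spec_id,
        {"centroids": centroids.tolist(), "objective": trace, "seed": seed},
    )


def segment_svm(
    features: np.ndarray,
    rois: ROISet,
    kernel: str = "linear",
    C: float = 1.0,
    spec_id: str = "",
    seed: int = 0,
) -> SegmentationResult:
    """Two-class SVM trained on ROI pixels, applied to every pixel.

    Features are standardized by the training-set statistics.
    """
    x, shape = _features_to_matrix(features)
    f3 = x.reshape(shape[0], shape[1], -1)
    xr, xs = rois.extract(f3)
    if len(xr) < 20 or len(xs) < 20:
        raise ValueError("both ROI classes need at least 20 pixels")
    xt = np.vstack([xr, xs])
    yt = np.concatenate([np.ones(len(xr)), np.zeros(len(xs))])
    mu, sd = xt.mean(axis=0), xt.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    clf = SVC(kernel=kernel, C=C, random_state=seed)
    clf.fit((xt - mu) / sd, yt)
    pred = clf.predict((x - mu) / sd)
    return _finish(
        pred.reshape(shape) == 1, "svm", spec_id,
        {"kernel": kernel, "C": C, "train_accuracy": float(clf.score((xt - mu) / sd, yt))},
    )


def evaluate_segmentation(
    result: SegmentationResult, reference_length_cm: float | None = None
) -> dict:
    """Quality gate: binary skewness, failure flag, optional length ratio."""
    skew = binary_skewness(result.mask)
    frac = float(np.asarray(result.mask).mean())
    failed = (
        frac in (0.0, 1.0)
        or not np.isfinite(skew)
        or skew < SKEWNESS_FAIL_THRESHOLD
    )
    result.skewness = skew
    result.failed = failed
    record = {
        "algorithm": result.algorithm,
        "spec_id": result.spec_id,
        "root_fraction": frac,
        "skewness": skew,
        "failed": failed,
    }
    if reference_length_cm is not None and result.root_length_cm is not None:
        record["length_ratio"] = (
            result.root_length_cm / reference_length_cm if reference_length_cm else np.nan
        )
    return record
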