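"""Radial spectral classification of root pixels and decay-time modelling.

Radial classes are distances to the root medial axis binned at the fixed
edges 0–0.1, then 0.2 mm steps up to 1.3 mm, with an open-ended eighth
class.  The radial model is a one-vs-one error-correcting-output-codes
classifier over depth-limited decision trees on ALS-corrected spectra
reduced to five principal components.  Root decay is modelled as
``t = a·exp(b·x)`` for a spectral feature x selected by Bhattacharyya
distance between the initial and final time point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from skimage.morphology import skeletonize
from sklearn.model_selection import train_test_split
from sklearn.multiclass import OneVsOneClassifier
from sklearn.tree import DecisionTreeClassifier

from .bandselect import bhattacharyya_distance, pca_scores
from .hypercube import HyperCube
from .postprocess import RootMask
from .pretreat import als_baseline, sg_first_derivative

log = logging.getLogger(__name__)

__all__ = [
    "RadialClassSpec",
    "RadialModel",
    "DecayModel",
    "label_radial_classes",
    "prepare_chemometric_features",
    "train_radial_model",
    "select_decay_feature",
    "fit_decay_model",
    "map_decay_image",
]

# class edges in mm from the root centre (medial axis); class 8 open-ended
RADIAL_EDGES_MM = (0.1, 0.3, 0.5, 0.7, 0.9, 1.1, 1.3)
N_RADIAL_CLASSES = 8


@dataclass
class RadialClassSpec:
    mm_per_px: float = 0.1
    edges_mm: tuple = RADIAL_EDGES_MM

    @property
    def n_classes(self) -> int:
        return len(self.edges_mm) + 1


@dataclass
class RadialModel:
    classifier: OneVsOneClassifier
    feature_pipeline: str
    train_idx: np.ndarray
    valid_idx: np.ndarray
    r_train: float
    r_valid: float
    allocation_matrix: pd.DataFrame
    explained_variance: np.ndarray | None = None


@dataclass
class DecayModel:
    transform: str = "raw"  # raw | sg_deriv1
    kind: str = "single"  # single | pair_difference
    wavelengths_nm: tuple = ()
    a: float = np.nan
    b: float = np.nan
    r2: float = np.nan
    holdout_days: tuple = ()
    holdout_residuals: tuple = ()
    score_table: pd.DataFrame | None = None
    degenerate: bool = False
    # alternative direction x = c + A·exp(−k·t)
    direction: str = "t_of_x"
    k: float = np.nan

    def predict_time(self, x: np.ndarray) -> np.ndarray:
        t = self.a * np.exp(self.b * np.asarray(x, dtype=float))
        return np.maximum(t, 0.0)

    def feature_values(self, cube: HyperCube, pixels: np.ndarray) -> np.ndarray:
        """Evaluate the selected spectral feature at given (row, col) pixels."""
        spectra = cube.data[pixels[:, 0], pixels[:, 1]].astype(np.float64)
        if self.transform == "sg_deriv1":
            spectra = sg_first_derivative(spectra)
        if self.kind == "single":
            b = cube.band_index(self.wavelengths_nm[0])
            return spectra[:, b]
        b1 = cube.band_index(self.wavelengths_nm[0])
        b2 = cube.band_index(self.wavelengths_nm[1])
        return spectra[:, b1] - spectra[:, b2]


def label_radial_classes(
    mask: RootMask | np.ndarray, spec: RadialClassSpec | None = None
) -> np.ndarray:
    """Per-pixel radial class image (1..8 on root pixels, 0 elsewhere).

    Each root pixel is assigned the distance to the nearest medial-axis
    pixel, converted to mm and binned at the spec's edges.
    """
    spec = spec or RadialClassSpec()
    m = mask.mask if isinstance(mask, RootMask) else np.asarray(mask, dtype=bool)
    mm_per_px = mask.mm_per_px if isinstance(mask, RootMask) else spec.mm_per_px
    out = np.zeros(m.shape, dtype=np.uint8)
    if not m.any():
        return out
    skel = skeletonize(m)
    if not skel.any():  # single-pixel degenerate masks
        skel = m
    dist_px = ndimage.distance_transform_edt(~skel)
    dist_mm = dist_px * mm_per_px
    classes = np.digitize(dist_mm, spec.edges_mm) + 1  # 1..n_classes
    out[m] = classes[m].astype(np.uint8)
    return out


def prepare_chemometric_features(
    cube: HyperCube,
    mask: RootMask | np.ndarray,
    n_components: int = 5,
    als_lambda: float = 1e4,
    als_p: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ALS-corrected root-pixel spectra reduced to principal-component scores.

    Returns (scores (n_root_px, n_components), explained variance ratio,
    root pixel coordinates (n, 2)).
    """
    m = mask.mask if isinstance(mask, RootMask) else np.asarray(mask, dtype=bool)
    if cube.shape[:2] != m.shape:
        raise ValueError("cube and mask are not aligned")
    if cube.n_bands < n_components:
        raise ValueError("cube has fewer bands than requested components")
    pixels = np.argwhere(m & cube.valid_mask)
    spectra = cube.data[pixels[:, 0], pixels[:, 1]].astype(np.float64)
    _, corrected = als_baseline(spectra, lam=als_lambda, p=als_p)
    scores, evr = pca_scores(corrected, n_components)
    return scores, evr, pixels


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.pearsonr(a, b)[0])


def allocation_matrix(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> pd.DataFrame:
    """Per-labelled-class percentage allocation (columns sum to 100) with a
    bottom row giving each class's share of all pixels."""
    cols = {}
    for c in classes:
        sel = y_true == c
        col = np.array([(y_pred[sel] == p).mean() * 100 if sel.any() else np.nan for p in classes])
        cols[c] = col
    df = pd.DataFrame(cols, index=[f"pred_{c}" for c in classes])
    df.loc["pct_total_pixels"] = [
        (y_true == c).mean() * 100 for c in classes
    ]
    return df


def train_radial_model(
    features: np.ndarray,
    labels: np.ndarray,
    split_seed: int = 0,
    max_depth: int = 10,
    feature_pipeline: str = "als+pca5",
) -> RadialModel:
    """Train/validate the one-vs-one ECOC decision-tree radial classifier.

    Stratified 50/50 split; classes with fewer than 2 pixels are dropped
    with a warning.  Reports Pearson r between labelled and predicted class
    index on both halves and the validation allocation matrix.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    keep_classes = [c for c in np.unique(y) if (y == c).sum() >= 2]
    dropped = set(np.unique(y)) - set(keep_classes)
    if dropped:
        log.warning("train_radial_model: dropping classes with < 2 pixels: %s", sorted(dropped))
    sel = np.isin(y, keep_classes)
    x, y = x[sel], y[sel]
    if len(keep_classes) < 2:
        raise ValueError("need at least 2 classes with >= 2 pixels")
    idx = np.arange(len(y))
    train_idx, valid_idx = train_test_split(
        idx, test_size=0.5, random_state=split_seed, stratify=y
    )
    clf = OneVsOneClassifier(
        DecisionTreeClassifier(max_depth=max_depth, random_state=split_seed)
    )
    clf.fit(x[train_idx], y[train_idx])
    pred_t = clf.predict(x[train_idx])
    pred_v = clf.predict(x[valid_idx])
    classes = np.array(sorted(keep_classes))
    return RadialModel(
        classifier=clf,
        feature_pipeline=feature_pipeline,
        train_idx=train_idx,
        valid_idx=valid_idx,
        r_train=_pearson(y[train_idx].astype(float), pred_t.astype(float)),
        r_valid=_pearson(y[valid_idx].astype(float), pred_v.astype(float)),
        allocation_matrix=allocation_matrix(y[valid_idx], pred_v, classes),
    )


def _candidate_features(
    spectra: np.ndarray, wavelengths: np.ndarray, transform: str, kind: str, band_step: int
):
    x = spectra.astype(np.float64)
    if transform == "sg_deriv1":
        x = sg_first_derivative(x)
    nb = x.shape[1]
    if kind == "single":
        for b in range(0, nb, band_step):
            yield (wavelengths[b],), x[:, b]
    else:
        for m in range(0, nb, band_step):
            for n in range(m + band_step, nb, band_step):
                yield (wavelengths[n], wavelengths[m]), x[:, n] - x[:, m]


def select_decay_feature(
    spectra_by_time: dict[float, np.ndarray],
    wavelengths: np.ndarray,
    transforms: tuple = ("raw", "sg_deriv1"),
    kinds: tuple = ("single", "pair_difference"),
    n_bins: int = 128,
    band_step: int = 1,
) -> DecayModel:
    """Pick the spectral feature best separating initial vs final time point.

    Candidates are {raw, first-derivative} × {single wavelength, wavelength
    difference}; the winner maximizes the Bhattacharyya distance between the
    first and last time point's root-pixel feature distributions.
    """
    times = sorted(spectra_by_time)
    if len(times) < 2:
        raise ValueError("need at least 2 time points")
    s0 = np.asarray(spectra_by_time[times[0]], dtype=np.float64)
    s1 = np.asarray(spectra_by_time[times[-1]], dtype=np.float64)
    rows = []
    best = None
    for tr in transforms:
        for kind in kinds:
            feats0 = _candidate_features(s0, wavelengths, tr, kind, band_step)
            feats1 = _candidate_features(s1, wavelengths, tr, kind, band_step)
            for (wl, f0), (_, f1) in zip(feats0, feats1):
                d = bhattacharyya_distance(f0, f1, n_bins=n_bins)
                rows.append({"transform": tr, "kind": kind, "wavelengths": wl, "distance": d})
                if best is None or d > best["distance"]:
                    best = rows[-1]
    table = pd.DataFrame(rows)
    if best is None or best["distance"] <= 0:
        raise ValueError("no discriminative feature: initial and final distributions coincide")
    return DecayModel(
        transform=best["transform"],
        kind=best["kind"],
        wavelengths_nm=tuple(float(w) for w in best["wavelengths"]),
        score_table=table,
    )


def fit_decay_model(
    feature_values: np.ndarray,
    times: np.ndarray,
    holdout: list[float] | None = None,
    model: DecayModel | None = None,
    direction: str = "t_of_x",
) -> DecayModel:
    """Fit the exponential decay model.

    Default direction ``t_of_x`` fits ``t = a·exp(b·x)`` by least squares on
    ``ln t`` vs x (training points only; holdout days are reported as
    residuals).  The alternative ``x_of_t`` fits ``x = c + A·exp(−k·t)`` and
    stores the recovered rate k.
    """
    x = np.asarray(feature_values, dtype=np.float64)
    t = np.asarray(times, dtype=np.float64)
    if x.shape != t.shape:
        raise ValueError("feature values and times must align")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    holdout = list(holdout or [])
    is_hold = np.isin(t, holdout)
    xt, tt = x[~is_hold], t[~is_hold]
    if len(tt) < 3:
        raise ValueError("need at least 3 training time points")
    out = model if model is not None else DecayModel()
    out.direction = direction
    out.holdout_days = tuple(holdout)
    if np.ptp(xt) == 0:
        out.degenerate = True
        log.warning("fit_decay_model: constant feature across times; fit degenerate")
        return out
    if direction == "t_of_x":
        slope, intercept, r, *_ = stats.linregress(xt, np.log(tt))
        out.a = float(np.exp(intercept))
        out.b = float(slope)
        out.r2 = float(r**2)
        if is_hold.any():
            out.holdout_residuals = tuple(
                float(p - o) for p, o in zip(out.predict_time(x[is_hold]), t[is_hold])
            )
    elif direction == "x_of_t":
        def f(tv, c, amp, k):
            return c + amp * np.exp(-k * tv)

        k0 = 1.0 / max(tt.mean(), 1e-9)
        p0 = (float(xt[-1]), float(xt[0] - xt[-1]), k0)
        popt, _ = optimize.curve_fit(f, tt, xt, p0=p0, maxfev=20000)
        out.k = float(popt[2])
        resid = xt - f(tt, *popt)
        ss_tot = float(((xt - xt.mean()) ** 2).sum())
        out.r2 = float(1.0 - (resid**2).sum() / ss_tot) if ss_tot > 0 else np.nan
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return out


def map_decay_image(
    cube: HyperCube, mask: RootMask | np.ndarray, model: DecayModel
) -> np.ndarray:
    """Predicted decay days per root pixel; background = NaN."""
    if not np.isfinite(model.a) or not np.isfinite(model.b):
        raise ValueError("decay model is not fitted")
    m = mask.mask if isinstance(mask, RootMask) else np.asarray(mask, dtype=bool)
    for wl in model.wavelengths_nm:
        if not (cube.wavelengths[0] <= wl <= cube.wavelengths[-1]):
            raise ValueError(f"model wavelength {wl} nm outside cube range")
    out = np.full(m.shape, np.nan, dtype=np.float64)
    pixels = np.argwhere(m & cube.valid_mask)
    if len(pixels) == 0:
        return out
    x = model.feature_values(cube, pixels)
    out[pixels[:, 0], pixels[:, 1]] = model.predict_time(x)
    return out
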