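"""Pre-treatment and wavelength scoring: non-Gaussian indicators,
Bhattacharyya separability, top-band selection, dimensionality reduction."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hypercube import HyperCube

log = logging.getLogger(__name__)

__all__ = [
    "ROISet",
    "BandScoreTable",
    "bhattacharyya_distance",
    "non_gaussian_scores",
    "rank_pretreatments",
    "select_top_bands",
    "reduce_dims",
    "pca_scores",
]

NONGAUSS_CRITERIA = ("skewness", "kurtosis", "entropy", "negentropy", "snr", "kl_divergence")


@dataclass
class ROISet:
    """Hand-labelled root (foreground) and soil (background) pixel sets."""

    root_pixels: np.ndarray  # (n, 2) row, col
    soil_pixels: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.root_pixels = np.asarray(self.root_pixels, dtype=np.intp).reshape(-1, 2)
        self.soil_pixels = np.asarray(self.soil_pixels, dtype=np.intp).reshape(-1, 2)
        if len(self.root_pixels) == 0 or len(self.soil_pixels) == 0:
            raise ValueError("both ROI classes must be non-empty")
        a = {tuple(p) for p in self.root_pixels}
        b = {tuple(p) for p in self.soil_pixels}
        if a & b:
            raise ValueError("root and soil ROIs overlap")

    @classmethod
    def from_masks(cls, root_mask: np.ndarray, soil_mask: np.ndarray, source: str = "") -> "ROISet":
        if np.any(root_mask & soil_mask):
            raise ValueError("root and soil ROI masks overlap")
        return cls(
            np.argwhere(root_mask), np.argwhere(soil_mask), source=source
        )

    def extract(self, image_or_cube: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Values (or spectra) at root and soil ROI pixels."""
        r = image_or_cube[self.root_pixels[:, 0], self.root_pixels[:, 1]]
        s = image_or_cube[self.soil_pixels[:, 0], self.soil_pixels[:, 1]]
        return r, s


@dataclass
class BandScoreTable:
    """Per-band scores by criterion plus optional band-pair difference matrix."""

    wavelengths: np.ndarray
    scores: pd.DataFrame  # index band, columns criteria
    bhattacharyya_diff: np.ndarray | None = None  # (bands, bands), NaN below diagonal
    meta: dict = field(default_factory=dict)

    def ranks(self) -> pd.DataFrame:
        """Per-criterion ranks, 1 = most informative (higher score better,
        except entropy where lower is better)."""
        out = {}
        for c in self.scores.columns:
            col = self.scores[c]
            asc = c == "entropy"
            out[c] = col.rank(ascending=asc, method="average")
        return pd.DataFrame(out, index=self.scores.index)


def bhattacharyya_distance(
    sample_a: np.ndarray, sample_b: np.ndarray, n_bins: int = 128
) -> float:
    """Bhattacharyya distance between two samples via shared histograms.

    Equal-width bins over the pooled min–max range; BC = Σ√(p·q),
    D = −ln(BC); disjoint supports give +inf, identical zero-width pooled
    range gives 0.
    """
    a = np.asarray(sample_a, dtype=np.float64).ravel()
    b = np.asarray(sample_b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p = np.histogram(a, bins=edges)[0] / a.size
    q = np.histogram(b, bins=edges)[0] / b.size
    bc = float(np.sum(np.sqrt(p * q)))
    if bc <= 0:
        return np.inf
    return max(0.0, -np.log(bc))


def _hist_entropy_bits(values: np.ndarray, edges: np.ndarray) -> float:
    p = np.histogram(values, bins=edges)[0] / values.size
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def non_gaussian_scores(values: np.ndarray, n_bins: int = 128) -> dict[str, float]:
    """Six deviation-from-Gaussianity indicators for one sample.

    skewness (3rd standardized moment), excess kurtosis, histogram Shannon
    entropy (bits), negentropy (entropy of the moment-matched Gaussian on the
    same bins minus sample entropy), SNR = mean/std, and KL(sample ‖ fitted
    Gaussian) over the shared bins.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 values")
    mu, sigma = float(x.mean()), float(x.std())
    if sigma == 0:
        raise ValueError("zero-variance sample: scores undefined")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    if edges[0] == edges[-1]:
        raise ValueError("zero-width sample range")
    h_sample = _hist_entropy_bits(x, edges)
    # moment-matched Gaussian discretized on the same bins
    cdf = stats.norm.cdf(edges, loc=mu, scale=sigma)
    q = np.diff(cdf)
    q = q / q.sum()
    qz = q[q > 0]
    h_gauss = float(-np.sum(qz * np.log2(qz)))
    p = np.histogram(x, bins=edges)[0] / x.size
    nz = p > 0
    kl = float(np.sum(p[nz] * np.log(p[nz] / np.maximum(q[nz], 1e-300))))
    return {
        "skewness": float(stats.skew(x)),
        "kurtosis": float(stats.kurtosis(x)),  # excess
        "entropy": h_sample,
        "negentropy": h_gauss - h_sample,
        "snr": mu / sigma,
        "kl_divergence": kl,
    }


def score_bands_nongauss(cube: HyperCube, n_bins: int = 128) -> BandScoreTable:
    """Whole-image non-Gaussian indicators per band (valid pixels only)."""
    flat = cube.data.reshape(-1, cube.n_bands)[cube.valid_mask.reshape(-1)]
    rows = []
    for b in range(cube.n_bands):
        x = flat[:, b]
        try:
            rows.append(non_gaussian_scores(x, n_bins=n_bins))
        except ValueError:
            rows.append({c: np.nan for c in NONGAUSS_CRITERIA})
    df = pd.DataFrame(rows)
    return BandScoreTable(cube.wavelengths.copy(), df)


def score_bands_bhattacharyya(
    cube: HyperCube, rois: ROISet, n_bins: int = 128
) -> np.ndarray:
    """ROI Bhattacharyya distance per single band."""
    r, s = rois.extract(cube.data)
    return np.array(
        [bhattacharyya_distance(r[:, b], s[:, b], n_bins) for b in range(cube.n_bands)]
    )


def score_band_pairs_bhattacharyya(
    cube: HyperCube, rois: ROISet, n_bins: int = 128, band_step: int = 1
) -> np.ndarray:
    """ROI Bhattacharyya distance of difference spectra N_λn − N_λm.

    Upper triangle only (the distance is symmetric for shared binning of the
    negated sample); NaN elsewhere.  ``band_step`` subsamples the band grid
    for large cubes.
    """
    r, s = rois.extract(cube.data)
    nb = cube.n_bands
    out = np.full((nb, nb), np.nan)
    idx = range(0, nb, band_step)
    for m in idx:
        for n in idx:
            if n <= m:
                continue
            out[m, n] = bhattacharyya_distance(
                r[:, n] - r[:, m], s[:, n] - s[:, m], n_bins
            )
    return out


def _midrank(values: np.ndarray, descending: bool = True) -> np.ndarray:
    s = pd.Series(values)
    return s.rank(ascending=not descending, method="average").to_numpy()


def rank_pretreatments(
    cubes_by_spec: dict, rois: ROISet, n_bins: int = 128, band_step: int = 1
) -> pd.DataFrame:
    """Rank pre-treatment variants by three selection criteria.

    For each spec: (a) average midrank over the six non-Gaussian indicators
    evaluated at the spec's most informative band; (b) max single-band ROI
    Bhattacharyya distance; (c) max band-pair difference-spectrum distance.
    Returns a table with absolute values and bracketed-style ranks, plus the
    union of top-3 specs per criterion in ``df.attrs['candidates']``.

    Ranking directions: |skewness|, |kurtosis|, negentropy, KL and SNR high =
    informative; entropy low = informative.
    """
    if len(cubes_by_spec) < 2:
        raise ValueError("need at least 2 pre-treatment variants to rank")
    labels, ng_scores, bh_single, bh_diff = [], [], [], []
    for key, cube in cubes_by_spec.items():
        flat = cube.data.reshape(-1, cube.n_bands)[cube.valid_mask.reshape(-1)]
        if not np.all(np.isfinite(flat)):
            log.warning("rank_pretreatments: spec %s produced non-finite image; excluded", key)
            continue
        labels.append(key)
        tbl = score_bands_nongauss(cube, n_bins=n_bins)
        # best band = max average standardized informativeness across criteria
        z = {}
        for c in NONGAUSS_CRITERIA:
            col = tbl.scores[c].to_numpy()
            if c in ("skewness", "kurtosis"):
                col = np.abs(col)
            if c == "entropy":
                col = -col
            sd = np.nanstd(col)
            z[c] = (col - np.nanmean(col)) / (sd if sd > 0 else 1.0)
        zmat = np.column_stack(list(z.values()))
        best_band = int(np.nanargmax(np.nanmean(zmat, axis=1)))
        ng_scores.append(tbl.scores.iloc[best_band].to_dict())
        bh_single.append(float(np.nanmax(score_bands_bhattacharyya(cube, rois, n_bins))))
        pair = score_band_pairs_bhattacharyya(cube, rois, n_bins, band_step=band_step)
        bh_diff.append(float(np.nanmax(pair)))

    ng = pd.DataFrame(ng_scores, index=labels)
    per_crit_ranks = {}
    for c in NONGAUSS_CRITERIA:
        col = ng[c].to_numpy()
        if c in ("skewness", "kurtosis"):
            col = np.abs(col)
        per_crit_ranks[c] = _midrank(col, descending=(c != "entropy"))
    avg_rank = np.mean(np.column_stack(list(per_crit_ranks.values())), axis=1)

    df = pd.DataFrame(
        {
            "nongauss_avg_rank": avg_rank,
            "nongauss_rank": _midrank(-avg_rank),
            "bhattacharyya_single": bh_single,
            "bhattacharyya_single_rank": _midrank(np.asarray(bh_single)),
            "bhattacharyya_diff": bh_diff,
            "bhattacharyya_diff_rank": _midrank(np.asarray(bh_diff)),
        },
        index=labels,
    )
    cand: list = []
    for col in ("nongauss_rank", "bhattacharyya_single_rank", "bhattacharyya_diff_rank"):
        top3 = df.sort_values(col).index[:3]
        cand.extend(t for t in top3 if t not in cand)
    df.attrs["candidates"] = cand
    return df


def select_top_bands(
    tables: dict[str, np.ndarray], wavelengths: np.ndarray, k: int = 10
) -> list[int]:
    """Select the k bands with highest nomination frequency across criteria.

    Each criterion's score array nominates its k best bands (higher score =
    better); bands are ranked by how many criteria nominated them.  Ties break
    by mean rank across criteria, then by lower wavelength.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    wavelengths = np.asarray(wavelengths, dtype=float)
    nb = wavelengths.size
    freq = np.zeros(nb, dtype=int)
    rank_sum = np.zeros(nb)
    for name, scores in tables.items():
        s = np.asarray(scores, dtype=float)
        if s.size != nb:
            raise ValueError(f"criterion {name!r} has wrong length")
        order = np.argsort(np.where(np.isnan(s), np.inf, -s), kind="stable")
        ranks = np.empty(nb)
        ranks[order] = np.arange(1, nb + 1)
        rank_sum += ranks
        freq[order[:k]] += 1
    mean_rank = rank_sum / max(len(tables), 1)
    candidates = np.nonzero(freq > 0)[0]
    if candidates.size < k:
        warnings.warn(f"only {candidates.size} distinct bands nominated (< k={k})")
    order = sorted(
        candidates, key=lambda b: (-freq[b], mean_rank[b], wavelengths[b])
    )
    return [int(b) for b in order[:k]]


def pca_scores(flat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA via eigendecomposition of the band covariance matrix.

    Returns (scores (n, k), explained variance ratio (k,)).
    """
    x = flat - flat.mean(axis=0)
    cov = (x.T @ x) / max(len(x) - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    total = vals.sum()
    evr = vals[:k] / (total if total > 0 else 1.0)
    return x @ vecs[:, :k], evr


def reduce_dims(
    cube: HyperCube,
    bands: list[int],
    mode: str,
    rois: ROISet | None = None,
    k: int = 5,
):
    """Reduce a cube to a 2-D image or band stack for segmentation.

    Modes: ``best1`` single most informative band; ``mean10`` mean over the
    band list; ``pca1`` principal-component score image with highest ROI
    contrast (PC1 when no ROIs given); ``stack10`` 3-D stack of the band
    list; ``pca_k`` first k score images.
    """
    if mode not in ("best1", "mean10", "pca1", "stack10", "pca_k"):
        raise ValueError(f"unknown reduction mode {mode!r}")
    if mode in ("best1", "mean10", "stack10"):
        if not bands or min(bands) < 0 or max(bands) >= cube.n_bands:
            raise ValueError("band list out of range")
    if mode == "best1":
        return cube.data[:, :, bands[0]].astype(np.float64)
    if mode == "mean10":
        return cube.data[:, :, bands].mean(axis=2).astype(np.float64)
    if mode == "stack10":
        return cube.data[:, :, bands].astype(np.float64)
    # PCA modes: fit on valid pixels, paint scores back into the frame
    flat = cube.data.reshape(-1, cube.n_bands).astype(np.float64)
    vflat = cube.valid_mask.reshape(-1)
    n_comp = max(k, 1) if mode == "pca_k" else min(cube.n_bands, max(k, 3))
    if cube.n_bands < n_comp:
        raise ValueError("fewer bands than requested components")
    scores, evr = pca_scores(flat[vflat], n_comp)
    full = np.zeros((flat.shape[0], n_comp))
    full[vflat] = scores
    imgs = full.reshape(cube.shape[0], cube.shape[1], n_comp)
    if mode == "pca_k":
        return imgs[:, :, :k]
    if rois is not None:
        dists = [
            bhattacharyya_distance(*rois.extract(imgs[:, :, c])) for c in range(n_comp)
        ]
        best = int(np.argmax(dists))
    else:
        best = 0
    return imgs[:, :, best]
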