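"""Configuration-driven orchestration: strategy search and whole-box runs."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import bandselect, postprocess, pretreat, segment
from .bandselect import ROISet
from .hypercube import CalibrationFrames, HyperCube, mask_dead_pixels, normalize, trim_bands
from .postprocess import RootMask
from .pretreat import PretreatmentSpec

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_strategy_search", "run_full_box", "process_box"]

ALGORITHMS = ("threshold", "kmeans", "fcm", "svm")


@dataclass
class PipelineConfig:
    """Validated pipeline settings.

    The defaults reproduce the study's chosen strategy: log-linearization +
    ALS correction, the single most informative band, thresholding (dark
    backgrounds) with fuzzy clustering as the bright-background alternative.
    """

    wavelength_lo: float = 1000.0
    wavelength_hi: float = 1700.0
    dead_pixel_k_mad: float = 20.0
    dead_pixel_abs_threshold: float | None = None
    pretreatments: list = field(default_factory=lambda: [s.label for s in pretreat.enumerate_specs()])
    default_pretreatment: dict = field(
        default_factory=lambda: {"linearization": "log_inv", "detrend": "als", "multiplicative": "none"}
    )
    k_bands: int = 10
    n_hist_bins: int = 128
    band_step: int = 1
    reduction: str = "best1"
    algorithm: str = "threshold"
    n_classes: int = 3
    fuzzifier: float = 2.0
    svm_kernel: str = "linear"
    min_extent_px: float = 10.0
    min_area_px: int = 20
    nominal_overlap: float = 0.1
    mm_per_px: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.wavelength_lo < self.wavelength_hi:
            raise ValueError("wavelength_lo must be < wavelength_hi")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown segmentation algorithm {self.algorithm!r}")
        if self.reduction not in ("best1", "mean10", "pca1", "stack10", "pca_k"):
            raise ValueError(f"unknown reduction {self.reduction!r}")
        if not 0 < self.nominal_overlap < 0.5:
            raise ValueError("nominal_overlap must be in (0, 0.5)")
        if self.k_bands < 1:
            raise ValueError("k_bands must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _prepare(cube_raw: HyperCube, cal: CalibrationFrames, config: PipelineConfig) -> HyperCube:
    cube = normalize(cube_raw, cal)
    cube = trim_bands(cube, config.wavelength_lo, config.wavelength_hi)
    cube, n_dead = mask_dead_pixels(
        cube, k_mad=config.dead_pixel_k_mad, abs_threshold=config.dead_pixel_abs_threshold
    )
    log.info("prepared cube %s: %d dead pixels masked", cube.shape, n_dead)
    return cube


def _segment_reduced(reduced, algo: str, config: PipelineConfig, rois: ROISet | None, spec_id: str):
    if algo == "threshold":
        img = reduced if reduced.ndim == 2 else reduced.mean(axis=2)
        return segment.segment_threshold(img, n_classes=config.n_classes, spec_id=spec_id)
    if algo == "kmeans":
        return segment.segment_kmeans(reduced, k=config.n_classes, seed=config.seed, spec_id=spec_id)
    if algo == "fcm":
        return segment.segment_fuzzy_cmeans(
            reduced, c=config.n_classes, m=config.fuzzifier, seed=config.seed, spec_id=spec_id
        )
    if algo == "svm":
        if rois is None:
            raise ValueError("SVM segmentation requires ROIs")
        return segment.segment_svm(
            reduced, rois, kernel=config.svm_kernel, spec_id=spec_id, seed=config.seed
        )
    raise ValueError(f"unknown algorithm {algo!r}")


def run_strategy_search(
    cube_raw: HyperCube,
    cal: CalibrationFrames,
    rois: ROISet,
    config: PipelineConfig,
    specs: list[PretreatmentSpec] | None = None,
    reductions: tuple = ("best1",),
    algorithms: tuple = ALGORITHMS,
    reference_length_cm: float | None = None,
) -> pd.DataFrame:
    """Grid search pre-treatment × reduction × segmentation on one image section.

    Failures are recorded per combination, never raised.  Deterministic for a
    fixed config seed.  Returns one row per combination with length, skewness
    and failure flags; ``df.attrs['ranking']`` holds the pre-treatment ranking
    table and ``df.attrs['candidates']`` its top-3-union candidate set.
    """
    if specs is None:
        specs = [
            PretreatmentSpec.from_dict(s) if isinstance(s, dict) else _spec_from_label(s)
            for s in config.pretreatments
        ]
    base = _prepare(cube_raw, cal, config)
    cubes_by_spec = {}
    for spec in specs:
        try:
            cubes_by_spec[spec.label] = pretreat.apply_pretreatment(base, spec)
        except Exception as exc:  # noqa: BLE001 - failures are data here
            log.warning("pre-treatment %s failed: %s", spec.label, exc)
    ranking = bandselect.rank_pretreatments(
        cubes_by_spec, rois, n_bins=config.n_hist_bins, band_step=config.band_step
    )

    rows = []
    for label, cube in cubes_by_spec.items():
        scores = bandselect.score_bands_bhattacharyya(cube, rois, config.n_hist_bins)
        bands = bandselect.select_top_bands(
            {"bhattacharyya": scores}, cube.wavelengths, k=config.k_bands
        )
        for red in reductions:
            try:
                reduced = bandselect.reduce_dims(cube, bands, red, rois=rois)
            except Exception as exc:  # noqa: BLE001
                log.warning("reduction %s failed for %s: %s", red, label, exc)
                continue
            for algo in algorithms:
                row = {"pretreatment": label, "reduction": red, "algorithm": algo}
                try:
                    res = _segment_reduced(reduced, algo, config, rois, label)
                    rm = postprocess.remove_noise_objects(
                        res.mask, config.min_extent_px, config.min_area_px, config.mm_per_px
                    )
                    res.root_length_cm = postprocess.estimate_root_length(rm)
                    rec = segment.evaluate_segmentation(res, reference_length_cm)
                    row.update(
                        length_cm=res.root_length_cm,
                        skewness=rec["skewness"],
                        failed=rec["failed"],
                        error="",
                    )
                except Exception as exc:  # noqa: BLE001
                    row.update(length_cm=np.nan, skewness=np.nan, failed=True, error=str(exc))
                rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["ranking"] = ranking
    df.attrs["candidates"] = ranking.attrs["candidates"]
    df.attrs["config_hash"] = config.config_hash()
    return df


def _spec_from_label(label: str) -> PretreatmentSpec:
    lin, det, mult = label.split("+")
    return PretreatmentSpec(lin, det, mult)


def process_box(
    strides_raw: list[HyperCube],
    cals: list[CalibrationFrames],
    config: PipelineConfig,
    rois: ROISet | None = None,
    bands: list[int] | None = None,
) -> tuple[RootMask, dict]:
    """Whole-box pipeline: per-stride normalize → mask → pretreat → reduce →
    segment, then stitch, denoise and measure length."""
    if not strides_raw:
        raise ValueError("no strides given")
    if len(cals) not in (1, len(strides_raw)):
        raise ValueError("need one calibration set, or one per stride")
    spec = PretreatmentSpec.from_dict(config.default_pretreatment)
    masks = []
    stage_log = []
    for i, raw in enumerate(strides_raw):
        cal = cals[i % len(cals)]
        cube = _prepare(raw, cal, config)
        stage_log.append({"stride": i, "stage": "prepare"})
        cube = pretreat.apply_pretreatment(cube, spec)
        stage_log.append({"stride": i, "stage": "pretreat", "spec": spec.label})
        if bands is None:
            if rois is None:
                # fall back: strongest water-band contrast = band with max variance
                scores = cube.data.reshape(-1, cube.n_bands)[cube.valid_mask.ravel()].var(axis=0)
            else:
                scores = bandselect.score_bands_bhattacharyya(cube, rois, config.n_hist_bins)
            stride_bands = bandselect.select_top_bands(
                {"score": scores}, cube.wavelengths, k=config.k_bands
            )
        else:
            stride_bands = bands
        reduced = bandselect.reduce_dims(cube, stride_bands, config.reduction, rois=rois)
        stage_log.append({"stride": i, "stage": "reduce", "bands": stride_bands})
        res = _segment_reduced(reduced, config.algorithm, config, rois, spec.label)
        stage_log.append({"stride": i, "stage": "segment", "skewness": res.skewness})
        masks.append(res.mask)
    stitched, layout = postprocess.stitch_strides(masks, config.nominal_overlap, binary=True)
    stage_log.append({"stage": "stitch", "offsets": layout.offsets})
    root = postprocess.remove_noise_objects(
        stitched, config.min_extent_px, config.min_area_px, config.mm_per_px
    )
    length = postprocess.estimate_root_length(root)
    stage_log.append({"stage": "measure", "length_cm": length})
    skew = segment.binary_skewness(root.mask)
    report = {
        "length_cm": length,
        "skewness": skew,
        "failed": bool(not np.isfinite(skew) or skew < segment.SKEWNESS_FAIL_THRESHOLD),
        "n_strides": len(strides_raw),
        "layout": layout.offsets,
        "config_hash": config.config_hash(),
        "log": stage_log,
    }
    return root, report


def run_full_box(config: PipelineConfig, stride_paths: list[str], white_path: str, dark_path: str,
                 rois: ROISet | None = None) -> tuple[RootMask, dict]:
    """Disk-driven whole-box run from ENVI stride + calibration files."""
    from .hypercube import read_envi_cube

    if not stride_paths:
        raise ValueError("no stride files given")
    try:
        white = read_envi_cube(white_path)
        dark = read_envi_cube(dark_path)
    except Exception as exc:
        raise FileNotFoundError(f"missing or unreadable calibration frames: {exc}") from exc
    cal = CalibrationFrames(white=white.data, dark=dark.data)
    strides = [read_envi_cube(p) for p in stride_paths]
    return process_box(strides, [cal], config, rois=rois)
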