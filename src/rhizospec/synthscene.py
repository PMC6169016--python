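"""Seeded synthetic rhizobox scenes with full ground truth.

Scenes emulate a push-broom NIR setup: 14-bit raw counts with white/dark
calibration frames, a scattering soil background, and root axes whose
reflectance carries water absorption features (~1450 and ~1050 nm) and a
structural-carbohydrate feature (~1630–1690 nm).  Ground truth (mask,
skeleton length, tissue map, decay parameters, stride offsets) is stored so
every pipeline stage can be tested without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .hypercube import CalibrationFrames, HyperCube
from .postprocess import estimate_root_length

__all__ = ["SceneParams", "SceneTruth", "generate_scene", "generate_decay_series", "cut_strides", "PRESETS"]

FULL_SCALE = 16383  # 14-bit camera


@dataclass
class SceneParams:
    height_px: int = 160
    width_px: int = 320
    n_bands: int = 64
    wl_min: float = 900.0
    wl_max: float = 1700.0
    mm_per_px: float = 0.1
    n_primary_roots: int = 3
    root_width_px: tuple = (3, 9)
    lateral_rate: float = 0.02  # branches per primary-axis step
    soil_reflectance: float = 0.42
    root_reflectance: float = 0.44  # base close to soil: contrast lives in the features
    water_depth: float = 0.30  # 1450 nm absorption depth (cortex)
    water_depth_stele_extra: float = 0.10
    water_1050_depth: float = 0.08
    structural_depth: float = 0.10  # 1630-1690 nm feature
    radial_gradient: float = 0.15  # fractional water-depth loss per mm from axis
    soil_texture_scale: float = 8.0  # px, aggregate correlation length
    soil_scatter: float = 0.06  # multiplicative scatter std
    noise_counts: float = 40.0  # additive Gaussian noise on raw counts
    dead_pixel_rate: float = 2e-4
    n_strides: int = 1
    stride_px: int = 320
    overlap: float = 0.1
    dynamic_range_frac: float = 0.85
    root_fraction_range: tuple = (0.02, 0.12)


PRESETS = {
    # full-geometry preset mirroring the acquisition setup
    # (width = stride + 9 nominal steps of 288 px at 10% overlap)
    "paper": SceneParams(
        height_px=320, width_px=2912, n_bands=256, n_strides=10, stride_px=320,
        n_primary_roots=6,
    ),
    # small preset for CI speed
    "ci": SceneParams(height_px=160, width_px=608, n_bands=64, n_strides=2, stride_px=320),
    # few thick axes, for radial-class analyses
    "radial": SceneParams(
        height_px=200, width_px=240, n_bands=64, n_primary_roots=2,
        root_width_px=(25, 31), lateral_rate=0.0,
    ),
}


@dataclass
class SceneTruth:
    raw: HyperCube  # counts
    calibration: CalibrationFrames
    reflectance: HyperCube  # designed noiseless reflectance field
    mask: np.ndarray
    skeleton_length_cm: float
    tissue_map: np.ndarray  # 0 soil, 1 cortex, 2 stele
    radial_distance_mm: np.ndarray
    params: SceneParams
    decay_state: dict = field(default_factory=dict)
    stride_offsets: list = field(default_factory=list)
    dead_pixels: np.ndarray | None = None


def _grow_root_mask(params: SceneParams, rng: np.random.Generator):
    """Random-walk primary axes with stochastic laterals; returns the mask
    and per-pixel axis width map."""
    h, w = params.height_px, params.width_px
    mask = np.zeros((h, w), dtype=bool)
    width_map = np.zeros((h, w), dtype=np.float32)
    wmin, wmax = params.root_width_px

    def draw_axis(r0, c0, direction, width, max_steps):
        r, c = float(r0), float(c0)
        ang = direction
        for _ in range(max_steps):
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < h and 0 <= ci < w):
                break
            rad = max(width / 2.0, 0.5)
            rr, cc = np.ogrid[
                max(ri - int(rad) - 1, 0) : min(ri + int(rad) + 2, h),
                max(ci - int(rad) - 1, 0) : min(ci + int(rad) + 2, w),
            ]
            disk = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
            sub = mask[rr.ravel()[0] : rr.ravel()[-1] + 1, cc.ravel()[0] : cc.ravel()[-1] + 1]
            sub |= disk
            wsub = width_map[rr.ravel()[0] : rr.ravel()[-1] + 1, cc.ravel()[0] : cc.ravel()[-1] + 1]
            np.maximum(wsub, np.where(disk, width, 0), out=wsub)
            ang += rng.normal(0, 0.08)
            r += np.cos(ang)
            c += np.sin(ang)
            if rng.random() < params.lateral_rate and width > wmin + 1:
                lat_ang = ang + rng.choice([-1, 1]) * rng.uniform(0.6, 1.2)
                draw_axis(r, c, lat_ang, max(width * 0.5, wmin), max_steps // 3)

    for _ in range(params.n_primary_roots):
        c0 = rng.uniform(0.1 * w, 0.9 * w)
        width = rng.uniform(wmin, wmax)
        draw_axis(0, c0, rng.normal(0, 0.15), width, int(h * 1.2))
    return mask, width_map


def _gaussian_feature(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def _soil_background(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated multiplicative field emulating aggregate texture."""
    h, w = params.height_px, params.width_px
    raw = rng.normal(0, 1, size=(h, w))
    smooth = ndimage.gaussian_filter(raw, params.soil_texture_scale)
    smooth /= max(smooth.std(), 1e-9)
    return 1.0 + params.soil_scatter * smooth


def generate_scene(
    params: SceneParams | None = None, seed: int = 0, decay_day: float = 0.0,
    decay_k: float = 0.02, decay_k_structural: float = 0.005,
) -> SceneTruth:
    """Generate one seeded scene with raw counts, calibration and truth.

    Water-band depths are scaled by ``exp(-decay_k * decay_day)`` and the
    structural band by the slower ``exp(-decay_k_structural * decay_day)``,
    so a decay series carries its signal in the derivative difference
    between the structural (~1650 nm) and water (~1450 nm) regions.
    """
    params = params or SceneParams()
    rng = np.random.default_rng(seed)
    h, w, nb = params.height_px, params.width_px, params.n_bands
    wl = np.linspace(params.wl_min, params.wl_max, nb)

    mask, _ = _grow_root_mask(params, rng)
    frac = mask.mean()
    lo, hi = params.root_fraction_range
    if frac < lo / 4 or frac > hi * 3:
        raise ValueError(f"infeasible root density: fraction {frac:.4f}")

    from skimage.morphology import skeletonize

    skel = skeletonize(mask)
    dist_mm = ndimage.distance_transform_edt(~skel) * params.mm_per_px
    # stele = inner 30% of the local radius, approximated by a fixed 0.15 mm core
    stele = mask & (dist_mm <= 0.15)
    tissue = np.zeros((h, w), dtype=np.uint8)
    tissue[mask] = 1
    tissue[stele] = 2

    water_scale = float(np.exp(-decay_k * decay_day))
    struct_scale = float(np.exp(-decay_k_structural * decay_day))

    # spectral shapes
    f1450 = _gaussian_feature(wl, 1450.0, 30.0)
    f1050 = _gaussian_feature(wl, 1050.0, 20.0)
    f_struct = _gaussian_feature(wl, 1660.0, 25.0)
    soil_base = params.soil_reflectance * (1.0 + 0.08 * (wl - wl[0]) / (wl[-1] - wl[0]))
    soil_base = soil_base - 0.03 * f1450  # soil moisture leaves a weak water dip

    reflectance = np.empty((h, w, nb), dtype=np.float32)
    soil_field = _soil_background(params, rng)
    reflectance[:] = soil_field[:, :, None] * soil_base[None, None, :]

    root_px = np.argwhere(mask)
    if len(root_px):
        d = dist_mm[root_px[:, 0], root_px[:, 1]]
        grad = np.clip(1.0 - params.radial_gradient * d, 0.3, 1.0)
        depth_1450 = params.water_depth * water_scale * grad
        depth_1450 = depth_1450 + params.water_depth_stele_extra * water_scale * (
            tissue[root_px[:, 0], root_px[:, 1]] == 2
        )
        depth_1050 = params.water_1050_depth * water_scale * grad
        depth_struct = params.structural_depth * struct_scale
        slope = 1.0 + 0.08 * (wl - wl[0]) / (wl[-1] - wl[0])
        spectra = (
            params.root_reflectance * slope[None, :]
            - depth_1450[:, None] * f1450[None, :]
            - depth_1050[:, None] * f1050[None, :]
            - depth_struct * f_struct[None, :]
        )
        scatter = 1.0 + rng.normal(0, 0.02, size=len(root_px))
        reflectance[root_px[:, 0], root_px[:, 1]] = (spectra * scatter[:, None]).astype(
            np.float32
        )

    truth_cube = HyperCube(reflectance.copy(), wl, meta={"mm_per_px": params.mm_per_px})

    # raw counts: R = D + N * (W - D), 14-bit, plus noise, spikes, dead pixels
    white_level = params.dynamic_range_frac * FULL_SCALE
    white_spectrum = white_level * (0.9 + 0.1 * _gaussian_feature(wl, 1300.0, 400.0))
    dark_level = 600.0
    white = np.tile(white_spectrum[None, :], (w, 1))  # (cols, bands)
    dark = np.full((w, nb), dark_level)
    counts = dark[None] + reflectance * (white - dark)[None]
    counts = counts + rng.normal(0, params.noise_counts, size=counts.shape)

    n_dead = rng.binomial(h * w, params.dead_pixel_rate)
    dead = np.zeros((h, w), dtype=bool)
    if n_dead:
        idx = rng.choice(h * w, size=n_dead, replace=False)
        dead.ravel()[idx] = True
        spike = np.where(np.arange(nb) % 2 == 0, 1.0, -1.0) * 0.4 * FULL_SCALE
        counts[dead] = np.clip(counts[dead] + spike[None, :], 0, FULL_SCALE)
    counts = np.clip(counts, 0, FULL_SCALE)

    raw_cube = HyperCube(
        counts.astype(np.float32), wl,
        meta={"mm_per_px": params.mm_per_px, "units": "counts", "seed": seed},
    )
    cal = CalibrationFrames(
        white=np.tile(white[None], (8, 1, 1))
        + rng.normal(0, params.noise_counts / 4, size=(8, w, nb)),
        dark=np.tile(dark[None], (8, 1, 1))
        + rng.normal(0, params.noise_counts / 4, size=(8, w, nb)),
    )

    offsets = stride_offsets(params)
    return SceneTruth(
        raw=raw_cube,
        calibration=cal,
        reflectance=truth_cube,
        mask=mask,
        skeleton_length_cm=estimate_root_length(mask, mm_per_px=params.mm_per_px),
        tissue_map=tissue,
        radial_distance_mm=dist_mm,
        params=params,
        decay_state={
            "day": decay_day,
            "k_water": decay_k,
            "k_structural": decay_k_structural,
            "water_scale": water_scale,
            "structural_scale": struct_scale,
        },
        stride_offsets=offsets,
        dead_pixels=dead,
    )


def stride_offsets(params: SceneParams) -> list[int]:
    """Column origin of each stride for the configured overlap."""
    step = int(round(params.stride_px * (1 - params.overlap)))
    return [i * step for i in range(params.n_strides)]


def cut_strides(image: np.ndarray, params: SceneParams, jitter: int = 0, seed: int = 0):
    """Cut a full-scene 2-D image (or 3-D cube) into overlapping strides.

    With ``jitter`` > 0, stride origins are perturbed by up to ±jitter px in
    both axes (emulating stage positioning error); the true offsets are
    returned alongside the strides.
    """
    rng = np.random.default_rng(seed)
    sw = params.stride_px
    h = image.shape[0]
    margin = int(jitter)
    sh = h - 2 * margin
    strides, offs = [], []
    for i, ox in enumerate(stride_offsets(params)):
        oy = margin
        if jitter and i > 0:
            ox = ox + int(rng.integers(-jitter, jitter + 1))
            oy = margin + int(rng.integers(-jitter, jitter + 1))
        ox = int(np.clip(ox, 0, image.shape[1] - sw))
        strides.append(image[oy : oy + sh, ox : ox + sw])
        offs.append((oy, ox))
    return strides, offs


def stride_calibrations(scene: SceneTruth, offs: list[tuple[int, int]]) -> list[CalibrationFrames]:
    """Per-stride calibration frames: the sensor line only spans the stride."""
    sw = scene.params.stride_px
    return [
        CalibrationFrames(
            scene.calibration.white[:, ox : ox + sw], scene.calibration.dark[:, ox : ox + sw]
        )
        for _, ox in offs
    ]


def generate_decay_series(
    times: list[float],
    k: float = 0.02,
    seed: int = 0,
    params: SceneParams | None = None,
) -> dict[float, SceneTruth]:
    """Scenes sharing one root geometry whose water band decays as exp(−k·t).

    Time 0 (if present) equals the base scene.  The same seed is reused for
    every time point so only the decay state differs.
    """
    if any(t < 0 for t in times) or list(times) != sorted(times):
        raise ValueError("times must be non-negative and ascending")
    return {
        float(t): generate_scene(params=params, seed=seed, decay_day=float(t), decay_k=k)
        for t in times
    }
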