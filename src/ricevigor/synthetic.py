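"""Synthetic multi-view seedling scenes with exact ground truth.

Stands in for net-house photographs: a parametric rice-like plant (tillers
carrying tapered, drooping leaves) is built in 3-D millimetre coordinates
and projected into the three camera views (top, side_0, side_90), so the
per-view silhouettes are mutually consistent.  Each view is rasterized once
into a binary truth mask; the RGB rendering colors exactly those pixels
green (hue 100–140°) on a dark background (< 0.1 brightness) and adds a
white scale marker of known physical length plus mild sensor noise.  Ground
truth (per-view area, top-view hull, caliper, eccentricity) is computed
from the truth masks with the geometry module's own definitions, so
end-to-end checks isolate the segmentation step.

All randomness flows from one explicitly seeded generator per scene;
regenerating with the same seed is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.color import hsv2rgb
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .errors import ValidationError
from .geometry import view_traits
from .io import View, ViewImage
from .segmentation import PlantMask, ScaleCalibration


@dataclass(frozen=True)
class PlantShapeParams:
    """Parametric plant-shape controls (all lengths in mm).

    Defaults emulate a ~3-week-old rice seedling: a few tillers, leaves
    50–150 mm long and 2–4 mm wide, moderate droop.  ``tip_width_mm`` blunts
    the leaf tip to a realistic minimum blade width (camera pixels never
    resolve a mathematically sharp tip); set it to 0 for closed-form shape
    checks against ideal ellipses.
    """

    n_leaves: int = 4
    leaf_length_mm: tuple = (50.0, 150.0)
    leaf_width_mm: tuple = (2.0, 4.0)
    n_tillers: int = 1
    droop_angle_deg: float = 35.0
    stem_height_mm: float = 35.0
    stem_width_mm: float = 2.0
    tip_width_mm: float = 1.0
    curvature: float = 1.0  # 0 = straight leaves
    elevation_deg: float = None  # blade take-off angle from vertical; None = random 25–35°

    def __post_init__(self):
        if not (0 <= self.n_leaves <= 16):
            raise ValidationError("n_leaves must be in [0, 16]")
        if not (0 <= self.n_tillers <= 6):
            raise ValidationError("n_tillers must be in [0, 6]")
        if not (0 <= self.droop_angle_deg <= 85):
            raise ValidationError("droop_angle_deg must be in [0, 85]")
        for lo, hi in (self.leaf_length_mm, self.leaf_width_mm):
            if not (0 < lo <= hi):
                raise ValidationError("leaf length/width ranges must be 0 < lo ≤ hi")
        if self.stem_height_mm <= 0 or self.stem_width_mm <= 0:
            raise ValidationError("stem dimensions must be positive")
        if self.tip_width_mm < 0 or self.curvature < 0:
            raise ValidationError("tip_width_mm and curvature must be ≥ 0")
        if self.elevation_deg is not None and not (0 <= self.elevation_deg <= 90):
            raise ValidationError("elevation_deg must be in [0, 90]")


@dataclass(frozen=True)
class NoiseParams:
    """Sensor-noise controls: additive Gaussian channel noise + salt specks.

    Defaults are mild (high SNR), reflecting controlled imaging under
    high-intensity artificial light.
    """

    gaussian_sigma: float = 0.01
    n_specks: int = 5
    speck_size_px: tuple = (1, 2)

    def __post_init__(self):
        if self.gaussian_sigma < 0 or self.n_specks < 0:
            raise ValidationError("noise levels must be ≥ 0")


ZERO_NOISE = NoiseParams(gaussian_sigma=0.0, n_specks=0)


@dataclass(frozen=True)
class SyntheticScene:
    images: dict  # View -> ViewImage
    truth_masks: dict  # View -> bool ndarray
    truth: dict  # per-view area (mm²) + top-view hull/caliper/eccentricity
    mm_per_pixel: float
    marker_points: tuple  # two (row, col) pixel coordinates
    marker_length_mm: float
    seed: int
    shape_params: PlantShapeParams = field(default=None)
    noise: NoiseParams = field(default=None)


# ---------------------------------------------------------------------------
# 3-D plant model
# ---------------------------------------------------------------------------


def _leaf_centerline(rng, attach, azimuth, length, droop_rad, curvature, elevation, n=80):
    """3-D polyline of one leaf blade, attached at ``attach`` (x, y, z) mm.

    The blade leaves the stem at ``elevation`` from vertical (default ~25–35°)
    and bends toward ``droop_rad`` along its length (simple arc droop).
    """
    s = np.linspace(0.0, 1.0, n)
    if elevation is None:
        alpha0 = np.deg2rad(25.0 + 10.0 * rng.random())
    else:
        alpha0 = np.deg2rad(elevation)
    alpha = alpha0 + curvature * (droop_rad - alpha0) * s**1.5
    ds = length / (n - 1)
    dr = np.sin(alpha) * ds
    dz = np.cos(alpha) * ds
    r = np.concatenate([[0.0], np.cumsum(dr[:-1])])
    z = attach[2] + np.concatenate([[0.0], np.cumsum(dz[:-1])])
    x = attach[0] + r * np.cos(azimuth)
    y = attach[1] + r * np.sin(azimuth)
    return np.stack([x, y, z], axis=1)


def _leaf_half_widths(width, tip_width, n=80):
    """Elliptical blade-width profile with a blunted tip, half-widths in mm."""
    s = np.linspace(0.0, 1.0, n)
    w = 0.5 * width * np.sqrt(np.clip(1.0 - (2.0 * s - 1.0) ** 2, 0.0, None))
    return np.maximum(w, 0.5 * tip_width)


def _build_plant(rng, params: PlantShapeParams):
    """List of (centerline_mm (N,3), half_widths_mm (N,)) tubes."""
    tubes = []
    if params.n_tillers == 0:
        return tubes
    # tiller stems: first vertical, rest tilted outward
    stems = []
    for t in range(params.n_tillers):
        if t == 0:
            tilt, taz = 0.0, 0.0
        else:
            tilt = np.deg2rad(5.0 + 10.0 * rng.random())
            taz = 2.0 * np.pi * rng.random()
        top = np.array(
            [
                params.stem_height_mm * np.sin(tilt) * np.cos(taz),
                params.stem_height_mm * np.sin(tilt) * np.sin(taz),
                params.stem_height_mm * np.cos(tilt),
            ]
        )
        stems.append(top)
        n = 24
        line = np.linspace([0.0, 0.0, 0.0], top, n)
        tubes.append((line, np.full(n, 0.5 * params.stem_width_mm)))
    # leaves: evenly spread azimuths with jitter, round-robin over tillers
    for i in range(params.n_leaves):
        azimuth = 2.0 * np.pi * i / max(params.n_leaves, 1)
        azimuth += rng.normal(0.0, 0.25)
        length = rng.uniform(*params.leaf_length_mm)
        width = rng.uniform(*params.leaf_width_mm)
        droop = np.deg2rad(params.droop_angle_deg * (0.7 + 0.6 * rng.random()))
        stem_top = stems[i % len(stems)]
        attach = stem_top * rng.uniform(0.6, 1.0)
        line = _leaf_centerline(
            rng, attach, azimuth, length, droop, params.curvature, params.elevation_deg
        )
        tubes.append((line, _leaf_half_widths(width, params.tip_width_mm)))
    return tubes


# ---------------------------------------------------------------------------
# Projection and rasterization
# ---------------------------------------------------------------------------


def _project(points_mm, view: View, shape, mm_per_pixel):
    """Orthographic projection of 3-D mm points into (row, col) pixels."""
    h, w = shape
    x, y, z = points_mm[:, 0], points_mm[:, 1], points_mm[:, 2]
    if view is View.TOP:
        rows = h / 2.0 - y / mm_per_pixel
        cols = w / 2.0 + x / mm_per_pixel
    elif view is View.SIDE_0:
        rows = (h - 20.0) - z / mm_per_pixel
        cols = w / 2.0 + x / mm_per_pixel
    else:  # SIDE_90: camera rotated 90° about the vertical axis
        rows = (h - 20.0) - z / mm_per_pixel
        cols = w / 2.0 + y / mm_per_pixel
    return np.stack([rows, cols], axis=1)


def _rasterize_tube(mask, pts_px, half_widths_px):
    """Fill the ribbon around a projected centerline into ``mask`` in place."""
    d = np.gradient(pts_px, axis=0)
    norms = np.hypot(d[:, 0], d[:, 1])
    # carry the previous tangent across zero-length projected steps
    for i in range(len(d)):
        if norms[i] < 1e-9:
            d[i] = d[i - 1] if i else np.array([0.0, 1.0])
            norms[i] = np.hypot(*d[i]) or 1.0
    normal = np.stack([-d[:, 1], d[:, 0]], axis=1) / norms[:, None]
    left = pts_px + normal * half_widths_px[:, None]
    right = pts_px - normal * half_widths_px[:, None]
    poly = np.vstack([left, right[::-1]])
    rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=mask.shape)
    mask[rr, cc] = True
    # round caps where the blade has width at its ends (blunt tips)
    for idx in (0, -1):
        if half_widths_px[idx] > 0.5:
            rr, cc = draw_disk(pts_px[idx], half_widths_px[idx], shape=mask.shape)
            mask[rr, cc] = True


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

_MARKER_ROW = 8
_MARKER_COL0 = 20
_MARKER_HALF_H = 2


def generate_scene(
    seed: int,
    params: PlantShapeParams = None,
    noise: NoiseParams = None,
    image_size=(512, 512),
    mm_per_pixel: float = 0.25,
    marker_length_mm: float = 50.0,
) -> SyntheticScene:
    """Generate one three-view scene with exact per-view truth masks.

    The white scale marker is a horizontal bar whose end-point pixel
    coordinates and physical length are reported for marker-based
    calibration; it is excluded from the truth masks.
    """
    if params is None:
        params = PlantShapeParams()
    if noise is None:
        noise = NoiseParams()
    if mm_per_pixel <= 0:
        raise ValidationError("mm_per_pixel must be positive")
    rng = np.random.default_rng(seed)
    tubes = _build_plant(rng, params)
    h, w = image_size
    marker_px = marker_length_mm / mm_per_pixel
    if _MARKER_COL0 + marker_px >= w:
        raise ValidationError("marker does not fit in the image")
    marker_points = (
        (float(_MARKER_ROW), float(_MARKER_COL0)),
        (float(_MARKER_ROW), float(_MARKER_COL0 + marker_px)),
    )

    truth_masks, images = {}, {}
    for view in View:
        mask = np.zeros(image_size, dtype=bool)
        for line_mm, half_w_mm in tubes:
            pts = _project(line_mm, view, image_size, mm_per_pixel)
            _rasterize_tube(mask, pts, half_w_mm / mm_per_pixel)
        truth_masks[view] = mask

        hsv = np.zeros((h, w, 3))
        hsv[:, :, 2] = 0.05  # dark background, brightness < 0.1
        hue = rng.uniform(100.0, 140.0, size=(h, w)) / 360.0
        val = rng.uniform(0.45, 0.60, size=(h, w))
        hsv[:, :, 0][mask] = hue[mask]
        hsv[:, :, 1][mask] = 0.65
        hsv[:, :, 2][mask] = val[mask]
        # salt specks: small bright-green clusters away from the marker
        for _ in range(noise.n_specks):
            r = int(rng.integers(_MARKER_ROW + 8, h - 2))
            c = int(rng.integers(2, w - 2))
            size = int(rng.integers(noise.speck_size_px[0], noise.speck_size_px[1] + 1))
            hsv[r : r + size, c : c + size] = (120.0 / 360.0, 0.6, 0.5)
        # white scale marker (low saturation, excluded by the sat threshold)
        r0, r1 = _MARKER_ROW - _MARKER_HALF_H, _MARKER_ROW + _MARKER_HALF_H + 1
        hsv[r0:r1, _MARKER_COL0 : int(_MARKER_COL0 + marker_px) + 1] = (0.0, 0.0, 0.98)
        rgb = hsv2rgb(hsv)
        if noise.gaussian_sigma > 0:
            rgb = rgb + rng.normal(0.0, noise.gaussian_sigma, size=rgb.shape)
        rgb = np.clip(rgb, 0.0, 1.0)
        images[view] = ViewImage(
            pixels=rgb,
            view=view,
            genotype="synthetic",
            replicate=1,
            das=14,
            source_path=f"synthetic:seed={seed}:{view.value}",
        )

    cal = ScaleCalibration(mm_per_pixel=mm_per_pixel)
    truth = {
        f"area_{v.value}_mm2": truth_masks[v].sum() * mm_per_pixel**2 for v in View
    }
    top = view_traits(
        PlantMask(
            foreground=truth_masks[View.TOP],
            view=View.TOP,
            calibration=cal,
            threshold_params=None,
        )
    )
    truth.update(
        top_hull_mm2=top.convex_hull_area,
        top_caliper_mm=top.caliper_length,
        top_eccentricity=top.eccentricity,
    )
    return SyntheticScene(
        images=images,
        truth_masks=truth_masks,
        truth=truth,
        mm_per_pixel=mm_per_pixel,
        marker_points=marker_points,
        marker_length_mm=marker_length_mm,
        seed=int(seed),
        shape_params=params,
        noise=noise,
    )


def write_scene(scene: SyntheticScene, outdir) -> dict:
    """Write scene PNGs, truth-mask PNGs (0/255) and a ground-truth JSON."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for view, image in scene.images.items():
        img_path = outdir / f"{view.value}.png"
        iio.imwrite(img_path, (image.pixels * 255).round().astype(np.uint8))
        mask_path = outdir / f"{view.value}_truth.png"
        iio.imwrite(
            mask_path, (scene.truth_masks[view].astype(np.uint8) * 255)
        )
        written[view.value] = str(img_path)
    meta = {
        "seed": scene.seed,
        "mm_per_pixel": scene.mm_per_pixel,
        "marker_points": scene.marker_points,
        "marker_length_mm": scene.marker_length_mm,
        "truth": {k: float(v) for k, v in scene.truth.items()},
        "shape_params": asdict(scene.shape_params),
        "noise": asdict(scene.noise),
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(meta, indent=2))
    written["truth"] = str(truth_path)
    return written
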