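"""Green-tissue segmentation and pixel-to-millimetre calibration.

Shoot tissue is separated from the background by thresholding in
hue/saturation/brightness space (green hue band, minimum saturation and
brightness for the dark pot background; a light-background preset inverts
the brightness logic for flatbed scans).  The raw mask is then cleaned by
morphological opening and removal of small 8-connected components, both of
which only ever remove pixels.  Every mask records the exact threshold
parameters applied and the scale calibration used to convert pixel counts
to mm².
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.morphology import disk, opening

from .errors import CalibrationError, ValidationError
from .io import View, ViewImage

log = logging.getLogger("ricevigor.segmentation")


class CalibrationSource(str, enum.Enum):
    CONFIG = "config"
    MARKER = "marker"


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-millimetre conversion factor and its provenance."""

    mm_per_pixel: float
    source: CalibrationSource = CalibrationSource.CONFIG
    marker_points: tuple = None
    marker_length_mm: float = None

    def __post_init__(self):
        if not (self.mm_per_pixel > 0):
            raise CalibrationError(
                f"mm_per_pixel must be positive, got {self.mm_per_pixel}"
            )
        if CalibrationSource(self.source) is CalibrationSource.MARKER:
            if self.marker_points is None or self.marker_length_mm is None:
                raise CalibrationError(
                    "marker-sourced calibration needs marker_points and "
                    "marker_length_mm"
                )

    @property
    def mm2_per_pixel(self) -> float:
        return self.mm_per_pixel**2


def calibrate_scale(points, known_length: float) -> ScaleCalibration:
    """Derive mm-per-pixel from two marker points of known separation.

    ``points`` is a pair of (row, col) or (x, y) pixel coordinates — only the
    Euclidean distance matters.
    """
    (p1, p2) = points
    if not (known_length > 0):
        raise CalibrationError(f"known_length must be positive, got {known_length}")
    dist = math.dist(tuple(map(float, p1)), tuple(map(float, p2)))
    if dist == 0:
        raise CalibrationError("marker points coincide; calibration is degenerate")
    cal = ScaleCalibration(
        mm_per_pixel=known_length / dist,
        source=CalibrationSource.MARKER,
        marker_points=(tuple(map(float, p1)), tuple(map(float, p2))),
        marker_length_mm=float(known_length),
    )
    log.info(
        "marker calibration: %.2f px over %.2f mm -> %.6f mm/px",
        dist,
        known_length,
        cal.mm_per_pixel,
    )
    return cal


@dataclass(frozen=True)
class SegmentationParams:
    """Hue/saturation/brightness bounds plus mask-cleanup settings.

    Hue is in degrees on [0, 360); saturation and brightness (value) on
    [0, 1].  The defaults are a generic green-on-dark setting; flatbed scans
    of excised leaves on a white platen use :func:`scan_defaults`.
    """

    hue_lo: float = 60.0
    hue_hi: float = 180.0
    sat_min: float = 0.15
    sat_max: float = 1.0
    val_min: float = 0.10
    val_max: float = 1.0
    open_radius: int = 1
    min_component: int = 25

    def __post_init__(self):
        if not (0 <= self.hue_lo < 360 and 0 <= self.hue_hi < 360):
            raise ValidationError("hue bounds must lie in [0, 360)")
        if self.hue_lo >= self.hue_hi:
            raise ValidationError("empty or inverted hue interval")
        for lo, hi, name in (
            (self.sat_min, self.sat_max, "saturation"),
            (self.val_min, self.val_max, "brightness"),
        ):
            if not (0 <= lo <= 1 and 0 <= hi <= 1):
                raise ValidationError(f"{name} bounds must lie in [0, 1]")
            if lo >= hi:
                raise ValidationError(f"empty or inverted {name} interval")
        if self.open_radius < 0 or self.min_component < 0:
            raise ValidationError("cleanup settings must be non-negative")


def scan_defaults() -> SegmentationParams:
    """Parameter preset for flatbed scans: green tissue on a light platen.

    Brightness logic is inverted relative to pot images — near-white platen
    pixels are excluded by the brightness ceiling rather than a floor.
    """
    return SegmentationParams(val_min=0.05, val_max=0.97, min_component=25)


@dataclass(frozen=True)
class PlantMask:
    """Calibrated binary foreground raster from one view."""

    foreground: np.ndarray
    view: View
    calibration: ScaleCalibration
    threshold_params: SegmentationParams

    def __post_init__(self):
        fg = np.asarray(self.foreground, dtype=bool)
        if fg.ndim != 2:
            raise ValidationError("foreground must be a 2-D binary raster")
        object.__setattr__(self, "foreground", fg)
        object.__setattr__(self, "view", View.parse(self.view))

    @property
    def pixel_count(self) -> int:
        return int(self.foreground.sum())

    @property
    def area_mm2(self) -> float:
        return self.pixel_count * self.calibration.mm2_per_pixel


def threshold_hsb(image: ViewImage, params: SegmentationParams) -> np.ndarray:
    """Raw HSB in-bounds mask, before any cleanup.

    A pixel is foreground iff its hue, saturation and brightness each lie
    inside the corresponding closed interval.
    """
    hsv = rgb2hsv(image.pixels)
    hue_deg = hsv[:, :, 0] * 360.0
    sat = hsv[:, :, 1]
    val = hsv[:, :, 2]
    return (
        (hue_deg >= params.hue_lo)
        & (hue_deg <= params.hue_hi)
        & (sat >= params.sat_min)
        & (sat <= params.sat_max)
        & (val >= params.val_min)
        & (val <= params.val_max)
    )


def clean_mask(raw: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Morphological opening then small-component removal (8-connectivity).

    Both steps are anti-extensive: the result is a subset of ``raw``.
    """
    mask = np.asarray(raw, dtype=bool)
    if params.open_radius > 0:
        mask = opening(mask, footprint=disk(params.open_radius))
        mask &= raw  # guard anti-extensivity against border padding
    if params.min_component > 0 and mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            keep = np.flatnonzero(sizes >= params.min_component) + 1
            mask = np.isin(labels, keep)
    return mask


def segment_plant(
    image: ViewImage,
    params: SegmentationParams = None,
    calibration: ScaleCalibration = None,
) -> PlantMask:
    """Segment green shoot tissue from one view and attach calibration.

    Deterministic: identical image and parameters always yield an identical
    mask.  The exact thresholds applied are stored on the result.
    """
    if params is None:
        params = SegmentationParams()
    if calibration is None:
        raise CalibrationError("segment_plant requires a ScaleCalibration")
    raw = threshold_hsb(image, params)
    mask = clean_mask(raw, params)
    log.info(
        "segment %s/%s rep%d das%d: hue=[%g,%g] sat=[%g,%g] val=[%g,%g] "
        "open=%d mincomp=%d -> %d px (raw %d)",
        image.genotype,
        image.view.value,
        image.replicate,
        image.das,
        params.hue_lo,
        params.hue_hi,
        params.sat_min,
        params.sat_max,
        params.val_min,
        params.val_max,
        params.open_radius,
        params.min_component,
        int(mask.sum()),
        int(raw.sum()),
    )
    return PlantMask(
        foreground=mask,
        view=image.view,
        calibration=calibration,
        threshold_params=params,
    )
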