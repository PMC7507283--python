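"""Geometric shoot traits from calibrated masks.

Per-view projected area is the calibrated foreground pixel count.  Top-view
shape descriptors follow the usual plant-imaging definitions: convex hull
area (ground-cover proxy), caliper length (maximum Feret diameter, canopy
size), compactness (projected area / hull area), and an elongation
descriptor from the second central moments (best-fit ellipse eccentricity,
plus the major-axis length in mm).  Whole-plant area by imaging (WPA_i) is
the sum of the three per-view projected areas; whole-plant area by scanning
(WPA_s) is the sum of per-object areas in a flatbed scan.

Pixels are treated as unit squares: the convex hull is taken over pixel
*corners*, so projected_area ≤ convex_hull_area holds exactly and
compactness never exceeds 1.  The caliper length is computed on the hull by
rotating calipers and equals the exact maximum pairwise corner distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import regionprops

from .errors import IncompleteSessionError, ValidationError
from .io import View
from .segmentation import PlantMask

# ---------------------------------------------------------------------------
# Trait records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ViewTraits:
    """Geometric descriptors of a single calibrated view."""

    projected_area: float  # mm²
    convex_hull_area: float  # mm²
    caliper_length: float  # mm
    eccentricity: float  # dimensionless, [0, 1)
    major_axis_length: float  # mm
    compactness: float  # dimensionless, (0, 1] for nonempty masks
    empty: bool = False


@dataclass(frozen=True)
class PlantTraits:
    """Per-plant record: WPA_i plus top-view shape descriptors."""

    wpa_i: float  # mm², summed over the three views
    per_view_areas: dict
    top_view_area: float  # mm²
    top: ViewTraits
    genotype: str = ""
    replicate: int = 1
    das: int = 1
    empty: bool = False


@dataclass(frozen=True)
class ScanRecord:
    """Flatbed-scan record: one area per excised leaf/stem object."""

    object_areas: tuple  # mm² per 8-connected object
    stem_area: float  # mm², summed over stem-labelled objects
    wpa_s: float  # mm², summed over all objects


# ---------------------------------------------------------------------------
# Convex hull and rotating calipers over pixel corners
# ---------------------------------------------------------------------------


def pixel_corner_points(mask: np.ndarray) -> np.ndarray:
    """Corner points (row, col) of all foreground pixels, as an (N, 2) array.

    Each pixel (r, c) contributes corners (r±½, c±½); duplicates shared by
    neighbouring pixels are removed.  Coordinates are doubled internally by
    callers that need exact integer arithmetic.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return np.empty((0, 2))
    offs = np.array([(-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)])
    pts = (np.stack([rows, cols], axis=1)[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    return np.unique(pts, axis=0)


def convex_hull_vertices(points: np.ndarray) -> np.ndarray:
    """CCW-ordered hull vertices of a 2-D point set (≥ 3 non-collinear)."""
    hull = ConvexHull(points)
    return points[hull.vertices]


def rotating_calipers_diameter(vertices: np.ndarray) -> float:
    """Maximum pairwise distance over a convex polygon's vertices.

    Classical antipodal-pairs sweep: for each edge, advance the opposite
    vertex while the triangle area keeps growing; the diameter is realised
    by one of the antipodal pairs visited.  O(h) for h hull vertices.
    """
    pts = np.asarray(vertices, dtype=float)
    h = len(pts)
    if h == 0:
        return 0.0
    if h <= 2:
        return float(np.linalg.norm(pts[0] - pts[-1]))

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    best = 0.0
    k = 1
    for i in range(h):
        j = (i + 1) % h
        # advance k while it moves away from edge (i, j)
        while abs(cross(pts[i], pts[j], pts[(k + 1) % h])) > abs(
            cross(pts[i], pts[j], pts[k])
        ):
            k = (k + 1) % h
        for p in (pts[i], pts[j]):
            d = float(np.hypot(*(p - pts[k])))
            if d > best:
                best = d
    return best


def max_feret_diameter_px(mask: np.ndarray) -> float:
    """Maximum Feret diameter of the foreground, in pixels (corner metric)."""
    pts = pixel_corner_points(mask)
    if len(pts) == 0:
        return 0.0
    try:
        verts = convex_hull_vertices(pts)
    except QhullError:  # collinear corner sets cannot occur for unit squares
        verts = pts
    return rotating_calipers_diameter(verts)


def _hull_area_px(mask: np.ndarray) -> float:
    pts = pixel_corner_points(mask)
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is area
    except QhullError:
        return 0.0


# ---------------------------------------------------------------------------
# Trait extraction
# ---------------------------------------------------------------------------

_EMPTY_TRAITS = ViewTraits(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, empty=True)


def view_traits(mask: PlantMask) -> ViewTraits:
    """Compute the geometric descriptors of one calibrated view.

    Empty masks yield an all-zero record flagged ``empty`` (young seedlings
    may segment to nothing under strict thresholds) so batch runs proceed.
    """
    fg = mask.foreground
    npx = int(fg.sum())
    mmpp = mask.calibration.mm_per_pixel
    if npx == 0:
        return _EMPTY_TRAITS
    projected = npx * mmpp**2
    hull_px2 = _hull_area_px(fg)
    hull = hull_px2 * mmpp**2
    caliper = max_feret_diameter_px(fg) * mmpp
    props = regionprops(fg.astype(np.uint8))[0]
    ecc = float(props.eccentricity)
    major = float(props.axis_major_length) * mmpp
    compact = projected / hull if hull > 0 else 1.0
    return ViewTraits(
        projected_area=projected,
        convex_hull_area=hull,
        caliper_length=caliper,
        eccentricity=ecc,
        major_axis_length=major,
        compactness=compact,
    )


def whole_plant_area_imaging(masks) -> PlantTraits:
    """Assemble WPA_i from exactly one top and two side-view masks.

    ``masks`` is an iterable or view-keyed mapping of :class:`PlantMask`;
    all three view labels must be present.  WPA_i is the plain sum of the
    three projected areas; shape descriptors come from the top view only.
    """
    if hasattr(masks, "values"):
        masks = list(masks.values())
    by_view = {}
    for m in masks:
        if m.view in by_view:
            raise ValidationError(f"duplicate view {m.view.value}")
        by_view[m.view] = m
    missing = [v.value for v in View if v not in by_view]
    if missing:
        raise IncompleteSessionError(f"session is missing view(s): {', '.join(missing)}")
    areas = {v.value: by_view[v].area_mm2 for v in View}
    top = view_traits(by_view[View.TOP])
    return PlantTraits(
        wpa_i=sum(areas.values()),
        per_view_areas=areas,
        top_view_area=areas[View.TOP.value],
        top=top,
        empty=all(by_view[v].pixel_count == 0 for v in View),
    )


def scan_traits(scan_mask: PlantMask, stem_labels=None) -> ScanRecord:
    """Per-object areas and WPA_s from a segmented flatbed scan.

    Each 8-connected component of the (already cleaned) mask becomes one
    object, ordered by first pixel in row-major scan order.  ``stem_labels``
    selects objects (0-based indices) whose summed area is reported as
    stem_area.
    """
    fg = scan_mask.foreground
    mm2 = scan_mask.calibration.mm2_per_pixel
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        if stem_labels:
            raise ValidationError("stem_labels reference a scan with no objects")
        return ScanRecord(object_areas=(), stem_area=0.0, wpa_s=0.0)
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
    areas = tuple(float(s) * mm2 for s in sizes)
    stem = 0.0
    if stem_labels is not None:
        for idx in stem_labels:
            if not (0 <= idx < n):
                raise ValidationError(
                    f"stem label {idx} out of range for {n} scan objects"
                )
            stem += areas[idx]
    return ScanRecord(object_areas=areas, stem_area=stem, wpa_s=float(sum(areas)))
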