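"""Shape descriptors for top-view rosette silhouettes.

A binary mask of one plant on one day is reduced to nine morphometric
parameters grouped by type:

* raw        — area (mm²), perimeter (mm)
* circular   — roundness, roundness2, isotropy (isoperimetric ratios of the
               silhouette, its convex hull, and the leaf-tip polygon)
* symmetric  — eccentricity (moment ellipse), rotational mass symmetry (RMS,
               mismatch between the hull and an equal-area centred disc)
* distance   — compactness (area over hull area), slenderness of leaves
               (SOL, squared skeleton length over area)

All geometry is computed in millimetre coordinates (``x = col·s``,
``y = row·s`` with ``s = mm_per_px``; origin at the top-left pixel corner).
The convex hull is taken over the *outer corners* of foreground pixels, so a
filled k×k square has hull area exactly ``k²`` pixel units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Point, Polygon
from skimage import measure, morphology

__all__ = [
    "BinaryMask",
    "RosetteGeometry",
    "DescriptorSet",
    "EmptyMaskError",
    "DegenerateHullError",
    "measure_area_perimeter",
    "compute_hull",
    "compute_skeleton_length",
    "roundness",
    "roundness2",
    "isotropy",
    "polygon_circularity",
    "eccentricity",
    "rms",
    "compactness",
    "sol",
    "describe",
    "DESCRIPTOR_NAMES",
]

DESCRIPTOR_NAMES = (
    "area",
    "perimeter",
    "roundness",
    "roundness2",
    "isotropy",
    "eccentricity",
    "rms",
    "compactness",
    "sol",
)


class EmptyMaskError(ValueError):
    """Raised when an operation needs foreground pixels and finds none."""

    def __init__(self, plant_id: str | None = None, day: int | None = None):
        self.plant_id = plant_id
        self.day = day
        super().__init__(f"empty-mask (plant_id={plant_id}, day={day})")


class DegenerateHullError(ValueError):
    """Raised when fewer than 3 non-collinear pixels prevent a convex hull."""


@dataclass
class BinaryMask:
    """One plant silhouette on one day.

    ``grid`` is a 2-D boolean raster (rows × cols, origin top-left);
    foreground is 8-connected. ``mm_per_px`` converts pixel lengths to mm.
    """

    grid: np.ndarray
    mm_per_px: float = 1.0
    plant_id: str = ""
    day: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if self.grid.dtype != bool:
            self.grid = self.grid > 0
        if not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be positive")

    @property
    def is_empty(self) -> bool:
        return not bool(self.grid.any())

    def largest_component(self) -> tuple["BinaryMask", int]:
        """Return the largest 8-connected component and the count of
        smaller components that were dropped."""
        labels, n = ndimage.label(self.grid, structure=np.ones((3, 3), int))
        if n <= 1:
            return self, 0
        sizes = ndimage.sum_labels(self.grid, labels, index=range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        return (
            BinaryMask(labels == keep, self.mm_per_px, self.plant_id, self.day),
            n - 1,
        )


@dataclass
class RosetteGeometry:
    """Geometric primitives shared by the descriptors (mm units)."""

    area_mm2: float
    perimeter_mm: float
    hull_polygon: np.ndarray  # (n, 2) x/y vertices, mm
    hull_area_mm2: float
    hull_perimeter_mm: float
    skeleton_length_mm: float
    centroid: tuple[float, float]
    second_central_moments: tuple[float, float, float]  # mu20, mu02, mu11
    tip_polygon: np.ndarray | None = None


@dataclass
class DescriptorSet:
    area: float
    perimeter: float
    roundness: float
    roundness2: float
    isotropy: float
    eccentricity: float
    rms: float
    compactness: float
    sol: float
    qc_flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in DESCRIPTOR_NAMES}


# ---------------------------------------------------------------------------
# raw parameters


def _contour_perimeter_px(grid: np.ndarray, win: int = 5) -> float:
    """Marching-squares boundary length with circular moving-average
    smoothing.  The smoothing removes the staircase bias that makes raw
    sub-pixel contours overestimate smooth boundaries (~5% on a disc)."""
    total = 0.0
    kernel = np.ones(win) / win
    for c in measure.find_contours(grid.astype(float), 0.5):
        closed = np.allclose(c[0], c[-1])
        if closed:
            c = c[:-1]
        if closed and len(c) >= win:
            pad = np.vstack([c[-(win // 2):], c, c[: win // 2]])
            c = np.column_stack(
                [np.convolve(pad[:, 0], kernel, "valid"),
                 np.convolve(pad[:, 1], kernel, "valid")]
            )
        pts = np.vstack([c, c[:1]]) if closed else c
        d = np.diff(pts, axis=0)
        total += float(np.hypot(d[:, 0], d[:, 1]).sum())
    return total


def _edge_pixel_count(grid: np.ndarray) -> float:
    """Foreground pixels 4-adjacent to background (or the frame edge)."""
    padded = np.pad(grid, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return float((grid & ~interior).sum())


def measure_area_perimeter(
    mask: BinaryMask, method: str = "contour"
) -> tuple[float, float]:
    """Area and perimeter in mm² / mm.

    ``method`` selects the boundary-length estimator: ``"contour"``
    (smoothed marching squares, default), ``"crofton"`` (4-direction
    Crofton), or ``"edge_count"`` (raw boundary-pixel count).
    """
    if mask.is_empty:
        raise EmptyMaskError(mask.plant_id, mask.day)
    s = mask.mm_per_px
    area = float(mask.grid.sum()) * s * s
    if method == "contour":
        per = _contour_perimeter_px(mask.grid)
    elif method == "crofton":
        per = float(measure.perimeter_crofton(mask.grid, directions=4))
    elif method == "edge_count":
        per = _edge_pixel_count(mask.grid)
    else:
        raise ValueError(f"unknown perimeter method {method!r}")
    return area, per * s


# ---------------------------------------------------------------------------
# convex hull (outer pixel-corner convention)


def _pixel_corner_points(grid: np.ndarray) -> np.ndarray:
    """Corner points (x, y) of boundary foreground pixels, pixel units."""
    padded = np.pad(grid, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    rows, cols = np.nonzero(grid & ~interior)
    # four corners of each pixel (r, c): x = col offset, y = row offset
    corners = np.empty((4 * len(rows), 2), float)
    for i, (dr, dc) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        corners[i::4, 0] = cols + dc
        corners[i::4, 1] = rows + dr
    return corners


def compute_hull(mask: BinaryMask) -> tuple[np.ndarray, float, float]:
    """Convex hull polygon (mm), its area (mm²) and perimeter (mm)."""
    if mask.is_empty:
        raise EmptyMaskError(mask.plant_id, mask.day)
    pts = _pixel_corner_points(mask.grid) * mask.mm_per_px
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:  # pragma: no cover - needs truly degenerate input
        raise DegenerateHullError(str(exc)) from exc
    poly = pts[hull.vertices]  # counter-clockwise order
    area = float(hull.volume)  # 2-D: volume is area
    d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    per = float(np.hypot(d[:, 0], d[:, 1]).sum())
    if area <= 0:
        raise DegenerateHullError("hull has zero area")
    return poly, area, per


# ---------------------------------------------------------------------------
# skeleton


def _dihedral_canonical(grid: np.ndarray) -> np.ndarray:
    """Canonical representative of a raster under the 8 dihedral transforms
    (rotations by 90° and mirrors), chosen by lexicographic byte order."""
    variants = []
    g = grid
    for _ in range(4):
        variants.extend((g, g[:, ::-1]))
        g = np.rot90(g)
    return min(variants, key=lambda v: (v.shape, v.tobytes()))


def compute_skeleton_length(mask: BinaryMask) -> float:
    """Total medial-axis length in mm.

    The skeleton is taken with ``skimage.morphology.skeletonize``; its
    length is the sum over adjacent skeleton-pixel pairs of 1 (orthogonal)
    or √2 (diagonal) pixel units.  Thinning has a directional bias, so the
    mask is first brought to a canonical orientation; the length is then
    invariant under 90° rotations and mirroring by construction.
    """
    if mask.is_empty:
        raise EmptyMaskError(mask.plant_id, mask.day)
    sk = morphology.skeletonize(_dihedral_canonical(mask.grid))
    if not sk.any():
        return 0.0
    # count each neighbour pair once via directional shifts
    orth = int((sk[:, :-1] & sk[:, 1:]).sum() + (sk[:-1, :] & sk[1:, :]).sum())
    diag = int((sk[:-1, :-1] & sk[1:, 1:]).sum() + (sk[:-1, 1:] & sk[1:, :-1]).sum())
    return (orth + math.sqrt(2.0) * diag) * mask.mm_per_px


# ---------------------------------------------------------------------------
# dimensionless descriptors


def _isoperimetric(area: float, perimeter: float) -> float:
    return 4.0 * math.pi * area / perimeter**2


def roundness(area: float, perimeter: float) -> float:
    """4πA/P²: 1 for a perfect circle, smaller for slender silhouettes.

    Discretisation can push the ratio slightly above 1; values are clipped
    to 1 (callers may flag the clip).
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return min(_isoperimetric(area, perimeter), 1.0)


def roundness2(hull_area: float, hull_perimeter: float) -> float:
    """Isoperimetric ratio of the convex hull, 4πA_h/P_h²."""
    if hull_area <= 0 or hull_perimeter <= 0:
        raise DegenerateHullError("hull area and perimeter must be positive")
    return min(_isoperimetric(hull_area, hull_perimeter), 1.0)


def polygon_circularity(polygon: np.ndarray) -> float:
    """4πA/P² of an arbitrary simple polygon given as (n, 2) vertices."""
    poly = Polygon(np.asarray(polygon, float))
    if poly.area <= 0 or poly.length <= 0:
        raise ValueError("polygon is degenerate")
    return min(_isoperimetric(poly.area, poly.length), 1.0)


def detect_leaf_tips(
    mask: BinaryMask,
    angular_prominence_deg: float = 10.0,
    radial_prominence_frac: float = 0.05,
    n_bins: int = 720,
) -> np.ndarray:
    """Leaf tips as local maxima of centroid distance along the boundary.

    The boundary is resampled onto a uniform angular grid around the
    centroid (taking the outermost radius per bin); peaks need an angular
    separation ≥ ``angular_prominence_deg`` and a radial prominence ≥
    ``radial_prominence_frac`` of the maximum radius.  Returns tip vertices
    (x, y) in mm, ordered by angle; may be empty for tipless silhouettes.
    """
    if mask.is_empty:
        raise EmptyMaskError(mask.plant_id, mask.day)
    s = mask.mm_per_px
    rows, cols = np.nonzero(mask.grid)
    # find_contours puts pixel centres at integer indices; keep the centroid
    # in that same frame so the radial profile commutes with rasters'
    # mirror/rotation symmetries
    cy = rows.mean() * s
    cx = cols.mean() * s
    boundary = []
    for c in measure.find_contours(mask.grid.astype(float), 0.5):
        boundary.append(c)
    if not boundary:
        return np.empty((0, 2))
    pts = np.vstack(boundary)
    x = pts[:, 1] * s
    y = pts[:, 0] * s
    theta = np.arctan2(y - cy, x - cx)
    r = np.hypot(x - cx, y - cy)
    # outermost radius per angular bin
    bins = ((theta + math.pi) / (2 * math.pi) * n_bins).astype(int) % n_bins
    prof = np.full(n_bins, -np.inf)
    np.maximum.at(prof, bins, r)
    # remember the outermost boundary point per bin so tips are actual
    # boundary points (keeps mirror/rotation symmetries raster-exact)
    argmax = np.full(n_bins, -1, int)
    for i in np.argsort(r):  # ascending: last write per bin is the max
        argmax[bins[i]] = i
    filled = prof > -np.inf
    if filled.sum() < 3:
        return np.empty((0, 2))
    # interpolate empty bins on the circle
    idx = np.arange(n_bins)
    prof = np.interp(idx, idx[filled], prof[filled], period=n_bins)
    rmax = prof.max()
    # wrap-around padding so peaks at the cut are found
    pad = n_bins // 4
    ext = np.concatenate([prof[-pad:], prof, prof[:pad]])
    distance = max(1, int(angular_prominence_deg / 360.0 * n_bins))
    peaks, _ = find_peaks(
        ext, distance=distance, prominence=radial_prominence_frac * rmax
    )
    peaks = np.unique(peaks[(peaks >= pad) & (peaks < pad + n_bins)] - pad)
    peaks = peaks[argmax[peaks] >= 0]
    pts_idx = argmax[peaks]
    tips = np.column_stack([x[pts_idx], y[pts_idx]])
    ang = np.arctan2(tips[:, 1] - cy, tips[:, 0] - cx)
    order = np.argsort(ang)
    # shift into the pixel-corner frame used by the other primitives
    return tips[order] + 0.5 * s


def isotropy(tip_polygon: np.ndarray) -> float:
    """Circularity of the leaf-tip polygon, 4πA/P².

    The polygon connects detected leaf tips in angular order around the
    centroid; with many evenly spread tips the value approaches 1.
    """
    tip_polygon = np.asarray(tip_polygon, float)
    if len(tip_polygon) < 3:
        raise ValueError("tip polygon needs at least 3 vertices")
    return polygon_circularity(tip_polygon)


def eccentricity(second_central_moments: tuple[float, float, float]) -> float:
    """Eccentricity of the ellipse sharing the mask's second moments.

    ``sqrt(1 − λ₂/λ₁)`` with λ₁ ≥ λ₂ the eigenvalues of the covariance
    matrix ``[[μ20, μ11], [μ11, μ02]]``. 0 for a circular region, → 1 for a
    degenerate line.
    """
    mu20, mu02, mu11 = second_central_moments
    tr = mu20 + mu02
    if tr <= 0:
        return 0.0
    det = mu20 * mu02 - mu11 * mu11
    disc = max(tr * tr / 4.0 - det, 0.0)
    l1 = tr / 2.0 + math.sqrt(disc)
    l2 = tr / 2.0 - math.sqrt(disc)
    if l1 <= 0:
        return 0.0
    return math.sqrt(max(1.0 - l2 / l1, 0.0))


def rms(
    hull_polygon: np.ndarray,
    centroid: tuple[float, float],
    quad_segs: int = 256,
) -> float:
    """Rotational mass symmetry.

    Ratio of the non-overlapping area between the convex hull and a disc of
    the same area centred at the plant centroid, to their overlapping area:
    ``area(hull Δ disc) / area(hull ∩ disc)``.  0 for a centred disc; grows
    with asymmetry.  The disc is a ``quad_segs``-segment circle polygon
    (relative area error < 1e-4 at the default resolution).
    """
    hull = Polygon(np.asarray(hull_polygon, float))
    if hull.area <= 0:
        raise DegenerateHullError("hull polygon has zero area")
    radius = math.sqrt(hull.area / math.pi)
    disc = Point(centroid).buffer(radius, quad_segs=quad_segs)
    inter = hull.intersection(disc).area
    if inter <= 0:
        return math.inf
    sym = hull.union(disc).area - inter
    return sym / inter


def compactness(area: float, hull_area: float) -> float:
    """Rosette area over convex-hull area, in (0, 1]."""
    if hull_area <= 0:
        raise DegenerateHullError("hull area must be positive")
    return min(area / hull_area, 1.0)


def sol(skeleton_length: float, area: float) -> float:
    """Slenderness of leaves: squared skeleton length over area."""
    if area <= 0:
        raise EmptyMaskError()
    return skeleton_length**2 / area


# ---------------------------------------------------------------------------
# composition


def compute_geometry(mask: BinaryMask, perimeter_method: str = "contour") -> RosetteGeometry:
    """All geometric primitives for one mask (largest component only)."""
    if mask.is_empty:
        raise EmptyMaskError(mask.plant_id, mask.day)
    area, per = measure_area_perimeter(mask, method=perimeter_method)
    hull_poly, hull_area, hull_per = compute_hull(mask)
    # a connected region's boundary is at least as long as its hull's;
    # clamp the estimator so the bound holds on coarse rasters too
    per = max(per, hull_per)
    skel = compute_skeleton_length(mask)
    s = mask.mm_per_px
    rows, cols = np.nonzero(mask.grid)
    cx = (cols.mean() + 0.5) * s
    cy = (rows.mean() + 0.5) * s
    x = (cols + 0.5) * s - cx
    y = (rows + 0.5) * s - cy
    mu20 = float((x * x).mean())
    mu02 = float((y * y).mean())
    mu11 = float((x * y).mean())
    tips = detect_leaf_tips(mask)
    return RosetteGeometry(
        area_mm2=area,
        perimeter_mm=per,
        hull_polygon=hull_poly,
        hull_area_mm2=hull_area,
        hull_perimeter_mm=hull_per,
        skeleton_length_mm=skel,
        centroid=(cx, cy),
        second_central_moments=(mu20, mu02, mu11),
        tip_polygon=tips if len(tips) >= 3 else None,
    )


def describe(mask: BinaryMask, perimeter_method: str = "contour") -> DescriptorSet:
    """Compute the full nine-descriptor set for one mask.

    Deterministic for a fixed mask.  Smaller 8-connected components are
    dropped (flagged ``multi-component``); degenerate tip polygons fall
    back to the convex hull (flagged ``tip-fallback``); isoperimetric
    ratios clipped at 1 are flagged ``clipped``.
    """
    flags: list[str] = []
    if mask.is_empty:
        raise EmptyMaskError(mask.plant_id, mask.day)
    main, dropped = mask.largest_component()
    if dropped:
        flags.append(f"multi-component:{dropped}")
    geo = compute_geometry(main, perimeter_method=perimeter_method)
    r1_raw = _isoperimetric(geo.area_mm2, geo.perimeter_mm)
    r2_raw = _isoperimetric(geo.hull_area_mm2, geo.hull_perimeter_mm)
    if r1_raw > 1 or r2_raw > 1:
        flags.append("clipped")
    if geo.tip_polygon is not None:
        iso = isotropy(geo.tip_polygon)
    else:
        flags.append("tip-fallback")
        iso = r2_raw if r2_raw <= 1 else 1.0
    if geo.second_central_moments[0] + geo.second_central_moments[1] <= 0:
        flags.append("zero-variance")
        ecc = 0.0
    else:
        ecc = eccentricity(geo.second_central_moments)
    return DescriptorSet(
        area=geo.area_mm2,
        perimeter=geo.perimeter_mm,
        roundness=min(r1_raw, 1.0),
        roundness2=min(r2_raw, 1.0),
        isotropy=iso,
        eccentricity=ecc,
        rms=rms(geo.hull_polygon, geo.centroid),
        compactness=compactness(geo.area_mm2, geo.hull_area_mm2),
        sol=sol(geo.skeleton_length_mm, geo.area_mm2),
        qc_flags=flags,
    )
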