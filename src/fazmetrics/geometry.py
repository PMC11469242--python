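"""Core planar geometry for FAZ morphometry.

The foveal avascular zone (FAZ) arrives either as a binary raster mask
(en face OCT-A segmentation) or as a polygon annotation.  Everything
downstream — the classic shape descriptors, the inner-ellipse fit and the
boundary distances — operates on a single canonical representation: a
simple, counter-clockwise polygon with vertices in micrometers.

Conventions
-----------
* x grows rightwards, y grows downwards (image convention), origin at the
  raster top-left; pixel centers sit at ``integer + 0.5``.
* The raster-to-polygon conversion traces the 0.5 iso-contour of the mask,
  so boundaries are placed with sub-pixel accuracy and the perimeter is not
  inflated by pixel staircase artifacts.
* All areas are in µm², lengths in µm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon as ShapelyPolygon
from skimage import measure

from .errors import InvalidPolygonError, NoForegroundError, ParameterError

logger = logging.getLogger(__name__)

#: µm per pixel on a 6 x 6 mm en face grid sampled at 1024 x 1024.
DEFAULT_PIXEL_SIZE_UM = 6000.0 / 1024.0


@dataclass(frozen=True)
class MaskImage:
    """Binary segmentation raster with an isotropic physical pixel scale."""

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ParameterError("mask must be a 2D array")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class FazPolygon:
    """Closed simple polygon (µm coordinates, CCW by positive shoelace sum)."""

    vertices: np.ndarray  # (n, 2) float array of (x_um, y_um)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidPolygonError("polygon needs >= 3 (x, y) vertices")
        # drop an explicitly repeated closing vertex
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise InvalidPolygonError("polygon needs >= 3 distinct vertices")
        if _shoelace(v) < 0:
            v = v[::-1].copy()
        object.__setattr__(self, "vertices", v)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def to_shapely(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.vertices)

    def centroid(self) -> np.ndarray:
        """Area centroid (geometric center) of the polygon interior."""
        v = self.vertices
        x, y = v[:, 0], v[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = cross.sum() / 2.0
        if abs(a) < 1e-12:
            raise InvalidPolygonError("zero-area polygon has no centroid")
        cx = ((x + xn) * cross).sum() / (6.0 * a)
        cy = ((y + yn) * cross).sum() / (6.0 * a)
        return np.array([cx, cy])

    def transformed(self, *, rotation_rad: float = 0.0,
                    translation_um: tuple[float, float] = (0.0, 0.0),
                    scale: float = 1.0) -> "FazPolygon":
        c, s = np.cos(rotation_rad), np.sin(rotation_rad)
        rot = np.array([[c, -s], [s, c]])
        v = scale * (self.vertices @ rot.T) + np.asarray(translation_um)
        return FazPolygon(v)


@dataclass(frozen=True)
class BoundaryCloud:
    """Arc-length-uniform point samples of a closed boundary."""

    points: np.ndarray  # (n, 2)
    source: str = "faz"  # {"faz", "ellipse"}

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 2:
            raise ParameterError("boundary cloud needs >= 2 points")
        object.__setattr__(self, "points", p)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class EquivalentEllipse:
    """Second-moment-equivalent ellipse of a filled region.

    ``major_axis_um`` / ``minor_axis_um`` are *full* axis lengths, matching
    the particle-analysis convention used by the roundness descriptor.
    """

    major_axis_um: float
    minor_axis_um: float
    theta_rad: float = 0.0

    def __post_init__(self) -> None:
        if not (self.major_axis_um >= self.minor_axis_um > 0):
            raise InvalidPolygonError("ellipse axes must satisfy major >= minor > 0")


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def mask_to_polygon(mask: MaskImage, min_component_px: int = 10,
                    smooth_sigma_px: float = 1.0) -> FazPolygon:
    """Trace the largest foreground component of a mask as a µm polygon.

    Interior holes are filled first (the FAZ is a single avascular region);
    the boundary is the 0.5 iso-contour of the filled component after a
    light Gaussian smoothing (``smooth_sigma_px``), which removes the pixel
    staircase so perimeter-based descriptors are not inflated.  Components
    smaller than ``min_component_px`` are ignored with a warning.
    """
    labels, n = ndimage.label(mask.pixels)
    if n == 0:
        raise NoForegroundError("mask has no foreground pixels")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if sizes[order[0]] < min_component_px:
        raise NoForegroundError(
            f"largest component ({int(sizes[order[0]])} px) below "
            f"min_component_px={min_component_px}"
        )
    if n > 1:
        logger.warning(
            "mask has %d foreground components; keeping the largest (%d px), "
            "ignoring %d smaller ones", n, int(sizes[order[0]]), n - 1,
        )
    component = ndimage.binary_fill_holes(labels == order[0] + 1)

    field = component.astype(float)
    if smooth_sigma_px > 0:
        field = ndimage.gaussian_filter(field, smooth_sigma_px)
    # pad so contours of blobs touching the border still close
    padded = np.pad(field, 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=lambda c: abs(_shoelace(c)))
    rows = contour[:, 0] - 1.0  # undo padding
    cols = contour[:, 1] - 1.0
    # find_contours indexes pixel centers at integers; shift to center-at-i+0.5
    x_um = (cols + 0.5) * mask.pixel_size_um
    y_um = (rows + 0.5) * mask.pixel_size_um
    return FazPolygon(np.column_stack([x_um, y_um]))


def polygon_area(p: FazPolygon) -> float:
    """Shoelace area of the polygon interior, µm²."""
    return abs(_shoelace(p.vertices))


def polygon_perimeter(p: FazPolygon) -> float:
    """Total boundary length including the closing edge, µm."""
    v = p.vertices
    return float(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1).sum())


def convex_hull(p: FazPolygon) -> FazPolygon:
    hull = p.to_shapely().convex_hull
    if hull.geom_type != "Polygon":
        raise InvalidPolygonError("degenerate (collinear) vertex set has no 2D hull")
    return FazPolygon(np.asarray(hull.exterior.coords)[:-1])


def _polygon_central_moments(v: np.ndarray) -> tuple[float, float, float, float]:
    """Exact second central moments (mu20, mu11, mu02) and area of the
    polygon interior, via Green's theorem."""
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if a == 0:
        raise InvalidPolygonError("zero-area polygon")
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    ixx = ((x * x + x * xn + xn * xn) * cross).sum() / 12.0
    iyy = ((y * y + y * yn + yn * yn) * cross).sum() / 12.0
    ixy = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum() / 24.0
    mu20 = ixx - a * cx * cx
    mu02 = iyy - a * cy * cy
    mu11 = ixy - a * cx * cy
    if a < 0:  # CW input: flip signs so moments describe the filled region
        a, mu20, mu02, mu11 = -a, -mu20, -mu02, -mu11
    return mu20, mu11, mu02, a


def equivalent_ellipse(p: FazPolygon) -> EquivalentEllipse:
    """Ellipse with the same area and second central moments as the
    polygon interior (region/filled-moment convention)."""
    mu20, mu11, mu02, a = _polygon_central_moments(p.vertices)
    cov = np.array([[mu20, mu11], [mu11, mu02]]) / a
    eigvals, eigvecs = np.linalg.eigh(cov)
    lam_minor, lam_major = float(eigvals[0]), float(eigvals[1])
    if lam_minor <= 0:
        raise InvalidPolygonError("degenerate region: vanishing second moment")
    # for an ellipse with semi-axis s the covariance eigenvalue is s^2 / 4
    major = 4.0 * np.sqrt(lam_major)
    minor = 4.0 * np.sqrt(lam_minor)
    vx, vy = eigvecs[:, 1]
    theta = float(np.arctan2(vy, vx)) % np.pi
    return EquivalentEllipse(major, minor, theta)


def _resample_polyline(v: np.ndarray, centroid: np.ndarray, n_points: int,
                       source: str) -> BoundaryCloud:
    """Uniform arc-length resampling of a closed polyline.

    The start point is the vertex whose direction from the centroid is
    nearest to angle zero (+x axis), which makes the sampling deterministic
    and independent of the input vertex ordering offset.
    """
    ang = np.arctan2(v[:, 1] - centroid[1], v[:, 0] - centroid[0])
    start = int(np.argmin(np.abs(np.angle(np.exp(1j * ang)))))
    v = np.roll(v, -start, axis=0)
    closed = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ParameterError("cannot resample a zero-length boundary")
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    xs = np.interp(targets, s, closed[:, 0])
    ys = np.interp(targets, s, closed[:, 1])
    return BoundaryCloud(np.column_stack([xs, ys]), source=source)


def resample_boundary(shape, n_points: int = 512) -> BoundaryCloud:
    """Sample ``n_points`` arc-length-uniform points on a closed boundary.

    ``shape`` is a :class:`FazPolygon` or an :class:`~fazmetrics.inner_ellipse.Ellipse`.
    """
    if n_points < 8:
        raise ParameterError("n_points must be >= 8")
    if isinstance(shape, FazPolygon):
        return _resample_polyline(shape.vertices, shape.centroid(), n_points, "faz")
    # duck-typed Ellipse: densely polygonize, then resample by arc length
    dense = shape.boundary_points(4096)
    center = np.array([shape.cx_um, shape.cy_um])
    return _resample_polyline(dense, center, n_points, "ellipse")


def signed_distance_to_polygon(points: np.ndarray, poly: ShapelyPolygon,
                               boundary=None) -> np.ndarray:
    """Signed Euclidean distance: positive inside the polygon, negative outside."""
    pts = shapely.points(points[:, 0], points[:, 1])
    if boundary is None:
        boundary = poly.exterior
    d = shapely.distance(pts, boundary)
    inside = shapely.covers(poly, pts)
    return np.where(inside, d, -d)
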