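"""Largest inscribed ("inner") ellipse of a FAZ polygon.

The inner ellipse (iE) models the healthy, pre-dropout avascular zone: an
irregular FAZ is viewed as an ellipse eroded outwards by capillary loss, so
the largest ellipse that still fits inside the segmented boundary is a
proxy for the original shape.  The fit maximizes the ellipse area subject
to (i) the whole ellipse boundary lying inside the polygon and (ii) the
polygon's geometric center lying strictly inside the ellipse.

The problem is non-convex for non-convex polygons, so the fit is a seeded
multi-start of a constrained local optimizer (SLSQP) with the containment
constraint enforced on a finite boundary sample and re-verified afterwards
on a much denser sample.

The derived biomarker ``diff iE`` is the absolute area difference between
the FAZ polygon and its inner ellipse; by containment it equals the area
of the dropout excess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.optimize import NonlinearConstraint, minimize

from .errors import CentroidOutsideError, FitFailedError, ParameterError
from .geometry import FazPolygon, equivalent_ellipse, polygon_area, signed_distance_to_polygon


@dataclass(frozen=True)
class Ellipse:
    """Ellipse with center ``(cx, cy)`` µm, semi-axes ``a >= b`` µm and
    major-axis rotation ``theta`` in [0, π)."""

    cx_um: float
    cy_um: float
    a_um: float
    b_um: float
    theta_rad: float

    def __post_init__(self) -> None:
        if self.b_um <= 0 or self.a_um <= 0:
            raise ParameterError("semi-axes must be positive")
        if self.a_um < self.b_um:
            a, b = self.b_um, self.a_um
            object.__setattr__(self, "a_um", a)
            object.__setattr__(self, "b_um", b)
            object.__setattr__(self, "theta_rad", self.theta_rad + np.pi / 2.0)
        object.__setattr__(self, "theta_rad", float(self.theta_rad) % np.pi)

    def boundary_points(self, n: int) -> np.ndarray:
        """``n`` points on the boundary, uniform in the ellipse parameter."""
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        return _ellipse_points(self.cx_um, self.cy_um, self.a_um, self.b_um,
                               self.theta_rad, t)

    def contains_point(self, x: float, y: float) -> bool:
        return _ellipse_quadratic(self, x, y) < 1.0


@dataclass(frozen=True)
class InnerEllipseFit:
    ellipse: Ellipse
    containment_violation_um: float
    n_restarts_used: int
    converged: bool


def _ellipse_points(cx, cy, a, b, theta, t):
    ct, st = np.cos(t), np.sin(t)
    c, s = np.cos(theta), np.sin(theta)
    x = cx + a * ct * c - b * st * s
    y = cy + a * ct * s + b * st * c
    return np.column_stack([x, y])


def _ellipse_quadratic(e: Ellipse, x: float, y: float) -> float:
    c, s = np.cos(e.theta_rad), np.sin(e.theta_rad)
    dx, dy = x - e.cx_um, y - e.cy_um
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return (u / e.a_um) ** 2 + (v / e.b_um) ** 2


def ellipse_area(e: Ellipse) -> float:
    return float(np.pi * e.a_um * e.b_um)


def fit_inner_ellipse(
    p: FazPolygon,
    n_boundary_samples: int = 256,
    tol_um: float = 0.5,
    n_restarts: int = 8,
    seed: int = 0,
    verify_samples: int = 2048,
    allow_pole_fallback: bool = False,
) -> InnerEllipseFit:
    """Approximate the largest ellipse inscribed in ``p``.

    Parameters
    ----------
    n_boundary_samples
        Ellipse-boundary points on which containment is enforced during
        optimization.
    tol_um
        Maximum tolerated excursion of the verified ellipse boundary
        outside the polygon.
    n_restarts
        Multi-starts: the moment-equivalent ellipse shrunk by half, plus
        seeded jittered variants.  Ties in area are broken towards the
        fit whose center is closest to the polygon centroid.
    allow_pole_fallback
        When the polygon centroid lies outside the polygon (extreme
        concavity), anchor the center constraint at the pole of
        inaccessibility instead of raising :class:`CentroidOutsideError`.
    """
    poly = p.to_shapely()
    boundary = poly.exterior
    centroid = p.centroid()
    if not poly.covers(shapely.points(centroid[0], centroid[1])):
        if not allow_pole_fallback:
            raise CentroidOutsideError(
                "polygon centroid lies outside the polygon; pass "
                "allow_pole_fallback=True to anchor at the pole of inaccessibility"
            )
        import warnings

        warnings.warn("centroid outside polygon: anchoring the inner-ellipse "
                      "center constraint at the pole of inaccessibility")
        from shapely.ops import polylabel

        pole = polylabel(poly, tolerance=0.1)
        centroid = np.array([pole.x, pole.y])

    ee = equivalent_ellipse(p)
    a0, b0 = ee.major_axis_um / 4.0, ee.minor_axis_um / 4.0  # semi-axes * 0.5
    theta0 = ee.theta_rad
    t_con = np.linspace(0.0, 2.0 * np.pi, n_boundary_samples, endpoint=False)
    scale = np.sqrt(polygon_area(p))

    minx, miny, maxx, maxy = poly.bounds
    log_ax_hi = np.log(np.hypot(maxx - minx, maxy - miny))
    log_ax_lo = np.log(max(tol_um, 1e-3))
    bounds = [(minx, maxx), (miny, maxy),
              (log_ax_lo, log_ax_hi), (log_ax_lo, log_ax_hi),
              (-2.0 * np.pi, 2.0 * np.pi)]

    def unpack(z):
        cx, cy, la, lb, th = z
        return cx, cy, np.exp(la), np.exp(lb), th

    def neg_area(z):
        # -a*b, scaled to order 1 (π factor constant)
        return -np.exp(z[2] + z[3]) / scale**2

    def containment(z):
        cx, cy, a, b, th = unpack(z)
        pts = _ellipse_points(cx, cy, a, b, th, t_con)
        return signed_distance_to_polygon(pts, poly, boundary)

    def center_inside(z):
        cx, cy, a, b, th = unpack(z)
        c, s = np.cos(th), np.sin(th)
        dx, dy = centroid[0] - cx, centroid[1] - cy
        u = dx * c + dy * s
        v = -dx * s + dy * c
        return np.array([1.0 - (u / a) ** 2 - (v / b) ** 2])

    constraints = [
        NonlinearConstraint(containment, 0.0, np.inf),
        NonlinearConstraint(center_inside, 1e-6, np.inf),
    ]

    rng = np.random.default_rng(seed)
    starts = [np.array([centroid[0], centroid[1], np.log(a0), np.log(b0), theta0])]
    # guaranteed-feasible start: circle at the anchor, radius just inside
    r_safe = 0.85 * float(boundary.distance(shapely.points(centroid[0], centroid[1])))
    if r_safe > tol_um:
        starts.append(np.array([centroid[0], centroid[1],
                                np.log(r_safe), np.log(r_safe), theta0]))
    for _ in range(max(0, n_restarts - len(starts))):
        jitter = np.array([
            rng.normal(0.0, 0.05 * scale),
            rng.normal(0.0, 0.05 * scale),
            rng.normal(0.0, 0.3),
            rng.normal(0.0, 0.3),
            rng.uniform(-np.pi / 2, np.pi / 2),
        ])
        starts.append(starts[0] + jitter)

    results = []
    for z0 in starts[: max(1, n_restarts)]:
        try:
            res = minimize(
                neg_area, np.clip(z0, [b[0] for b in bounds], [b[1] for b in bounds]),
                method="SLSQP", bounds=bounds, constraints=constraints,
                options={"maxiter": 200, "ftol": 1e-10},
            )
        except (ValueError, OverflowError):
            continue
        cx, cy, a, b, th = unpack(res.x)
        if not np.isfinite([cx, cy, a, b, th]).all():
            continue
        try:
            ell = Ellipse(cx, cy, a, b, th)
        except ParameterError:
            continue
        def violation_of(e: Ellipse) -> float:
            sd = signed_distance_to_polygon(e.boundary_points(verify_samples),
                                            poly, boundary)
            return float(max(0.0, -sd.min()))

        violation = violation_of(ell)
        if violation > tol_um:
            # repair: shrink the axes about the center until contained
            lo, hi, repaired = 0.3, 1.0, None
            for _ in range(12):
                mid = 0.5 * (lo + hi)
                cand = Ellipse(cx, cy, a * mid, b * mid, th)
                if violation_of(cand) <= 0.5 * tol_um:
                    repaired, lo = cand, mid
                else:
                    hi = mid
            if repaired is None:
                continue
            ell = repaired
            violation = violation_of(ell)
        if not ell.contains_point(centroid[0], centroid[1]):
            continue
        dist_c = float(np.hypot(cx - centroid[0], cy - centroid[1]))
        results.append((ellipse_area(ell), dist_c, ell, violation, bool(res.success)))

    if not results:
        raise FitFailedError(
            f"no restart produced a contained ellipse within tol_um={tol_um}"
        )
    # largest area wins; near-ties (within 1e-6 relative) broken by the
    # smallest center-to-centroid distance, for determinism on symmetric input
    best_area = max(r[0] for r in results)
    candidates = [r for r in results if r[0] >= best_area * (1.0 - 1e-6)]
    area, dist_c, ell, violation, success = min(candidates, key=lambda r: r[1])
    return InnerEllipseFit(
        ellipse=ell,
        containment_violation_um=violation,
        n_restarts_used=len(starts),
        converged=success,
    )


def diff_inner_ellipse(p: FazPolygon, fit: InnerEllipseFit) -> float:
    """Absolute area difference |FAZ area − iE area| in µm² (the "diff iE"
    biomarker); with a contained ellipse this is the dropout excess area."""
    return abs(polygon_area(p) - ellipse_area(fit.ellipse))
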