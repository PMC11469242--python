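"""The six established FAZ shape descriptors.

All descriptors except area are dimensionless and invariant under rigid
motion and uniform scaling:

* circularity      = 4π·area / perimeter²            (1 for a circle)
* acircularity     = perimeter / perimeter of the equal-area circle
* roundness        = 4·area / (π·major_axis²)         (major axis of the
                     second-moment-equivalent ellipse, full length)
* solidity         = area / convex-hull area
* convexity        = convex-hull perimeter / perimeter (standard convention,
                     1 for convex shapes, < 1 with boundary irregularity)

Note ``acircularity == circularity**-0.5`` identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidPolygonError, ParameterError
from .geometry import (
    EquivalentEllipse,
    FazPolygon,
    convex_hull,
    equivalent_ellipse,
    polygon_area,
    polygon_perimeter,
)

#: the reciprocal ratio (shape perimeter over hull perimeter); kept for
#: compatibility with reports that print convexity >= 1
CONVEXITY_CONVENTIONS = ("standard", "paper_printed")


@dataclass(frozen=True)
class ClassicMetrics:
    area_um2: float
    perimeter_um: float
    circularity: float
    acircularity: float
    roundness: float
    solidity: float
    convexity: float


def circularity(p: FazPolygon) -> float:
    area = polygon_area(p)
    per = polygon_perimeter(p)
    if per <= 0:
        raise InvalidPolygonError("zero perimeter")
    return 4.0 * np.pi * area / per**2


def acircularity(p: FazPolygon) -> float:
    """Perimeter relative to the perimeter of the circle of equal area."""
    area = polygon_area(p)
    if area <= 0:
        raise InvalidPolygonError("zero area")
    return polygon_perimeter(p) / (2.0 * np.sqrt(np.pi * area))


def roundness(p: FazPolygon, ee: EquivalentEllipse | None = None) -> float:
    if ee is None:
        ee = equivalent_ellipse(p)
    if ee.major_axis_um <= 0:
        raise InvalidPolygonError("degenerate equivalent ellipse")
    return 4.0 * polygon_area(p) / (np.pi * ee.major_axis_um**2)


def solidity(p: FazPolygon) -> float:
    hull_area = polygon_area(convex_hull(p))
    if hull_area <= 0:
        raise InvalidPolygonError("degenerate hull")
    return polygon_area(p) / hull_area


def convexity(p: FazPolygon, convention: str = "standard") -> float:
    """Hull-perimeter ratio.

    ``standard`` returns hull/shape (<= 1, decreasing with irregularity);
    ``paper_printed`` returns the reciprocal shape/hull ratio.
    """
    if convention not in CONVEXITY_CONVENTIONS:
        raise ParameterError(f"unknown convexity convention {convention!r}")
    hull_per = polygon_perimeter(convex_hull(p))
    per = polygon_perimeter(p)
    if hull_per <= 0 or per <= 0:
        raise InvalidPolygonError("degenerate hull")
    ratio = hull_per / per
    return ratio if convention == "standard" else 1.0 / ratio


def classic_metrics(p: FazPolygon, convexity_convention: str = "standard") -> ClassicMetrics:
    """All six descriptors (plus perimeter) in one pass."""
    ee = equivalent_ellipse(p)
    return ClassicMetrics(
        area_um2=polygon_area(p),
        perimeter_um=polygon_perimeter(p),
        circularity=circularity(p),
        acircularity=acircularity(p),
        roundness=roundness(p, ee),
        solidity=solidity(p),
        convexity=convexity(p, convexity_convention),
    )
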