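"""Hausdorff and Chamfer distances between boundary point clouds.

Both metrics compare the FAZ boundary with the fitted inner-ellipse
boundary, each resampled to the same number of arc-length-uniform points.
The Hausdorff distance (µm) reports the single largest deviation; the
Chamfer distance (µm², squared distances) reports an average discrepancy
and is therefore less sensitive to a single deep notch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError
from .geometry import BoundaryCloud, FazPolygon, resample_boundary
from .inner_ellipse import InnerEllipseFit

CD_REDUCTIONS = ("mean_of_directions", "sum_of_directions", "forward_only")


@dataclass(frozen=True)
class DistancePair:
    hd_um: float
    cd_um2: float
    n_faz_points: int
    n_ellipse_points: int


def _points(c) -> np.ndarray:
    pts = c.points if isinstance(c, BoundaryCloud) else np.asarray(c, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ParameterError("point cloud must be a non-empty (n, 2) array")
    return pts


def _nearest_sq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared distance from each point of ``a`` to its nearest point in ``b``."""
    if a.shape[0] * b.shape[0] <= 1024 * 1024:
        d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
        return d2.min(axis=1)
    d, _ = cKDTree(b).query(a)
    return d**2


def directed_hausdorff(a, b) -> float:
    """max over a of the distance to the nearest point of b, µm."""
    pa, pb = _points(a), _points(b)
    return float(np.sqrt(_nearest_sq(pa, pb).max()))


def hausdorff(a, b) -> float:
    """Symmetric Hausdorff distance: the greater of the two directed values."""
    return max(directed_hausdorff(a, b), directed_hausdorff(b, a))


def chamfer(a, b, reduction: str = "mean_of_directions") -> float:
    """Average squared nearest-point distance between two clouds, µm².

    ``mean_of_directions`` (default) averages the two directed means,
    ``sum_of_directions`` adds them, ``forward_only`` uses a→b only.
    """
    if reduction not in CD_REDUCTIONS:
        raise ParameterError(f"unknown chamfer reduction {reduction!r}")
    pa, pb = _points(a), _points(b)
    fwd = float(_nearest_sq(pa, pb).mean())
    if reduction == "forward_only":
        return fwd
    bwd = float(_nearest_sq(pb, pa).mean())
    if reduction == "sum_of_directions":
        return fwd + bwd
    return 0.5 * (fwd + bwd)


def faz_ie_distances(
    p: FazPolygon,
    fit: InnerEllipseFit,
    n_points: int = 512,
    cd_reduction: str = "mean_of_directions",
) -> DistancePair:
    """HD and CD between the FAZ boundary and the inner-ellipse boundary."""
    if n_points < 64:
        raise ParameterError("n_points must be >= 64")
    faz_cloud = resample_boundary(p, n_points)
    ie_cloud = resample_boundary(fit.ellipse, n_points)
    return DistancePair(
        hd_um=hausdorff(faz_cloud, ie_cloud),
        cd_um2=chamfer(faz_cloud, ie_cloud, cd_reduction),
        n_faz_points=len(faz_cloud),
        n_ellipse_points=len(ie_cloud),
    )
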