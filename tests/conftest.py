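"""Shared fixtures: canonical shapes, random polygon factories, and a small
synthetic cohort generated once per session."""

import numpy as np
import pytest

from fazmetrics.geometry import FazPolygon
from fazmetrics.synthetic import CohortSpec, generate_cohort


def regular_polygon(n: int, r: float = 100.0, center=(0.0, 0.0)) -> FazPolygon:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return FazPolygon(np.column_stack([center[0] + r * np.cos(t),
                                       center[1] + r * np.sin(t)]))


def discretized_ellipse(a: float, b: float, theta: float = 0.0,
                        n: int = 512, center=(0.0, 0.0)) -> FazPolygon:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    c, s = np.cos(theta), np.sin(theta)
    return FazPolygon(np.column_stack([center[0] + x * c - y * s,
                                       center[1] + x * s + y * c]))


def random_star_polygon(rng: np.random.Generator, n_vertices: int = 48,
                        base_r: float = 250.0, irregularity: float = 0.3) -> FazPolygon:
    """Star-convex polygon: positive single-valued radius around the origin."""
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = np.full(n_vertices, base_r)
    for k in range(2, 6):
        amp = rng.uniform(0.0, irregularity * base_r / k)
        r += amp * np.cos(k * t + rng.uniform(0.0, 2.0 * np.pi))
    r = np.maximum(r, 0.2 * base_r)
    return FazPolygon(np.column_stack([r * np.cos(t), r * np.sin(t)]))


@pytest.fixture
def unit_square() -> FazPolygon:
    return FazPolygon(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def circle_256() -> FazPolygon:
    return regular_polygon(256, r=100.0)


@pytest.fixture(scope="session")
def signal_cohort():
    """Small synthetic cohort with a real GS -> shape-irregularity effect,
    full metric columns computed with batch-speed fit settings."""
    spec = CohortSpec(n_patients=60, seed=7)
    return generate_cohort(spec, compute_metrics=True)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)

def shoelace_fan_triangulation(vertices: np.ndarray) -> float:
    """Polygon area as the sum of signed fan-triangle areas from vertex 0."""
    total = 0.0
    v0 = vertices[0]
    for i in range(1, len(vertices) - 1):
        a = vertices[i] - v0
        b = vertices[i + 1] - v0
        total += 0.5 * (a[0] * b[1] - a[1] * b[0])
    return abs(total)


def gift_wrapping_hull(points: np.ndarray) -> np.ndarray:
    """Jarvis-march convex hull, CCW vertex order."""
    pts = np.unique(np.round(points, 12), axis=0)
    start = min(range(len(pts)), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % len(pts)
        for j in range(len(pts)):
            if j == cur:
                continue
            u = pts[cand] - pts[cur]
            w = pts[j] - pts[cur]
            cross = u[0] * w[1] - u[1] * w[0]
            if cross < 0 or (cross == 0 and
                             np.linalg.norm(pts[j] - pts[cur]) >
                             np.linalg.norm(pts[cand] - pts[cur])):
                cand = j
        if cand == start:
            break
        hull.append(cand)
    return pts[hull]


def brute_force_nearest_sq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.empty(len(a))
    for i, pa in enumerate(a):
        out[i] = min(float((pa[0] - pb[0]) ** 2 + (pa[1] - pb[1]) ** 2) for pb in b)
    return out
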