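"""Synthetic FAZ shapes and cohorts with known ground truth.

A healthy FAZ is modeled as a smooth ellipse; coronary-disease-associated
capillary dropout is modeled as *outward* radial protrusions of the
boundary (capillary loss enlarges the avascular zone locally), realized as
raised-cosine bumps at random angles.  The base ellipse is therefore always
contained in the generated shape, so the true largest inscribed ellipse is
at least the base ellipse — which is what makes the family a ground-truth
testbed for the inner-ellipse biomarkers.

The cohort generator couples shape irregularity to a simulated Gensini
score drawn from a zero-inflated Poisson (structural zeros are the
CAD-free patients), with a stronger effect in left than right eyes and
age/sex/diabetes covariates that drift with disease severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .errors import SpecError
from .gensini import severity_groups
from .geometry import DEFAULT_PIXEL_SIZE_UM, FazPolygon, MaskImage

#: half-width of the default 6 x 6 mm scan, µm — shapes are centered here
GRID_CENTER_UM = 3000.0


@dataclass(frozen=True)
class ShapeSpec:
    """One synthetic FAZ: base ellipse + outward dropout notches + noise.

    Defaults give a realistic FAZ: ~0.28 mm² area, mild irregularity.
    Depths/widths may be scalars (shared) or per-notch sequences.
    """

    base_a_um: float = 330.0
    base_b_um: float = 270.0
    base_theta_rad: float = 0.0
    n_notches: int = 4
    notch_depth_um: float | tuple = 60.0
    notch_width_rad: float | tuple = 0.5
    boundary_noise_um: float = 2.0
    n_vertices: int = 512
    seed: int = 0

    def depths(self) -> np.ndarray:
        d = np.broadcast_to(np.asarray(self.notch_depth_um, float), (self.n_notches,))
        if (d < 0).any():
            raise SpecError("notch depths must be nonnegative (outward only)")
        return d

    def widths(self) -> np.ndarray:
        w = np.broadcast_to(np.asarray(self.notch_width_rad, float), (self.n_notches,))
        if (w <= 0).any():
            raise SpecError("notch widths must be positive")
        if w.sum() > 2.0 * np.pi:
            raise SpecError("total notch width exceeds the full circle")
        return w


@dataclass(frozen=True)
class SyntheticShape:
    polygon: FazPolygon
    mask: MaskImage
    truth: dict


def _ellipse_radius(phi: np.ndarray, a: float, b: float, theta: float) -> np.ndarray:
    psi = phi - theta
    return a * b / np.sqrt((b * np.cos(psi)) ** 2 + (a * np.sin(psi)) ** 2)


def _wrap(x: np.ndarray) -> np.ndarray:
    return (x + np.pi) % (2.0 * np.pi) - np.pi


def _bump_profile(phi, centers, depths, widths):
    total = np.zeros_like(phi)
    for c, d, w in zip(centers, depths, widths):
        u = _wrap(phi - c)
        inside = np.abs(u) <= w / 2.0
        total[inside] += d * 0.5 * (1.0 + np.cos(2.0 * np.pi * u[inside] / w))
    return total


def _place_notch_angles(rng, widths) -> np.ndarray:
    """Seeded non-overlapping notch centers (rejection sampling)."""
    n = len(widths)
    if n == 0:
        return np.empty(0)
    for _ in range(2000):
        centers = np.sort(rng.uniform(0.0, 2.0 * np.pi, n))
        gaps_ok = True
        for i in range(n):
            j = (i + 1) % n
            if j == i:
                continue
            gap = (centers[j] - centers[i]) % (2.0 * np.pi)
            if gap < (widths[i] + widths[j]) / 2.0:
                gaps_ok = False
                break
        if gaps_ok:
            return centers
    raise SpecError("could not place non-overlapping notches; reduce count/width")


def generate_shape(spec: ShapeSpec,
                   pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                   grid_px: int = 1024) -> SyntheticShape:
    """Deterministic (seeded) synthetic FAZ with analytic truth bookkeeping.

    ``truth`` carries the base ellipse, the quadrature-integrated planned
    excess area of the notches, and the notch geometry actually used.
    Boundary noise is a smooth random radial perturbation clipped outward
    so the base ellipse stays contained.
    """
    rng = np.random.default_rng(spec.seed)
    depths, widths = spec.depths(), spec.widths()
    centers = _place_notch_angles(rng, widths)

    # low-order Fourier noise: smooth, zero-mean, std ~ boundary_noise_um
    n_modes = 8
    amp = rng.normal(0.0, 1.0, n_modes)
    phase = rng.uniform(0.0, 2.0 * np.pi, n_modes)

    def noise(phi):
        if spec.boundary_noise_um == 0:
            return np.zeros_like(phi)
        modes = np.arange(2, 2 + n_modes)
        s = sum(a * np.cos(k * phi + p) for a, k, p in zip(amp, modes, phase))
        return spec.boundary_noise_um * s / np.sqrt(n_modes / 2.0)

    def radius(phi):
        r_e = _ellipse_radius(phi, spec.base_a_um, spec.base_b_um, spec.base_theta_rad)
        r = r_e + _bump_profile(phi, centers, depths, widths) + noise(phi)
        return np.maximum(r, r_e)  # outward-only: base ellipse stays inside

    phi_v = np.linspace(0.0, 2.0 * np.pi, spec.n_vertices, endpoint=False)
    r_v = radius(phi_v)
    cx = cy = GRID_CENTER_UM
    vertices = np.column_stack([cx + r_v * np.cos(phi_v), cy + r_v * np.sin(phi_v)])
    polygon = FazPolygon(vertices)

    # planned excess area of the bumps alone (noise-free), by dense quadrature
    phi_q = np.linspace(0.0, 2.0 * np.pi, 1 << 15, endpoint=False)
    r_e_q = _ellipse_radius(phi_q, spec.base_a_um, spec.base_b_um, spec.base_theta_rad)
    r_b_q = r_e_q + _bump_profile(phi_q, centers, depths, widths)
    excess = 0.5 * np.trapezoid(
        np.append(r_b_q**2 - r_e_q**2, r_b_q[0] ** 2 - r_e_q[0] ** 2),
        dx=phi_q[1] - phi_q[0],
    )

    # rasterize (vertices in pixel coordinates; pixel centers at i + 0.5)
    rr, cc = draw_polygon(vertices[:, 1] / pixel_size_um - 0.5,
                          vertices[:, 0] / pixel_size_um - 0.5,
                          shape=(grid_px, grid_px))
    pixels = np.zeros((grid_px, grid_px), dtype=bool)
    pixels[rr, cc] = True
    mask = MaskImage(pixels, pixel_size_um=pixel_size_um)

    truth = {
        "base_ellipse": {
            "cx_um": cx, "cy_um": cy, "a_um": spec.base_a_um,
            "b_um": spec.base_b_um, "theta_rad": spec.base_theta_rad,
        },
        "base_area_um2": float(np.pi * spec.base_a_um * spec.base_b_um),
        "planned_excess_area_um2": float(excess),
        "notch_centers_rad": centers.tolist(),
        "notch_depths_um": depths.tolist(),
        "notch_widths_rad": widths.tolist(),
    }
    return SyntheticShape(polygon=polygon, mask=mask, truth=truth)


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic per-patient cohort coupling Gensini score to FAZ shape.

    ``p_zero`` defaults to 73/212 ≈ 0.344, the CAD-free fraction of a
    cardiology cohort; the diseased Poisson mean of 30 places the bulk of
    scores across the moderate and severe severity groups.  The notch
    depth/count grow linearly with GS (``effect_map``), with right eyes
    attenuated relative to left eyes.
    """

    n_patients: int = 200
    p_zero: float = 73.0 / 212.0
    gs_mean: float = 30.0
    depth_base_um: float = 8.0
    depth_per_gs_um: float = 0.9
    depth_max_um: float = 120.0
    laterality_multiplier_od: float = 0.6
    n_vertices: int = 384
    seed: int = 0

    def effect_map(self, gs: float) -> tuple[int, float]:
        """Monotone GS → (n_notches, notch_depth_um)."""
        n_notches = int(min(6, 1 + gs // 15))
        depth = min(self.depth_max_um, self.depth_base_um + self.depth_per_gs_um * gs)
        return n_notches, depth


def generate_cohort(
    spec: CohortSpec,
    compute_metrics: bool = True,
    fit_kwargs: Optional[dict] = None,
    return_shapes: bool = False,
):
    """Cohort table (one row per eye) with covariates, GS, severity groups
    and — optionally — the nine shape biomarkers of the generated eyes.

    ``fit_kwargs`` tune the inner-ellipse fit for batch throughput
    (defaults: 2 restarts, 64 containment samples).
    """
    if spec.n_patients < 4:
        raise SpecError("cohort needs at least 4 patients")
    if not 0.0 <= spec.p_zero <= 1.0:
        raise SpecError("p_zero must be a probability")
    rng = np.random.default_rng(spec.seed)
    from .io import RunConfig, compute_record  # deferred: io imports nothing from here

    fk = {"n_restarts": 2, "n_boundary_samples": 64}
    fk.update(fit_kwargs or {})
    cfg = RunConfig(n_restarts=fk["n_restarts"],
                    n_boundary_samples=fk["n_boundary_samples"])

    rows, shapes = [], {}
    for i in range(spec.n_patients):
        structural_zero = rng.uniform() < spec.p_zero
        gs = 0.0 if structural_zero else float(rng.poisson(spec.gs_mean))
        sev = min(gs / 60.0, 1.0)
        age = float(np.clip(rng.normal(58.0 + 6.0 * sev, 10.0), 30.0, 92.0))
        sex = int(rng.uniform() < 0.45 + 0.3 * sev)  # 1 = male
        diabetes = int(rng.uniform() < 0.19 + 0.13 * sev)
        groups = severity_groups(gs)
        n_notches, depth = spec.effect_map(gs)
        for eye, mult in (("OD", spec.laterality_multiplier_od), ("OS", 1.0)):
            base_a = float(rng.normal(330.0, 25.0))
            base_b = float(rng.normal(270.0, 20.0))
            sspec = ShapeSpec(
                base_a_um=base_a, base_b_um=base_b,
                base_theta_rad=float(rng.uniform(0.0, np.pi)),
                n_notches=n_notches if depth * mult > 0 else 0,
                notch_depth_um=depth * mult,
                notch_width_rad=0.5,
                boundary_noise_um=2.0,
                n_vertices=spec.n_vertices,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            shape = generate_shape(sspec)
            row = {
                "patient_id": f"P{i:04d}", "eye": eye, "age_y": age,
                "sex": sex, "diabetes": diabetes, "gs": gs,
                "ternary_group": groups.ternary, "binary_group": groups.binary,
            }
            if compute_metrics:
                rec = compute_record(shape.polygon, cfg,
                                     patient_id=row["patient_id"], eye=eye,
                                     seed=int(rng.integers(0, 2**31 - 1)))
                for key in ("area_um2", "perimeter_um", "circularity",
                            "acircularity", "roundness", "solidity", "convexity",
                            "ie_area_um2", "diff_ie_um2", "hd_um", "cd_um2"):
                    row[key] = rec[key]
            rows.append(row)
            if return_shapes:
                shapes[(row["patient_id"], eye)] = shape
    table = pd.DataFrame(rows)
    return (table, shapes) if return_shapes else table
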