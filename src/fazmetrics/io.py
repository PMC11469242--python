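"""Readers, run configuration and the per-eye metrics record.

Inputs are binary raster masks (PNG/TIFF, nonzero = foreground) or
QuPath-style GeoJSON polygon annotations; outputs are one
:class:`MetricsRecord` per eye, streamed into an RFC 4180 CSV whose header
comments capture the full run configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from PIL import Image

from .classic import classic_metrics
from .distances import faz_ie_distances
from .errors import ConfigError, ParameterError
from .geometry import DEFAULT_PIXEL_SIZE_UM, FazPolygon, MaskImage, mask_to_polygon
from .inner_ellipse import diff_inner_ellipse, ellipse_area, fit_inner_ellipse

logger = logging.getLogger(__name__)

CSV_SCHEMA_VERSION = "1"

METRIC_COLUMNS = [
    "area_um2", "perimeter_um", "circularity", "acircularity", "roundness",
    "solidity", "convexity", "ie_area_um2", "diff_ie_um2", "hd_um", "cd_um2",
]


@dataclass(frozen=True)
class RunConfig:
    """All knobs of the metric pipeline, with field defaults matching the
    6 × 6-mm / 1024-px en face geometry."""

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    min_component_px: int = 10
    n_boundary_samples: int = 256
    tol_um: float = 0.5
    n_restarts: int = 8
    n_points: int = 512
    cd_reduction: str = "mean_of_directions"
    convexity_convention: str = "standard"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "min_component_px", "n_boundary_samples",
                     "tol_um", "n_restarts", "n_points"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def px_to_um(length_px: float, cfg: RunConfig | None = None) -> float:
    """Convert a pixel length to micrometers at the configured scale."""
    if length_px < 0:
        raise ParameterError("length_px must be nonnegative")
    cfg = cfg or RunConfig()
    return length_px * cfg.pixel_size_um


def read_mask(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> MaskImage:
    """8-bit PNG/TIFF mask; any nonzero pixel is foreground."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return MaskImage(arr > 0, pixel_size_um=pixel_size_um)


def read_geojson(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> FazPolygon:
    """First Polygon feature of a QuPath FeatureCollection export.

    Coordinates are interpreted as pixels (image convention, y down) and
    scaled to µm; only the first (exterior) ring is used.
    """
    with open(path) as fh:
        doc = json.load(fh)
    features = doc.get("features", [doc] if doc.get("geometry") else [])
    for feat in features:
        geom = feat.get("geometry", {})
        if geom.get("type") == "Polygon":
            ring = np.asarray(geom["coordinates"][0], dtype=float)
            return FazPolygon(ring * pixel_size_um)
        if geom.get("type") == "MultiPolygon":
            rings = [np.asarray(poly[0], dtype=float) for poly in geom["coordinates"]]
            largest = max(rings, key=lambda r: abs(
                0.5 * (r[:, 0] @ np.roll(r[:, 1], -1) - np.roll(r[:, 0], -1) @ r[:, 1])))
            return FazPolygon(largest * pixel_size_um)
    raise ParameterError(f"no Polygon feature found in {path}")


def compute_record(
    polygon: FazPolygon,
    cfg: RunConfig | None = None,
    patient_id: str = "",
    eye: str = "",
    seed: int | None = None,
) -> dict:
    """All nine biomarkers (plus perimeter and fit diagnostics) for one eye."""
    cfg = cfg or RunConfig()
    cm = classic_metrics(polygon, cfg.convexity_convention)
    fit = fit_inner_ellipse(
        polygon,
        n_boundary_samples=cfg.n_boundary_samples,
        tol_um=cfg.tol_um,
        n_restarts=cfg.n_restarts,
        seed=cfg.seed if seed is None else seed,
    )
    dp = faz_ie_distances(polygon, fit, n_points=cfg.n_points,
                          cd_reduction=cfg.cd_reduction)
    return {
        "patient_id": patient_id,
        "eye": eye,
        "pixel_size_um": cfg.pixel_size_um,
        "area_um2": cm.area_um2,
        "area_mm2": cm.area_um2 * 1e-6,
        "perimeter_um": cm.perimeter_um,
        "circularity": cm.circularity,
        "acircularity": cm.acircularity,
        "roundness": cm.roundness,
        "solidity": cm.solidity,
        "convexity": cm.convexity,
        "ie_area_um2": ellipse_area(fit.ellipse),
        "diff_ie_um2": diff_inner_ellipse(polygon, fit),
        "hd_um": dp.hd_um,
        "cd_um2": dp.cd_um2,
        "fit_violation_um": fit.containment_violation_um,
        "fit_converged": fit.converged,
        "fit_n_restarts": fit.n_restarts_used,
    }


def _load_input(path: Path, cfg: RunConfig) -> FazPolygon:
    if path.suffix.lower() in (".json", ".geojson"):
        return read_geojson(path, cfg.pixel_size_um)
    mask = read_mask(path, cfg.pixel_size_um)
    return mask_to_polygon(mask, cfg.min_component_px)


def compute_all(paths: Iterable, cfg: RunConfig | None = None,
                out_csv=None, sidecar_dir=None) -> pd.DataFrame:
    """Run the full metric pipeline over mask/GeoJSON files.

    Per-file failures are logged and recorded; the run only fails (raises)
    if every input fails.  With ``out_csv`` the table is written as CSV with
    the configuration embedded in ``#``-prefixed header comments.
    """
    cfg = cfg or RunConfig()
    records, failures = [], []
    for path in paths:
        path = Path(path)
        try:
            polygon = _load_input(path, cfg)
            rec = compute_record(polygon, cfg, patient_id=path.stem)
            rec["source_file"] = str(path)
            records.append(rec)
            if sidecar_dir is not None:
                side = Path(sidecar_dir) / f"{path.stem}.fit.json"
                side.write_text(json.dumps({
                    k: rec[k] for k in
                    ("fit_violation_um", "fit_converged", "fit_n_restarts")
                }, indent=2))
        except Exception as exc:  # per-file isolation is the contract
            logger.error("failed on %s: %s", path, exc)
            failures.append({"source_file": str(path), "error": str(exc)})
    if not records and failures:
        raise ParameterError(f"all {len(failures)} inputs failed")
    df = pd.DataFrame(records)
    if out_csv is not None:
        write_metrics_csv(df, out_csv, cfg)
    return df


def write_metrics_csv(df: pd.DataFrame, path, cfg: RunConfig | None = None) -> None:
    """CSV with 12-significant-digit floats and config provenance comments."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# fazmetrics csv schema {CSV_SCHEMA_VERSION}\n")
        if cfg is not None:
            fh.write(f"# config: {json.dumps(cfg.to_dict(), sort_keys=True)}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_metrics_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
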