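"""Adjusted Gensini score and CAD severity grouping.

The Gensini score (GS) quantifies angiographic coronary artery disease by
summing, over all lesions, a severity point value determined by the
stenosis percentage (25% → 1 doubling up to 100% → 32) weighted by a
multiplier reflecting the functional importance of the affected coronary
segment (e.g., left main ×5, proximal LAD ×2.5).  The adjustment used here
additionally scores the Ramus intermedius with multiplier 1.

Severity groups:

* ternary — 0: GS 0–3, 1: GS 4–31, 2: GS > 31 (at least one complete
  stenosis or equivalent);
* binary — 0: GS 0–3, 1: GS > 14; the band (3, 14] is excluded to keep
  mere coronary sclerosis out of the "significant CAD" class.

The point and multiplier tables are configuration data
(``data/gensini_tables.json``); custom tables may be supplied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Union

import pandas as pd

from .errors import ConfigError, ParameterError

EXCLUDED = "excluded"

#: GS above which the ternary group is 2 / the binary group is 1
TERNARY_CUTS = (3.0, 31.0)
BINARY_CUTS = (3.0, 14.0)


@dataclass(frozen=True)
class Lesion:
    segment_id: str
    stenosis_pct: float


@dataclass(frozen=True)
class SeverityGroups:
    ternary: int
    binary: Union[int, str]  # 0, 1 or "excluded"


def load_tables(path=None) -> dict:
    """Scoring tables: ``severity_points`` (stenosis % → points) and
    ``segment_multipliers`` (segment id → weight)."""
    if path is None:
        text = resources.files("fazmetrics.data").joinpath("gensini_tables.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    try:
        points = {float(k): float(v) for k, v in raw["severity_points"].items()}
        mult = {k: float(v) for k, v in raw["segment_multipliers"].items()}
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed Gensini tables: {exc}") from exc
    if any(v <= 0 for v in points.values()) or any(v <= 0 for v in mult.values()):
        raise ConfigError("severity points and multipliers must be positive")
    return {"severity_points": points, "segment_multipliers": mult}


def _snap_stenosis(pct: float, categories: list[float]) -> float:
    if pct in categories:
        return pct
    nearest = min(categories, key=lambda c: (abs(c - pct), c))
    warnings.warn(
        f"stenosis {pct}% is not a scoring category; snapped to {nearest}%",
        stacklevel=3,
    )
    return nearest


def gensini_score(lesions, tables: dict | None = None) -> float:
    """Sum of severity points × segment multiplier over all lesions."""
    if tables is None:
        tables = load_tables()
    points = tables["severity_points"]
    mult = tables["segment_multipliers"]
    categories = sorted(points)
    total = 0.0
    for lesion in lesions:
        if lesion.segment_id not in mult:
            raise ConfigError(f"unknown coronary segment {lesion.segment_id!r}")
        pct = _snap_stenosis(float(lesion.stenosis_pct), categories)
        total += points[pct] * mult[lesion.segment_id]
    return total


def severity_groups(gs: float) -> SeverityGroups:
    """Map a GS to the ternary and binary severity groups."""
    if gs < 0:
        raise ParameterError("Gensini score cannot be negative")
    if gs <= TERNARY_CUTS[0]:
        ternary = 0
    elif gs <= TERNARY_CUTS[1]:
        ternary = 1
    else:
        ternary = 2
    if gs <= BINARY_CUTS[0]:
        binary: Union[int, str] = 0
    elif gs <= BINARY_CUTS[1]:
        binary = EXCLUDED
    else:
        binary = 1
    return SeverityGroups(ternary=ternary, binary=binary)


def score_lesion_table(lesions_df: pd.DataFrame, tables: dict | None = None) -> pd.DataFrame:
    """Per-patient GS and severity groups from a lesion table with columns
    ``patient_id, segment_id, stenosis_pct`` (patients without lesion rows
    must appear with an empty/NaN segment to receive GS 0)."""
    required = {"patient_id", "segment_id", "stenosis_pct"}
    if not required.issubset(lesions_df.columns):
        raise ConfigError(f"lesion table must have columns {sorted(required)}")
    if tables is None:
        tables = load_tables()
    rows = []
    for pid, grp in lesions_df.groupby("patient_id", sort=True):
        lesions = [
            Lesion(str(r.segment_id), float(r.stenosis_pct))
            for r in grp.itertuples()
            if isinstance(r.segment_id, str) and r.segment_id and pd.notna(r.stenosis_pct)
        ]
        gs = gensini_score(lesions, tables)
        groups = severity_groups(gs)
        rows.append({"patient_id": pid, "gs": gs,
                     "ternary_group": groups.ternary, "binary_group": groups.binary})
    return pd.DataFrame(rows)
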