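"""Cartilage volume normalization and percent reductions.

The knee is described by seven sub-regions: patella (P), medial/lateral
tibial compartments (MT, LT), medial/lateral femoral condyles (MF, LF) and
their central weight-bearing areas (CMF, CLF). Volumes are normalized to
body mass times height; the analysis endpoint is the percent reduction
relative to the pre-run volume, which is invariant to that normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import MissingRegionError

#: The seven knee cartilage sub-regions, fixed order.
REGIONS: Tuple[str, ...] = ("P", "MT", "LT", "MF", "LF", "CMF", "CLF")


@dataclass(frozen=True)
class CartilageRecord:
    """Pre/post volumes of one region for one subject and condition."""

    subject_id: str
    condition: str
    region: str
    pre_mm3: float
    post_mm3: float
    mass_kg: float
    height_m: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.pre_mm3 <= 0 or self.post_mm3 <= 0:
            raise ValueError("volumes must be positive")
        if self.mass_kg <= 0 or self.height_m <= 0:
            raise ValueError("mass and height must be positive")


@dataclass(frozen=True)
class ReductionRecord:
    subject_id: str
    condition: str
    region: str
    pct_reduction: float
    normalized_pre: float
    normalized_post: float


def normalize_volume(vc_mm3: float, mass_kg: float, height_m: float) -> float:
    """Volume divided by body mass times height, mm^3/(kg*m)."""
    if mass_kg <= 0 or height_m <= 0:
        raise ValueError("mass and height must be positive")
    return vc_mm3 / (mass_kg * height_m)


def percent_reduction(pre_mm3: float, post_mm3: float) -> float:
    """100 * (pre - post) / pre; negative when volume increased."""
    if pre_mm3 <= 0:
        raise ValueError("pre-run volume must be positive")
    return 100.0 * (pre_mm3 - post_mm3) / pre_mm3


def reduction_record(record: CartilageRecord) -> ReductionRecord:
    return ReductionRecord(
        subject_id=record.subject_id,
        condition=record.condition,
        region=record.region,
        pct_reduction=percent_reduction(record.pre_mm3, record.post_mm3),
        normalized_pre=normalize_volume(record.pre_mm3, record.mass_kg, record.height_m),
        normalized_post=normalize_volume(
            record.post_mm3, record.mass_kg, record.height_m
        ),
    )


def subject_region_average(reductions_pct: Sequence[float]) -> float:
    """Unweighted mean percent reduction across footwear conditions."""
    if len(reductions_pct) == 0:
        raise ValueError("no reductions to average")
    return float(np.mean(reductions_pct))


def validate_region_sets(records: Iterable[CartilageRecord]) -> None:
    """Every (subject, condition) must carry exactly the seven regions."""
    seen: Dict[Tuple[str, str], List[str]] = {}
    for rec in records:
        seen.setdefault((rec.subject_id, rec.condition), []).append(rec.region)
    problems = []
    for (sid, cond), regions in sorted(seen.items()):
        missing = sorted(set(REGIONS) - set(regions))
        duplicated = sorted({r for r in regions if regions.count(r) > 1})
        if missing:
            problems.append(f"{sid}/{cond}: missing {missing}")
        if duplicated:
            problems.append(f"{sid}/{cond}: duplicated {duplicated}")
    if problems:
        raise MissingRegionError("; ".join(problems))


def reductions_frame(records: Sequence[CartilageRecord]) -> pd.DataFrame:
    """Validated long-format reductions table.

    Columns: subject, condition, region, pct_reduction, normalized_pre,
    normalized_post.
    """
    validate_region_sets(records)
    rows = [reduction_record(r) for r in records]
    return pd.DataFrame(
        {
            "subject": [r.subject_id for r in rows],
            "condition": [r.condition for r in rows],
            "region": [r.region for r in rows],
            "pct_reduction": [r.pct_reduction for r in rows],
            "normalized_pre": [r.normalized_pre for r in rows],
            "normalized_post": [r.normalized_post for r in rows],
        }
    )
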