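"""Habitual-motion-path baseline and deviation score.

The baseline is the per-subject mean of the frontal/transverse knee angles
sampled at the critical flexion angle across half-squat repetitions. The
deviation of a running condition combines the per-plane distances from that
baseline into a single score::

    dev_total = dev_front + 0.5 * dev_trans

with per-plane deviations taken as absolute differences by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .config import DEFAULT_SHOE_ORDER, TRANSVERSE_WEIGHT
from .errors import TieBreakWarning


@dataclass(frozen=True)
class HMPBaseline:
    subject_id: str
    frontal_deg: float
    transverse_deg: float
    n_squats_used: int
    per_squat_values: Tuple[Tuple[float, float], ...] = ()
    n_excluded: int = 0


@dataclass(frozen=True)
class HMPDeviation:
    subject_id: str
    condition: str
    dev_front_deg: float
    dev_trans_deg: float
    dev_total_deg: float
    n_strides: int = 1


@dataclass(frozen=True)
class SubjectDeviationSummary:
    subject_id: str
    per_shoe: Mapping[str, HMPDeviation]
    overall_deg: float
    min_shoe: str
    max_shoe: str


def combine_planes(
    dev_front: float, dev_trans: float, transverse_weight: float = TRANSVERSE_WEIGHT
) -> float:
    """Total deviation score: frontal plus weighted transverse deviation."""
    return dev_front + transverse_weight * dev_trans


def compute_baseline(
    squat_crossings: Sequence[Tuple[float, float]],
    subject_id: str = "",
    n_excluded: int = 0,
) -> HMPBaseline:
    """Component-wise mean of per-squat (frontal, transverse) crossings.

    ``n_excluded`` counts squats dropped upstream (e.g. no 40-deg crossing).
    """
    if len(squat_crossings) == 0:
        raise ValueError(
            f"no valid squat crossings for subject {subject_id!r} "
            f"({n_excluded} excluded)"
        )
    arr = np.asarray(squat_crossings, dtype=float)
    return HMPBaseline(
        subject_id=subject_id,
        frontal_deg=float(arr[:, 0].mean()),
        transverse_deg=float(arr[:, 1].mean()),
        n_squats_used=len(squat_crossings),
        per_squat_values=tuple((float(f), float(t)) for f, t in arr),
        n_excluded=n_excluded,
    )


def compute_deviation(
    run_crossing: Tuple[float, float],
    baseline: HMPBaseline,
    signed: bool = False,
    transverse_weight: float = TRANSVERSE_WEIGHT,
) -> Tuple[float, float, float]:
    """Per-plane deviation of one running crossing from the squat baseline.

    Returns ``(dev_front, dev_trans, dev_total)``. Absolute differences by
    default; ``signed=True`` retains the sign (running minus baseline).
    """
    df = run_crossing[0] - baseline.frontal_deg
    dt = run_crossing[1] - baseline.transverse_deg
    if not signed:
        df, dt = abs(df), abs(dt)
    return df, dt, combine_planes(df, dt, transverse_weight)


def aggregate_condition(
    stride_deviations: Sequence[Tuple[float, float, float]],
    subject_id: str = "",
    condition: str = "",
    transverse_weight: float = TRANSVERSE_WEIGHT,
) -> HMPDeviation:
    """Per-component mean over strides; the total is recomputed from the
    averaged components (equivalent to averaging totals — the score is
    linear in its components)."""
    if len(stride_deviations) == 0:
        raise ValueError(f"no strides to aggregate for {subject_id!r}/{condition!r}")
    arr = np.asarray(stride_deviations, dtype=float)
    df = float(arr[:, 0].mean())
    dt = float(arr[:, 1].mean())
    return HMPDeviation(
        subject_id=subject_id,
        condition=condition,
        dev_front_deg=df,
        dev_trans_deg=dt,
        dev_total_deg=combine_planes(df, dt, transverse_weight),
        n_strides=len(stride_deviations),
    )


def _extreme_shoe(totals: Dict[str, float], order: Sequence[str], largest: bool) -> str:
    extreme = max(totals.values()) if largest else min(totals.values())
    tied = [shoe for shoe, v in totals.items() if v == extreme]
    if len(tied) > 1:
        ranked = sorted(
            tied, key=lambda s: order.index(s) if s in order else len(order)
        )
        warnings.warn(
            f"tied {'max' if largest else 'min'} deviation among {sorted(tied)}; "
            f"choosing {ranked[0]} by condition order",
            TieBreakWarning,
            stacklevel=3,
        )
        return ranked[0]
    return tied[0]


def summarize_subject(
    per_shoe: Mapping[str, HMPDeviation],
    shoe_order: Sequence[str] = DEFAULT_SHOE_ORDER,
) -> SubjectDeviationSummary:
    """Overall (mean-over-conditions) deviation plus the extreme shoes.

    Ties for the extreme shoes are broken by the fixed condition order with
    a :class:`TieBreakWarning`.
    """
    if len(per_shoe) < 2:
        raise ValueError("need at least 2 conditions to summarize a subject")
    subject_ids = {d.subject_id for d in per_shoe.values() if d.subject_id}
    if len(subject_ids) > 1:
        raise ValueError(f"mixed subjects in per_shoe mapping: {sorted(subject_ids)}")
    totals = {shoe: d.dev_total_deg for shoe, d in per_shoe.items()}
    return SubjectDeviationSummary(
        subject_id=next(iter(subject_ids), ""),
        per_shoe=dict(per_shoe),
        overall_deg=float(np.mean(list(totals.values()))),
        min_shoe=_extreme_shoe(totals, shoe_order, largest=False),
        max_shoe=_extreme_shoe(totals, shoe_order, largest=True),
    )


def split_groups(
    summaries: Sequence[SubjectDeviationSummary],
) -> Tuple[List[SubjectDeviationSummary], List[SubjectDeviationSummary]]:
    """Median split into (high, low) deviation halves.

    Subjects are sorted by overall deviation; the top half forms the high
    group. An exact tie at the boundary is broken by subject id order with
    a :class:`TieBreakWarning`.
    """
    n = len(summaries)
    if n < 2 or n % 2 != 0:
        raise ValueError(
            f"group split needs an even subject count, got {n}; "
            "assign groups explicitly instead"
        )
    ordered = sorted(summaries, key=lambda s: (s.overall_deg, s.subject_id))
    half = n // 2
    if ordered[half - 1].overall_deg == ordered[half].overall_deg:
        warnings.warn(
            "tie at the median split boundary; resolved by subject id order",
            TieBreakWarning,
            stacklevel=2,
        )
    low = list(ordered[:half])
    high = list(ordered[half:])
    return high, low
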