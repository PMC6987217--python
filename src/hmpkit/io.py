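"""Readers, writers and the end-to-end pipeline.

All interchange formats are plain text: trial CSV (time + angle columns,
optional vertical GRF), cartilage CSV, deviations/reductions/summary CSVs,
a JSON dataset manifest and a JSON study report. Floats are written with
shortest-roundtrip formatting, so every writer/reader pair is lossless and
re-runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import cartilage as _cartilage
from . import hmp as _hmp
from . import kinematics as _kin
from . import stats as _stats
from .config import AnalysisConfig
from .errors import EmptyPhaseError, NoCrossingError, SchemaError
from .synthetic import CohortDataset

logger = logging.getLogger("hmpkit")

TRIAL_COLUMNS = ("time_s", "flexion_deg", "adduction_deg", "int_rot_deg")
GRF_COLUMN = "grf_vertical_N"
CARTILAGE_COLUMNS = (
    "subject",
    "shoe",
    "region",
    "pre_mm3",
    "post_mm3",
    "mass_kg",
    "height_m",
)


# ---------------------------------------------------------------- trial CSV


def write_trial_csv(trial: _kin.Trial, path) -> None:
    data = {
        "time_s": trial.time_s,
        "flexion_deg": trial.flexion_deg,
        "adduction_deg": trial.adduction_deg,
        "int_rot_deg": trial.int_rot_deg,
    }
    if trial.grf_vertical_N is not None:
        data[GRF_COLUMN] = trial.grf_vertical_N
    pd.DataFrame(data).to_csv(path, index=False)


def read_trial_csv(
    path,
    subject_id: str = "",
    condition: str = "",
    movement_kind: str = "",
) -> _kin.Trial:
    """Read and validate one trial CSV.

    Raises :class:`SchemaError` naming any missing required column; the
    Trial constructor enforces the uniform-time invariant (the error
    reports the maximum gap).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, skip_blank_lines=True)
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    grf = frame[GRF_COLUMN].to_numpy() if GRF_COLUMN in frame.columns else None
    if not movement_kind:
        movement_kind = "run" if grf is not None else "squat"
    return _kin.Trial(
        time_s=frame["time_s"].to_numpy(),
        flexion_deg=frame["flexion_deg"].to_numpy(),
        adduction_deg=frame["adduction_deg"].to_numpy(),
        int_rot_deg=frame["int_rot_deg"].to_numpy(),
        grf_vertical_N=grf,
        movement_kind=movement_kind,
        subject_id=subject_id,
        condition=condition,
    )


# ------------------------------------------------------------ cartilage CSV


def write_cartilage_csv(records: Sequence[_cartilage.CartilageRecord], path) -> None:
    pd.DataFrame(
        {
            "subject": [r.subject_id for r in records],
            "shoe": [r.condition for r in records],
            "region": [r.region for r in records],
            "pre_mm3": [r.pre_mm3 for r in records],
            "post_mm3": [r.post_mm3 for r in records],
            "mass_kg": [r.mass_kg for r in records],
            "height_m": [r.height_m for r in records],
        }
    ).to_csv(path, index=False)


def read_cartilage_csv(path) -> List[_cartilage.CartilageRecord]:
    frame = pd.read_csv(path, skip_blank_lines=True)
    missing = [c for c in CARTILAGE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return [
        _cartilage.CartilageRecord(
            subject_id=str(row.subject),
            condition=str(row.shoe),
            region=str(row.region),
            pre_mm3=float(row.pre_mm3),
            post_mm3=float(row.post_mm3),
            mass_kg=float(row.mass_kg),
            height_m=float(row.height_m),
        )
        for row in frame.itertuples()
    ]


# --------------------------------------------------------- result tables


def write_baseline_csv(baselines: Sequence[_hmp.HMPBaseline], path) -> None:
    pd.DataFrame(
        {
            "subject": [b.subject_id for b in baselines],
            "frontal_deg": [b.frontal_deg for b in baselines],
            "transverse_deg": [b.transverse_deg for b in baselines],
            "n_squats_used": [b.n_squats_used for b in baselines],
            "n_excluded": [b.n_excluded for b in baselines],
        }
    ).to_csv(path, index=False)


def read_baseline_csv(path) -> List[_hmp.HMPBaseline]:
    frame = pd.read_csv(path, skip_blank_lines=True)
    return [
        _hmp.HMPBaseline(
            subject_id=str(row.subject),
            frontal_deg=float(row.frontal_deg),
            transverse_deg=float(row.transverse_deg),
            n_squats_used=int(row.n_squats_used),
            n_excluded=int(getattr(row, "n_excluded", 0)),
        )
        for row in frame.itertuples()
    ]


def write_deviations_csv(deviations: Sequence[_hmp.HMPDeviation], path) -> None:
    pd.DataFrame(
        {
            "subject": [d.subject_id for d in deviations],
            "condition": [d.condition for d in deviations],
            "dev_front_deg": [d.dev_front_deg for d in deviations],
            "dev_trans_deg": [d.dev_trans_deg for d in deviations],
            "dev_total_deg": [d.dev_total_deg for d in deviations],
            "n_strides": [d.n_strides for d in deviations],
        }
    ).to_csv(path, index=False)


def read_deviations_csv(path) -> List[_hmp.HMPDeviation]:
    frame = pd.read_csv(path, skip_blank_lines=True)
    return [
        _hmp.HMPDeviation(
            subject_id=str(row.subject),
            condition=str(row.condition),
            dev_front_deg=float(row.dev_front_deg),
            dev_trans_deg=float(row.dev_trans_deg),
            dev_total_deg=float(row.dev_total_deg),
            n_strides=int(row.n_strides),
        )
        for row in frame.itertuples()
    ]


def write_summary_csv(summaries: Sequence[_hmp.SubjectDeviationSummary], path) -> None:
    pd.DataFrame(
        {
            "subject": [s.subject_id for s in summaries],
            "overall_deg": [s.overall_deg for s in summaries],
            "min_shoe": [s.min_shoe for s in summaries],
            "max_shoe": [s.max_shoe for s in summaries],
        }
    ).to_csv(path, index=False)


# ------------------------------------------------------------ C3D (optional)


def read_c3d(path, marker_map: Mapping[str, Sequence[str]]) -> Dict[str, np.ndarray]:
    """Per-segment marker trajectories (frames, n_markers, 3) in metres.

    ``marker_map`` maps segment names to ordered C3D point labels. Requires
    the optional ``ezc3d`` dependency.
    """
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "reading C3D files requires the optional dependency 'ezc3d'"
        ) from exc
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    c3d = ezc3d.c3d(str(path))
    labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    units = c3d["parameters"]["POINT"].get("UNITS", {}).get("value", ["mm"])
    scale = 0.001 if units and str(units[0]).lower().startswith("mm") else 1.0
    points = c3d["data"]["points"]  # (4, n_markers, n_frames)
    out: Dict[str, np.ndarray] = {}
    for segment, wanted in marker_map.items():
        idx = []
        for label in wanted:
            if label not in labels:
                raise SchemaError(
                    f"{path}: label {label!r} not in C3D; available: {labels}"
                )
            idx.append(labels.index(label))
        out[segment] = np.transpose(points[:3, idx, :], (2, 0, 1)) * scale
    return out


# --------------------------------------------------------------- dataset IO


def write_dataset(dataset: CohortDataset, out_dir) -> Path:
    """Write a cohort dataset: trial CSVs, cartilage CSV, truth CSV and a
    JSON manifest. Deterministic for a fixed dataset."""
    out = Path(out_dir)
    trials_dir = out / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subjects": [s.subject_id for s in dataset.subjects],
        "shoes": list(dataset.cfg.shoes),
        "trials": [],
        "cartilage": "cartilage.csv",
        "truth": "truth.csv",
    }
    for sid in sorted(dataset.squat_trials):
        for k, trial in enumerate(dataset.squat_trials[sid]):
            rel = f"trials/{sid}_squat_{k:03d}.csv"
            write_trial_csv(trial, out / rel)
            manifest["trials"].append(
                {"file": rel, "subject": sid, "kind": "squat", "condition": "squat"}
            )
    for (sid, shoe) in sorted(dataset.running_trials):
        for k, trial in enumerate(dataset.running_trials[(sid, shoe)]):
            rel = f"trials/{sid}_run_{shoe}_{k:03d}.csv"
            write_trial_csv(trial, out / rel)
            manifest["trials"].append(
                {"file": rel, "subject": sid, "kind": "run", "condition": shoe}
            )
    write_cartilage_csv(dataset.cartilage_records, out / "cartilage.csv")
    pd.DataFrame(dataset.truth_rows()).to_csv(out / "truth.csv", index=False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


# ----------------------------------------------------------------- pipeline


def _crossing_time(trial: _kin.Trial, phase: _kin.PhaseInterval, critical: float):
    flex = trial.flexion_deg
    for i in range(phase.start_index, phase.end_index - 1):
        lo, hi = flex[i], flex[i + 1]
        if lo == critical and hi > lo:
            return float(trial.time_s[i])
        if lo < critical <= hi:
            frac = (critical - lo) / (hi - lo)
            return float(trial.time_s[i] + frac * (trial.time_s[i + 1] - trial.time_s[i]))
    return None


def _maybe_filter(series, cutoff, fs, order):
    if cutoff is None:
        return series
    return _kin.lowpass(series, cutoff, fs, order)


def pipeline(
    dataset_dir, out_dir, config: Optional[AnalysisConfig] = None
) -> _stats.StudyResult:
    """Run baseline -> deviations -> reductions -> statistics end to end.

    Reads a dataset directory (manifest + trial CSVs + cartilage CSV),
    writes every intermediate table plus ``report.json`` to ``out_dir`` and
    returns the :class:`~hmpkit.stats.StudyResult`. Every excluded trial is
    logged with its reason and counted in the report; deterministic for
    fixed inputs.
    """
    config = config or AnalysisConfig()
    data = Path(dataset_dir)
    manifest_path = data / "manifest.json"
    if not manifest_path.exists():
        raise SchemaError(f"no manifest.json in dataset directory {data}")
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    if not manifest.get("trials"):
        raise SchemaError(f"dataset {data} lists no trials")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    squat_crossings: Dict[str, list] = {}
    stride_devs: Dict[Tuple[str, str], list] = {}
    exclusions: List[dict] = []
    events: List[dict] = []
    n_excluded_squats: Dict[str, int] = {}
    n_trials_in = 0

    def _exclude(entry, stage, exc):
        logger.warning("excluding %s at %s: %s", entry["file"], stage, exc)
        exclusions.append({"file": entry["file"], "stage": stage, "reason": str(exc)})

    # -- squats -> baselines
    run_entries = []
    for entry in manifest["trials"]:
        n_trials_in += 1
        if entry["kind"] != "squat":
            run_entries.append(entry)
            continue
        sid = entry["subject"]
        squat_crossings.setdefault(sid, [])
        n_excluded_squats.setdefault(sid, 0)
        try:
            trial = read_trial_csv(
                data / entry["file"], subject_id=sid, condition="squat",
                movement_kind="squat",
            )
            fs = trial.sampling_rate
            trial.flexion_deg = _maybe_filter(
                trial.flexion_deg, config.angle_lowpass_hz, fs, config.filter_order
            )
            trial.adduction_deg = _maybe_filter(
                trial.adduction_deg, config.angle_lowpass_hz, fs, config.filter_order
            )
            trial.int_rot_deg = _maybe_filter(
                trial.int_rot_deg, config.angle_lowpass_hz, fs, config.filter_order
            )
            phase = _kin.detect_eccentric_phase(trial.flexion_deg)
            crossing = _kin.angles_at_critical_flexion(
                trial, phase, config.critical_flexion_deg
            )
            squat_crossings[sid].append(crossing)
            events.append(
                {
                    "trial": entry["file"],
                    "stance_start_s": None,
                    "stance_end_s": None,
                    "eccentric_end_s": float(trial.time_s[phase.end_index - 1]),
                    "crossing_time_s": _crossing_time(
                        trial, phase, config.critical_flexion_deg
                    ),
                }
            )
        except (NoCrossingError, EmptyPhaseError, ValueError, SchemaError) as exc:
            n_excluded_squats[sid] += 1
            _exclude(entry, "squat", exc)

    baselines = {}
    for sid, crossings in squat_crossings.items():
        baselines[sid] = _hmp.compute_baseline(
            crossings, subject_id=sid, n_excluded=n_excluded_squats[sid]
        )

    # -- running trials -> per-condition deviations
    for entry in run_entries:
        sid, shoe = entry["subject"], entry["condition"]
        key = (sid, shoe)
        stride_devs.setdefault(key, [])
        try:
            trial = read_trial_csv(
                data / entry["file"], subject_id=sid, condition=shoe,
                movement_kind="run",
            )
            if trial.grf_vertical_N is None:
                raise SchemaError("running trial without grf_vertical_N column")
            fs = trial.sampling_rate
            force = _maybe_filter(
                trial.grf_vertical_N, config.force_lowpass_hz, fs, config.filter_order
            )
            for name in ("flexion_deg", "adduction_deg", "int_rot_deg"):
                setattr(
                    trial,
                    name,
                    _maybe_filter(
                        getattr(trial, name), config.angle_lowpass_hz, fs,
                        config.filter_order,
                    ),
                )
            stances = _kin.detect_stance(
                force,
                config.stance_threshold_N,
                fs,
                min_duration_s=config.min_stance_duration_s,
            )
            if not stances:
                raise EmptyPhaseError("no stance phase detected")
            baseline = baselines.get(sid)
            if baseline is None:
                raise SchemaError(f"no squat baseline for subject {sid}")
            for stance in stances:
                phase = _kin.detect_eccentric_phase(trial.flexion_deg, within=stance)
                crossing = _kin.angles_at_critical_flexion(
                    trial, phase, config.critical_flexion_deg
                )
                stride_devs[key].append(
                    _hmp.compute_deviation(
                        crossing,
                        baseline,
                        signed=config.signed_deviation,
                        transverse_weight=config.eq1_transverse_weight,
                    )
                )
                events.append(
                    {
                        "trial": entry["file"],
                        "stance_start_s": float(trial.time_s[stance.start_index]),
                        "stance_end_s": float(trial.time_s[stance.end_index - 1]),
                        "eccentric_end_s": float(trial.time_s[phase.end_index - 1]),
                        "crossing_time_s": _crossing_time(
                            trial, phase, config.critical_flexion_deg
                        ),
                    }
                )
        except (NoCrossingError, EmptyPhaseError, ValueError, SchemaError) as exc:
            _exclude(entry, "run", exc)

    deviations = [
        _hmp.aggregate_condition(
            devs, subject_id=sid, condition=shoe,
            transverse_weight=config.eq1_transverse_weight,
        )
        for (sid, shoe), devs in sorted(stride_devs.items())
        if devs
    ]
    per_subject: Dict[str, Dict[str, _hmp.HMPDeviation]] = {}
    for dev in deviations:
        per_subject.setdefault(dev.subject_id, {})[dev.condition] = dev
    summaries = [
        _hmp.summarize_subject(shoes, shoe_order=config.shoe_order)
        for sid, shoes in sorted(per_subject.items())
    ]

    # -- cartilage reductions
    records = read_cartilage_csv(data / manifest.get("cartilage", "cartilage.csv"))
    reductions = _cartilage.reductions_frame(records)

    # -- statistics
    result = _stats.run_study_analysis(summaries, reductions, config)

    # -- artifacts
    ordered_baselines = [baselines[sid] for sid in sorted(baselines)]
    write_baseline_csv(ordered_baselines, out / "baseline.csv")
    write_deviations_csv(deviations, out / "deviations.csv")
    write_summary_csv(summaries, out / "summary.csv")
    reductions.to_csv(out / "reductions.csv", index=False)
    pd.DataFrame(
        events,
        columns=[
            "trial",
            "stance_start_s",
            "stance_end_s",
            "eccentric_end_s",
            "crossing_time_s",
        ],
    ).to_csv(out / "events.csv", index=False)
    report = result.to_json_dict()
    report["counts"] = {
        "trials_in": n_trials_in,
        "trials_used": n_trials_in - len(exclusions),
        "trials_excluded": len(exclusions),
    }
    report["exclusions"] = exclusions
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return result


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
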