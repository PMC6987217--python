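"""Synthetic cohort generator with known ground truth.

Produces half-squat and treadmill-running knee angle trials, marker clouds
for the rigid-fit chain, vertical ground-reaction force traces, and pre/post
cartilage volumes whose percent reductions are linearly coupled to the
configured motion-path deviation. Every quantity the analysis pipeline
estimates is available as ground truth, so end-to-end recovery is testable
without any external data.

Construction guarantees:

* every flexion trace crosses the 40-deg critical angle exactly once with
  positive slope inside its eccentric phase;
* the frontal/transverse angles are affine functions of flexion pinned to
  the subject's baseline (plus per-shoe offsets when running) at 40 deg, so
  with zero noise the pipeline's linearly interpolated crossing values
  reproduce the configured truth to floating-point precision;
* all draws are keyed on (seed, kind, subject, repetition), making each
  trial individually reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .cartilage import REGIONS, CartilageRecord
from .config import CRITICAL_FLEXION_DEG, DEFAULT_SHOE_ORDER, TRANSVERSE_WEIGHT
from .errors import ConfigError, DegenerateGeometryError, UnknownShoeError
from .hmp import combine_planes
from .kinematics import Trial

GRAVITY = 9.81

# Affine dependence of the non-sagittal angles on flexion (deg per deg).
FRONTAL_SLOPE_PER_DEG = 0.08
TRANSVERSE_SLOPE_PER_DEG = -0.05

#: Default peak stance flexion for running (guarantees the 40-deg crossing).
RUN_PEAK_FLEXION_DEG = 50.0

#: Fraction of stance at which running flexion peaks (end of eccentric part).
STANCE_PEAK_FRACTION = 0.45

_DEFAULT_PRE_VOLUMES = {
    "P": 3800.0,
    "MT": 1900.0,
    "LT": 2600.0,
    "MF": 1500.0,
    "LF": 1600.0,
    "CMF": 1200.0,
    "CLF": 1300.0,
}


@dataclass
class CohortConfig:
    """Study layout: subjects x footwear conditions x repetitions."""

    n_subjects: int = 12
    shoes: Sequence[str] = field(default_factory=lambda: list(DEFAULT_SHOE_ORDER))
    sampling_rate_mocap: float = 200.0
    sampling_rate_force: float = 1000.0
    n_squats_per_subject: int = 10
    n_strides_per_condition: int = 20
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_subjects < 2 or self.n_subjects % 2 != 0:
            bad.append("n_subjects")
        if len(self.shoes) < 1 or len(set(self.shoes)) != len(self.shoes):
            bad.append("shoes")
        if self.sampling_rate_mocap <= 0:
            bad.append("sampling_rate_mocap")
        if self.sampling_rate_force <= 0:
            bad.append("sampling_rate_force")
        if self.n_squats_per_subject < 1:
            bad.append("n_squats_per_subject")
        if self.n_strides_per_condition < 1:
            bad.append("n_strides_per_condition")
        if bad:
            raise ConfigError("invalid cohort config: " + ", ".join(bad), fields=bad)


@dataclass
class SubjectTruth:
    """Ground-truth parameters of one synthetic subject."""

    subject_id: str
    body_mass_kg: float
    body_height_m: float
    baseline_frontal_deg: float
    baseline_transverse_deg: float
    shoe_offsets: Mapping[str, Tuple[float, float]]
    region_pre_volumes_mm3: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PRE_VOLUMES)
    )
    coupling_alpha_pct: Mapping[str, float] = field(
        default_factory=lambda: {r: 3.0 for r in REGIONS}
    )
    coupling_beta_pct_per_deg: Mapping[str, float] = field(
        default_factory=lambda: {r: 0.3 for r in REGIONS}
    )
    reduction_noise_sd_pct: float = 0.0
    angle_noise_sd_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0 or self.body_height_m <= 0:
            raise ValueError("mass and height must be positive")
        if any(v <= 0 for v in self.region_pre_volumes_mm3.values()):
            raise ValueError("pre volumes must be positive")

    def expected_deviation(
        self, shoe: str, transverse_weight: float = TRANSVERSE_WEIGHT
    ) -> Tuple[float, float, float]:
        """Noise-free (dev_front, dev_trans, dev_total) implied by the
        configured per-shoe offsets."""
        off_f, off_t = self._offsets(shoe)
        df, dt = abs(off_f), abs(off_t)
        return df, dt, combine_planes(df, dt, transverse_weight)

    def expected_reduction_pct(self, region: str, deviation_deg: float) -> float:
        r = (
            self.coupling_alpha_pct[region]
            + self.coupling_beta_pct_per_deg[region] * deviation_deg
        )
        return max(r, 0.0)

    def _offsets(self, shoe: str) -> Tuple[float, float]:
        try:
            return self.shoe_offsets[shoe]
        except KeyError:
            raise UnknownShoeError(
                f"shoe {shoe!r} not defined for subject {self.subject_id!r}; "
                f"known: {sorted(self.shoe_offsets)}"
            ) from None


@dataclass
class TruthParams:
    """Population distributions from which subject truths are drawn."""

    baseline_frontal_range: Tuple[float, float] = (-2.0, 8.0)
    baseline_transverse_range: Tuple[float, float] = (-8.0, 2.0)
    # population-mean (frontal, transverse) offset magnitude per shoe
    shoe_offset_means: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "neutral": (3.0, 2.0),
            "lateral_post": (5.0, 3.5),
            "medial_post": (1.5, 1.0),
        }
    )
    shoe_offset_jitter_sd: float = 1.0
    body_mass_mean_kg: float = 70.9
    body_mass_sd_kg: float = 9.9
    body_height_mean_m: float = 1.77
    body_height_sd_m: float = 0.08
    pre_volume_jitter_frac: float = 0.15
    coupling_alpha_pct: float = 3.0
    coupling_beta_pct_per_deg: float = 0.3
    reduction_noise_sd_pct: float = 0.0
    angle_noise_sd_deg: float = 0.0


def _rng(seed: int, *tags) -> np.random.Generator:
    """Deterministic generator keyed on the seed and a tag tuple."""
    words = [np.uint32(seed & 0xFFFFFFFF), np.uint32((seed >> 32) & 0xFFFFFFFF)]
    for tag in tags:
        digest = hashlib.blake2s(str(tag).encode(), digest_size=4).digest()
        words.append(np.uint32(int.from_bytes(digest, "little")))
    return np.random.default_rng(np.random.SeedSequence(words))


def draw_subject_truth(
    index: int, cfg: CohortConfig, params: Optional[TruthParams] = None
) -> SubjectTruth:
    """Draw one subject's ground truth from the population distributions."""
    params = params or TruthParams()
    rng = _rng(cfg.seed, "truth", index)
    sid = f"S{index + 1:02d}"
    offsets: Dict[str, Tuple[float, float]] = {}
    for shoe in cfg.shoes:
        mean_f, mean_t = params.shoe_offset_means.get(shoe, (2.0, 1.5))
        off_f = abs(mean_f + rng.normal(0.0, params.shoe_offset_jitter_sd))
        off_t = abs(mean_t + rng.normal(0.0, params.shoe_offset_jitter_sd))
        offsets[shoe] = (off_f, off_t)
    jitter = params.pre_volume_jitter_frac
    pre = {
        r: v * float(rng.uniform(1.0 - jitter, 1.0 + jitter))
        for r, v in _DEFAULT_PRE_VOLUMES.items()
    }
    return SubjectTruth(
        subject_id=sid,
        body_mass_kg=max(40.0, float(rng.normal(params.body_mass_mean_kg, params.body_mass_sd_kg))),
        body_height_m=max(1.4, float(rng.normal(params.body_height_mean_m, params.body_height_sd_m))),
        baseline_frontal_deg=float(rng.uniform(*params.baseline_frontal_range)),
        baseline_transverse_deg=float(rng.uniform(*params.baseline_transverse_range)),
        shoe_offsets=offsets,
        region_pre_volumes_mm3=pre,
        coupling_alpha_pct={r: params.coupling_alpha_pct for r in REGIONS},
        coupling_beta_pct_per_deg={r: params.coupling_beta_pct_per_deg for r in REGIONS},
        reduction_noise_sd_pct=params.reduction_noise_sd_pct,
        angle_noise_sd_deg=params.angle_noise_sd_deg,
    )


def _nonsagittal(
    flexion: np.ndarray,
    frontal_at_critical: float,
    transverse_at_critical: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    d = flexion - CRITICAL_FLEXION_DEG
    frontal = frontal_at_critical + FRONTAL_SLOPE_PER_DEG * d
    transverse = transverse_at_critical + TRANSVERSE_SLOPE_PER_DEG * d
    if noise_sd > 0:
        frontal = frontal + rng.normal(0.0, noise_sd, size=flexion.size)
        transverse = transverse + rng.normal(0.0, noise_sd, size=flexion.size)
    return frontal, transverse


def generate_squat_trial(
    subject: SubjectTruth, rep_index: int, cfg: CohortConfig
) -> Trial:
    """One half-squat repetition: raised-cosine flexion excursion.

    Flexion rises monotonically from below 10 deg to a peak in [80, 100]
    deg and returns, crossing 40 deg exactly once rising and once falling.
    """
    rng = _rng(cfg.seed, "squat", subject.subject_id, rep_index)
    fs = cfg.sampling_rate_mocap
    duration = float(rng.uniform(1.6, 2.4))
    start_deg = float(rng.uniform(4.0, 8.0))
    peak_deg = float(rng.uniform(80.0, 100.0))
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    flexion = start_deg + (peak_deg - start_deg) * 0.5 * (
        1.0 - np.cos(2.0 * np.pi * t / t[-1])
    )
    frontal, transverse = _nonsagittal(
        flexion,
        subject.baseline_frontal_deg,
        subject.baseline_transverse_deg,
        subject.angle_noise_sd_deg,
        rng,
    )
    return Trial(
        time_s=t,
        flexion_deg=flexion,
        adduction_deg=frontal,
        int_rot_deg=transverse,
        movement_kind="squat",
        subject_id=subject.subject_id,
        condition="squat",
        extras={
            "peak_index": int(np.argmax(flexion)),
            "peak_flexion_deg": peak_deg,
            "start_flexion_deg": start_deg,
        },
    )


def generate_running_trial(
    subject: SubjectTruth, shoe: str, stride_index: int, cfg: CohortConfig
) -> Trial:
    """One running stride: flight - stance - flight on a uniform time base.

    The vertical force is a smooth bump peaking near 2.5 body weights and
    exactly zero outside stance; stance flexion rises from 15-20 deg at
    contact to 50 deg (the eccentric part, crossing 40 deg once rising)
    before falling again. At the rising 40-deg crossing the non-sagittal
    angles equal baseline + shoe offset (+ noise).
    """
    off_f, off_t = subject._offsets(shoe)
    rng = _rng(cfg.seed, "run", subject.subject_id, shoe, stride_index)
    fs = cfg.sampling_rate_mocap
    stance_s = float(rng.uniform(0.2, 0.35))
    flight_s = float(rng.uniform(0.06, 0.12))
    n = int(round((stance_s + 2 * flight_s) * fs)) + 1
    t = np.arange(n) / fs

    s = (t - flight_s) / stance_s  # stance-normalized time
    in_stance = (s >= 0.0) & (s <= 1.0)

    peak_force = float(rng.uniform(2.4, 2.6)) * subject.body_mass_kg * GRAVITY
    force = np.zeros(n)
    force[in_stance] = peak_force * np.sin(np.pi * np.clip(s[in_stance], 0.0, 1.0)) ** 2

    contact_deg = float(rng.uniform(15.0, 20.0))
    peak_deg = RUN_PEAK_FLEXION_DEG
    flexion = np.full(n, contact_deg)
    rising = in_stance & (s <= STANCE_PEAK_FRACTION)
    falling = in_stance & (s > STANCE_PEAK_FRACTION)
    flexion[rising] = contact_deg + (peak_deg - contact_deg) * 0.5 * (
        1.0 - np.cos(np.pi * s[rising] / STANCE_PEAK_FRACTION)
    )
    flexion[falling] = contact_deg + (peak_deg - contact_deg) * 0.5 * (
        1.0 + np.cos(np.pi * (s[falling] - STANCE_PEAK_FRACTION) / (1.0 - STANCE_PEAK_FRACTION))
    )
    frontal, transverse = _nonsagittal(
        flexion,
        subject.baseline_frontal_deg + off_f,
        subject.baseline_transverse_deg + off_t,
        subject.angle_noise_sd_deg,
        rng,
    )
    stance_idx = np.flatnonzero(in_stance)
    return Trial(
        time_s=t,
        flexion_deg=flexion,
        adduction_deg=frontal,
        int_rot_deg=transverse,
        grf_vertical_N=force,
        movement_kind="run",
        subject_id=subject.subject_id,
        condition=shoe,
        extras={
            "stance_start_index": int(stance_idx[0]),
            "stance_end_index": int(stance_idx[-1]) + 1,
            "stance_duration_s": stance_s,
            "peak_index": int(np.argmax(flexion)),
            "contact_flexion_deg": contact_deg,
        },
    )


def generate_marker_trial(
    pose_sequence: Sequence[Tuple[np.ndarray, np.ndarray]],
    template: np.ndarray,
    noise_sd_m: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Marker trajectories (n_frames, n_markers, 3): the template moved by
    each frame's (rotation, translation) plus isotropic Gaussian noise."""
    template = np.asarray(template, dtype=float)
    if template.ndim != 2 or template.shape[1] != 3 or template.shape[0] < 3:
        raise DegenerateGeometryError("template must be >=3 points of shape (n, 3)")
    centered = template - template.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-12 * max(1.0, sv[0]):
        raise DegenerateGeometryError("template points are collinear")
    rng = rng or np.random.default_rng()
    frames = np.empty((len(pose_sequence), template.shape[0], 3))
    for i, (rotation, translation) in enumerate(pose_sequence):
        frames[i] = template @ np.asarray(rotation, dtype=float).T + np.asarray(
            translation, dtype=float
        )
    if noise_sd_m > 0:
        frames = frames + rng.normal(0.0, noise_sd_m, size=frames.shape)
    return frames


def generate_cartilage_volumes(
    subject: SubjectTruth,
    shoe: str,
    realized_deviation: float,
    rng: Optional[np.random.Generator] = None,
) -> List[CartilageRecord]:
    """Seven region records with percent reductions linearly coupled to the
    realized deviation: ``alpha + beta * deviation + noise``, truncated to
    be non-negative; post volume = pre * (1 - reduction/100)."""
    if realized_deviation < 0:
        raise ValueError("realized_deviation must be >= 0")
    if shoe not in subject.shoe_offsets:
        raise UnknownShoeError(
            f"shoe {shoe!r} not defined for subject {subject.subject_id!r}; "
            f"known: {sorted(subject.shoe_offsets)}"
        )
    rng = rng or np.random.default_rng()
    records = []
    for region in REGIONS:
        reduction = (
            subject.coupling_alpha_pct[region]
            + subject.coupling_beta_pct_per_deg[region] * realized_deviation
        )
        if subject.reduction_noise_sd_pct > 0:
            reduction += float(rng.normal(0.0, subject.reduction_noise_sd_pct))
        reduction = max(reduction, 0.0)
        pre = subject.region_pre_volumes_mm3[region]
        records.append(
            CartilageRecord(
                subject_id=subject.subject_id,
                condition=shoe,
                region=region,
                pre_mm3=pre,
                post_mm3=pre * (1.0 - reduction / 100.0),
                mass_kg=subject.body_mass_kg,
                height_m=subject.body_height_m,
            )
        )
    return records


@dataclass
class CohortDataset:
    """Full synthetic dataset plus its generating truth."""

    cfg: CohortConfig
    subjects: List[SubjectTruth]
    squat_trials: Dict[str, List[Trial]]
    running_trials: Dict[Tuple[str, str], List[Trial]]
    cartilage_records: List[CartilageRecord]

    def truth_rows(self) -> List[dict]:
        rows = []
        for s in self.subjects:
            for shoe in self.cfg.shoes:
                df, dt, tot = s.expected_deviation(shoe)
                rows.append(
                    {
                        "subject": s.subject_id,
                        "condition": shoe,
                        "mass_kg": s.body_mass_kg,
                        "height_m": s.body_height_m,
                        "baseline_frontal_deg": s.baseline_frontal_deg,
                        "baseline_transverse_deg": s.baseline_transverse_deg,
                        "offset_frontal_deg": s.shoe_offsets[shoe][0],
                        "offset_transverse_deg": s.shoe_offsets[shoe][1],
                        "true_dev_front_deg": df,
                        "true_dev_trans_deg": dt,
                        "true_dev_total_deg": tot,
                    }
                )
        return rows


def generate_cohort(
    cfg: CohortConfig, params: Optional[TruthParams] = None
) -> CohortDataset:
    """Generate the full study dataset, deterministic under ``cfg.seed``.

    Cartilage reductions are coupled to each shoe's configured (noise-free)
    total deviation.
    """
    cfg.validate()
    params = params or TruthParams()
    subjects = [draw_subject_truth(i, cfg, params) for i in range(cfg.n_subjects)]
    squats = {
        s.subject_id: [
            generate_squat_trial(s, r, cfg) for r in range(cfg.n_squats_per_subject)
        ]
        for s in subjects
    }
    runs: Dict[Tuple[str, str], List[Trial]] = {}
    cartilage: List[CartilageRecord] = []
    for s in subjects:
        for shoe in cfg.shoes:
            runs[(s.subject_id, shoe)] = [
                generate_running_trial(s, shoe, k, cfg)
                for k in range(cfg.n_strides_per_condition)
            ]
            _, _, tot = s.expected_deviation(shoe)
            cartilage.extend(
                generate_cartilage_volumes(
                    s, shoe, tot, rng=_rng(cfg.seed, "cartilage", s.subject_id, shoe)
                )
            )
    return CohortDataset(
        cfg=cfg,
        subjects=subjects,
        squat_trials=squats,
        running_trials=runs,
        cartilage_records=cartilage,
    )
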