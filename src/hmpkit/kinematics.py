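"""Marker-to-angle kinematics and movement phase detection.

Provides the least-squares rigid segment fit, the Cardan decomposition of
the relative thigh/shank rotation into knee joint angles, stance detection
from vertical ground-reaction force, eccentric-phase delimitation, and the
extraction of frontal/transverse angles at the critical flexion angle.

Angle convention (declared, see package docs): intrinsic Cardan sequence
X -> Y' -> Z'' where X is flexion (mediolateral axis), Y adduction and Z
internal rotation; all angles in degrees, positive per right-hand rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    EmptyPhaseError,
    GimbalWarning,
    NoCrossingError,
)

#: Cardan sequence: flexion (X), adduction (Y), internal rotation (Z), intrinsic.
CARDAN_SEQUENCE = "XYZ"

#: Tolerance (deg) around |adduction| = 90 that triggers a gimbal warning.
_GIMBAL_TOL_DEG = 1e-6

_TIME_UNIFORMITY_TOL_S = 1e-6


@dataclass
class Trial:
    """One movement repetition: uniformly sampled knee angles (+ optional GRF).

    Attributes
    ----------
    time_s : ndarray
        Strictly increasing, uniform sample times in seconds.
    flexion_deg, adduction_deg, int_rot_deg : ndarray
        Knee joint angle components, degrees, same length as ``time_s``.
    grf_vertical_N : ndarray or None
        Vertical ground-reaction force (running trials only).
    movement_kind : str
        ``"squat"`` or ``"run"``.
    extras : dict
        Generator-side ground truth (e.g. ``peak_index``); never serialized.
    """

    time_s: np.ndarray
    flexion_deg: np.ndarray
    adduction_deg: np.ndarray
    int_rot_deg: np.ndarray
    grf_vertical_N: Optional[np.ndarray] = None
    movement_kind: str = "squat"
    subject_id: str = ""
    condition: str = ""
    extras: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        for name in ("flexion_deg", "adduction_deg", "int_rot_deg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.time_s.shape:
                raise ValueError(
                    f"{name} length {arr.size} != time length {self.time_s.size}"
                )
            setattr(self, name, arr)
        if self.grf_vertical_N is not None:
            grf = np.asarray(self.grf_vertical_N, dtype=float)
            if grf.shape != self.time_s.shape:
                raise ValueError("grf_vertical_N length mismatch with time")
            self.grf_vertical_N = grf
        if self.time_s.size < 2:
            raise ValueError("trial needs at least two samples")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        gap = float(np.max(np.abs(dt - dt.mean())))
        if gap > _TIME_UNIFORMITY_TOL_S:
            raise ValueError(f"time not uniform: max deviation {gap:.3g} s")

    @property
    def n_samples(self) -> int:
        return self.time_s.size

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])


@dataclass(frozen=True)
class SegmentPose:
    """Rigid pose of one body segment: proper rotation + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation determinant must be +1")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-9:
            raise ValueError("rotation must be orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)


@dataclass(frozen=True)
class PhaseInterval:
    """Half-open sample interval [start_index, end_index) of one phase."""

    start_index: int
    end_index: int
    kind: str = "stance"

    def __post_init__(self) -> None:
        if not 0 <= self.start_index < self.end_index:
            raise ValueError(
                f"invalid interval [{self.start_index}, {self.end_index})"
            )

    def __len__(self) -> int:
        return self.end_index - self.start_index


def _check_noncollinear(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-12 * max(1.0, s[0]):
        raise DegenerateGeometryError("template points are collinear")


def fit_rigid_transform(template: np.ndarray, observed: np.ndarray) -> SegmentPose:
    """Least-squares rigid transform mapping ``template`` onto ``observed``.

    Solves min_{R,t} sum_i ||R a_i + t - b_i||^2 over proper rotations
    (Kabsch/SVD with reflection correction). Returns the pose together with
    the RMS point residual.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 points or collinear template.
    ValueError
        Mismatched point counts.
    """
    a = np.asarray(template, dtype=float)
    b = np.asarray(observed, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or b.ndim != 2 or b.shape[1] != 3:
        raise ValueError("point sets must have shape (n, 3)")
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"point counts differ: template {a.shape[0]} vs observed {b.shape[0]}"
        )
    if a.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 matched points")
    _check_noncollinear(a)

    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    H = (a - ca).T @ (b - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    resid = b - (a @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return SegmentPose(rotation=R, translation=t, residual_rms=rms)


def compose_knee_angles(
    flexion_deg: float, adduction_deg: float, int_rot_deg: float
) -> np.ndarray:
    """Rotation matrix for the declared Cardan sequence (inverse of the
    decomposition in :func:`knee_angles_from_poses`)."""
    return Rotation.from_euler(
        CARDAN_SEQUENCE, [flexion_deg, adduction_deg, int_rot_deg], degrees=True
    ).as_matrix()


def knee_angles_from_poses(
    thigh: SegmentPose, shank: SegmentPose
) -> Tuple[float, float, float]:
    """Decompose the relative rotation thigh^T . shank into knee angles.

    Returns (flexion, adduction, internal rotation) in degrees. Emits a
    :class:`GimbalWarning` when |adduction| is within 1e-6 deg of 90.
    """
    rel = thigh.rotation.T @ shank.rotation
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy's own gimbal warning
        flex, add, rot = Rotation.from_matrix(rel).as_euler(
            CARDAN_SEQUENCE, degrees=True
        )
    if abs(abs(add) - 90.0) < _GIMBAL_TOL_DEG:
        warnings.warn(
            f"adduction {add:.9f} deg is at gimbal lock; flexion/rotation "
            "are not uniquely determined",
            GimbalWarning,
            stacklevel=2,
        )
    return float(flex), float(add), float(rot)


def knee_angle_series(
    thigh_poses: Sequence[SegmentPose], shank_poses: Sequence[SegmentPose]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame knee angles, unwrapped to be continuous across frames."""
    if len(thigh_poses) != len(shank_poses):
        raise ValueError("pose sequences differ in length")
    triples = np.array(
        [knee_angles_from_poses(th, sh) for th, sh in zip(thigh_poses, shank_poses)]
    )
    unwrapped = np.unwrap(triples, axis=0, period=360.0)
    return unwrapped[:, 0], unwrapped[:, 1], unwrapped[:, 2]


def detect_stance(
    grf_vertical: np.ndarray,
    threshold_N: float,
    sampling_rate: float,
    min_duration_s: float = 0.1,
) -> List[PhaseInterval]:
    """Maximal intervals with force >= threshold, edge-refined.

    Onset/offset are located by linear interpolation between the straddling
    samples and rounded to the nearest sample; intervals shorter than
    ``min_duration_s`` are discarded. Returns [] when nothing is found.
    """
    f = np.asarray(grf_vertical, dtype=float)
    above = f >= threshold_N
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(f.size)

    intervals: List[PhaseInterval] = []
    for i0, i1 in zip(starts, ends):
        start = i0
        if i0 > 0 and f[i0] != f[i0 - 1]:
            frac = (threshold_N - f[i0 - 1]) / (f[i0] - f[i0 - 1])
            start = int(round(i0 - 1 + frac))
        end = i1
        if i1 < f.size and f[i1 - 1] != f[i1]:
            frac = (f[i1 - 1] - threshold_N) / (f[i1 - 1] - f[i1])
            end = max(int(round(i1 - 1 + frac)), i1 - 1)
        start = max(start, 0)
        end = min(end, f.size)
        if end <= start:
            continue
        if (end - start) / sampling_rate < min_duration_s:
            continue
        intervals.append(PhaseInterval(start, end, kind="stance"))
    return intervals


def detect_eccentric_phase(
    flexion_deg: np.ndarray, within: Optional[PhaseInterval] = None
) -> PhaseInterval:
    """Interval from the search-region start to the flexion maximum.

    The returned half-open interval includes the maximum-flexion sample.

    Raises
    ------
    EmptyPhaseError
        Maximum at the first sample (no flexion-increasing portion).
    """
    flex = np.asarray(flexion_deg, dtype=float)
    if within is None:
        start, end = 0, flex.size
    else:
        start, end = within.start_index, within.end_index
        if end > flex.size:
            raise ValueError("interval extends beyond series")
    region = flex[start:end]
    if region.size < 2:
        raise EmptyPhaseError("search region too short for an eccentric phase")
    peak = int(np.argmax(region)) + start
    if peak == start:
        raise EmptyPhaseError("flexion maximum at first sample; no eccentric phase")
    return PhaseInterval(start, peak + 1, kind="eccentric")


def angles_at_critical_flexion(
    trial: Trial, phase: PhaseInterval, critical_deg: float
) -> Tuple[float, float]:
    """Frontal/transverse angles at the first rising crossing of the
    critical flexion angle inside ``phase``, linearly interpolated.

    An exact sample hit on a rising segment returns that sample's angles.

    Raises
    ------
    NoCrossingError
        No rising crossing inside the phase; the message names the trial.
    """
    flex = trial.flexion_deg
    frontal = trial.adduction_deg
    transverse = trial.int_rot_deg
    i0, i1 = phase.start_index, phase.end_index
    for i in range(i0, i1 - 1):
        lo, hi = flex[i], flex[i + 1]
        if lo == critical_deg and hi > lo:
            return float(frontal[i]), float(transverse[i])
        if lo < critical_deg <= hi:
            if hi == critical_deg:
                return float(frontal[i + 1]), float(transverse[i + 1])
            frac = (critical_deg - lo) / (hi - lo)
            return (
                float(frontal[i] + frac * (frontal[i + 1] - frontal[i])),
                float(transverse[i] + frac * (transverse[i + 1] - transverse[i])),
            )
    ident = f"{trial.subject_id or 'trial'}/{trial.condition or trial.movement_kind}"
    raise NoCrossingError(
        f"flexion never crosses {critical_deg} deg rising inside "
        f"[{i0}, {i1}) of {ident}"
    )


def lowpass(
    series: np.ndarray, cutoff_hz: float, sampling_rate: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass; output length equals input length."""
    nyquist = sampling_rate / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=sampling_rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(series, dtype=float))
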