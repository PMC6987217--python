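"""Central analysis configuration.

All tunable constants of the analysis live here with their defaults: the
critical flexion angle (40 deg), the transverse-plane weight of the total
deviation score (0.5), the stance-detection threshold, filter settings,
the significance level, and the deterministic tie rules.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .errors import ConfigError

#: Default footwear condition order; also the deterministic tie-break order.
DEFAULT_SHOE_ORDER = ("neutral", "lateral_post", "medial_post")

#: Knee flexion angle (degrees) at which non-sagittal angles are sampled.
CRITICAL_FLEXION_DEG = 40.0

#: Weight applied to the transverse-plane deviation in the total score.
TRANSVERSE_WEIGHT = 0.5


@dataclass
class AnalysisConfig:
    """End-to-end pipeline settings with validated invariants."""

    critical_flexion_deg: float = CRITICAL_FLEXION_DEG
    eq1_transverse_weight: float = TRANSVERSE_WEIGHT
    stance_threshold_N: float = 20.0
    min_stance_duration_s: float = 0.1
    # Filters are opt-in: None disables. Zero-phase Butterworth when set.
    angle_lowpass_hz: Optional[float] = None
    force_lowpass_hz: Optional[float] = None
    filter_order: int = 4
    alpha: float = 0.05
    seed: int = 0
    signed_deviation: bool = False
    holm_correction: bool = False
    shoe_order: Sequence[str] = field(default_factory=lambda: list(DEFAULT_SHOE_ORDER))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bad = []
        if not 0.0 < self.critical_flexion_deg < 90.0:
            bad.append("critical_flexion_deg")
        if not self.eq1_transverse_weight > 0.0:
            bad.append("eq1_transverse_weight")
        if not 0.0 < self.alpha < 1.0:
            bad.append("alpha")
        if self.stance_threshold_N < 0.0:
            bad.append("stance_threshold_N")
        if self.min_stance_duration_s < 0.0:
            bad.append("min_stance_duration_s")
        if self.filter_order < 1:
            bad.append("filter_order")
        for name in ("angle_lowpass_hz", "force_lowpass_hz"):
            value = getattr(self, name)
            if value is not None and value <= 0.0:
                bad.append(name)
        if bad:
            raise ConfigError(
                "invalid analysis configuration: " + ", ".join(bad), fields=bad
            )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(
                "unknown configuration keys: " + ", ".join(sorted(unknown)),
                fields=sorted(unknown),
            )
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_mapping(data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["shoe_order"] = list(self.shoe_order)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
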