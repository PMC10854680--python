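"""Ordinal EHR feature assembly for the regular and privileged spaces.

Regular-space EHR features are collected at five lookback times (t-16, t-12,
t-8, t-4 and t0 hours); the privileged vector uses the single observation in
the ten minutes ending at t6.  Each time block concatenates, in order:

* five vital signs (temperature degC, SpO2 %, heart rate bpm, mean arterial
  pressure mmHg, respiratory rate /min) and hourly urine output (mL/h),
  numeric;
* ten lab values, ordinally encoded 1..4 in increasing severity
  (0 = nothing logged);
* seven cardiovascular infusions, ordinally encoded 1..3 by dose severity
  (0 = not running).

So a block is 23 values; the regular vector spans 5 blocks (115 values) and
the privileged vector one block (23 values).  Missing numeric vitals/urine
are filled by last observation carried forward across lookbacks, falling
back to a configured population default; missing labs/infusions encode as 0.

The encoding thresholds shipped in :func:`default_encoding_config` are
clinically plausible defaults, not a canonical published table; they are
fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .exceptions import ConfigurationError, InputError

__all__ = [
    "LOOKBACK_OFFSETS_H",
    "PRIVILEGED_OFFSET_H",
    "VITAL_NAMES",
    "LAB_NAMES",
    "INFUSION_NAMES",
    "REGULAR_EHR_LENGTH",
    "PRIVILEGED_EHR_LENGTH",
    "EhrObservation",
    "LabEncoder",
    "InfusionEncoder",
    "OrdinalEncodingConfig",
    "default_encoding_config",
    "encode_labs",
    "encode_infusions",
    "assemble_regular_ehr",
    "assemble_privileged_ehr",
]

LOOKBACK_OFFSETS_H: tuple[float, ...] = (-16.0, -12.0, -8.0, -4.0, 0.0)
PRIVILEGED_OFFSET_H: float = 6.0
_ALLOWED_OFFSETS = frozenset(LOOKBACK_OFFSETS_H) | {PRIVILEGED_OFFSET_H}

VITAL_NAMES: tuple[str, ...] = (
    "temperature",
    "spo2",
    "heart_rate",
    "mean_arterial_pressure",
    "respiratory_rate",
)
LAB_NAMES: tuple[str, ...] = (
    "creatinine",
    "glucose",
    "hematocrit",
    "hemoglobin",
    "inr",
    "lactate",
    "platelet_count",
    "potassium",
    "sodium",
    "wbc",
)
INFUSION_NAMES: tuple[str, ...] = (
    "dobutamine",
    "dopamine",
    "epinephrine",
    "isoproterenol",
    "milrinone",
    "norepinephrine",
    "vasopressin",
)

_BLOCK_LENGTH = len(VITAL_NAMES) + 1 + len(LAB_NAMES) + len(INFUSION_NAMES)  # 23
REGULAR_EHR_LENGTH = _BLOCK_LENGTH * len(LOOKBACK_OFFSETS_H)  # 115
PRIVILEGED_EHR_LENGTH = _BLOCK_LENGTH  # 23


@dataclass(frozen=True)
class EhrObservation:
    """Timestamped EHR snapshot matched to one timeline offset.

    ``vitals`` maps vital names to values (missing keys allowed), ``labs``
    and ``infusions`` map names to raw values/doses; absent entries mean
    nothing was logged.
    """

    time_offset_h: float
    vitals: Mapping[str, float] = field(default_factory=dict)
    urine_output: float | None = None
    labs: Mapping[str, float] = field(default_factory=dict)
    infusions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_offset_h not in _ALLOWED_OFFSETS:
            raise InputError(
                f"time_offset_h must be one of {sorted(_ALLOWED_OFFSETS)}, "
                f"got {self.time_offset_h}"
            )
        for name in self.vitals:
            if name not in VITAL_NAMES:
                raise InputError(f"unknown vital {name!r}")
        for name in self.labs:
            if name not in LAB_NAMES:
                raise InputError(f"unknown lab {name!r}")
        for name in self.infusions:
            if name not in INFUSION_NAMES:
                raise InputError(f"unknown infusion {name!r}")


@dataclass(frozen=True)
class LabEncoder:
    """Threshold encoder for one lab: raw value -> severity 1..4.

    ``thresholds`` are three strictly increasing cut points.  With direction
    ``"high"`` severity increases with the value (bin i if value < t_i,
    else 4); with ``"low"`` it increases as the value falls.
    """

    thresholds: tuple[float, float, float]
    direction: str = "high"

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.thresholds)
        if len(t) != 3 or not (t[0] < t[1] < t[2]):
            raise ConfigurationError(
                f"lab thresholds must be three strictly increasing values, got {t}"
            )
        if self.direction not in ("high", "low"):
            raise ConfigurationError("direction must be 'high' or 'low'")
        object.__setattr__(self, "thresholds", t)

    def encode(self, value: float | None) -> int:
        if value is None:
            return 0
        # a value exactly on a cut point stays in the milder bin
        severity = 1 + int(np.searchsorted(self.thresholds, value, side="left"))
        if self.direction == "low":
            severity = 5 - severity
        return severity


@dataclass(frozen=True)
class InfusionEncoder:
    """Dose encoder for one infusion: raw dose -> severity 1..3."""

    thresholds: tuple[float, float]

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.thresholds)
        if len(t) != 2 or not (t[0] < t[1]):
            raise ConfigurationError(
                f"infusion thresholds must be two strictly increasing values, got {t}"
            )
        object.__setattr__(self, "thresholds", t)

    def encode(self, dose: float | None) -> int:
        if dose is None:
            return 0
        return 1 + int(np.searchsorted(self.thresholds, dose, side="left"))


@dataclass(frozen=True)
class OrdinalEncodingConfig:
    """Per-lab and per-infusion encoders plus numeric fill defaults."""

    labs: Mapping[str, LabEncoder]
    infusions: Mapping[str, InfusionEncoder]
    vital_defaults: Mapping[str, float]
    urine_default: float

    def __post_init__(self) -> None:
        missing = [n for n in LAB_NAMES if n not in self.labs]
        if missing:
            raise ConfigurationError(f"missing lab encoders: {missing}")
        missing = [n for n in INFUSION_NAMES if n not in self.infusions]
        if missing:
            raise ConfigurationError(f"missing infusion encoders: {missing}")
        missing = [n for n in VITAL_NAMES if n not in self.vital_defaults]
        if missing:
            raise ConfigurationError(f"missing vital defaults: {missing}")


def default_encoding_config() -> OrdinalEncodingConfig:
    """Clinically plausible default thresholds (non-canonical).

    Lab cut points follow common abnormality grades (e.g. lactate 2/4/8
    mmol/L); infusion cut points follow typical low/high dose ranges
    (e.g. norepinephrine 0.1/0.5 ug/kg/min).
    """
    labs = {
        "creatinine": LabEncoder((1.2, 2.0, 3.5)),  # mg/dL
        "glucose": LabEncoder((140.0, 180.0, 250.0)),  # mg/dL
        "hematocrit": LabEncoder((21.0, 27.0, 36.0), direction="low"),  # %
        "hemoglobin": LabEncoder((7.0, 9.0, 12.0), direction="low"),  # g/dL
        "inr": LabEncoder((1.2, 1.5, 2.5)),
        "lactate": LabEncoder((2.0, 4.0, 8.0)),  # mmol/L
        "platelet_count": LabEncoder((50.0, 100.0, 150.0), direction="low"),  # 1e3/uL
        "potassium": LabEncoder((4.5, 5.5, 6.5)),  # mEq/L
        "sodium": LabEncoder((146.0, 150.0, 155.0)),  # mEq/L
        "wbc": LabEncoder((12.0, 20.0, 35.0)),  # 1e3/uL
    }
    infusions = {
        "dobutamine": InfusionEncoder((5.0, 10.0)),  # ug/kg/min
        "dopamine": InfusionEncoder((5.0, 15.0)),  # ug/kg/min
        "epinephrine": InfusionEncoder((0.05, 0.2)),  # ug/kg/min
        "isoproterenol": InfusionEncoder((2.0, 10.0)),  # ug/min
        "milrinone": InfusionEncoder((0.25, 0.5)),  # ug/kg/min
        "norepinephrine": InfusionEncoder((0.1, 0.5)),  # ug/kg/min
        "vasopressin": InfusionEncoder((0.03, 0.06)),  # U/min
    }
    vital_defaults = {
        "temperature": 37.0,
        "spo2": 97.0,
        "heart_rate": 80.0,
        "mean_arterial_pressure": 85.0,
        "respiratory_rate": 16.0,
    }
    return OrdinalEncodingConfig(
        labs=labs, infusions=infusions, vital_defaults=vital_defaults, urine_default=60.0
    )


def encode_labs(
    raw_labs: Mapping[str, float], config: OrdinalEncodingConfig
) -> np.ndarray:
    """Ten lab ordinals in :data:`LAB_NAMES` order (absent -> 0)."""
    return np.array(
        [config.labs[name].encode(raw_labs.get(name)) for name in LAB_NAMES],
        dtype=np.float64,
    )


def encode_infusions(
    raw_infusions: Mapping[str, float], config: OrdinalEncodingConfig
) -> np.ndarray:
    """Seven infusion ordinals in :data:`INFUSION_NAMES` order (absent -> 0)."""
    return np.array(
        [config.infusions[name].encode(raw_infusions.get(name)) for name in INFUSION_NAMES],
        dtype=np.float64,
    )


def _encode_block(
    obs: EhrObservation | None,
    config: OrdinalEncodingConfig,
    carried_vitals: dict[str, float],
    carried_urine: list[float],
) -> np.ndarray:
    """One 23-value time block, updating the carry-forward state in place."""
    vitals = obs.vitals if obs is not None else {}
    for name in VITAL_NAMES:
        if name in vitals and vitals[name] is not None:
            carried_vitals[name] = float(vitals[name])
    if obs is not None and obs.urine_output is not None:
        carried_urine[0] = float(obs.urine_output)
    numeric = [carried_vitals[name] for name in VITAL_NAMES] + [carried_urine[0]]
    labs = encode_labs(obs.labs if obs is not None else {}, config)
    infusions = encode_infusions(obs.infusions if obs is not None else {}, config)
    return np.concatenate([numeric, labs, infusions])


def assemble_regular_ehr(
    observations: Iterable[EhrObservation], config: OrdinalEncodingConfig
) -> np.ndarray:
    """The 115-value regular-space EHR vector over the five lookback times.

    Observations are keyed by their ``time_offset_h``; offsets other than
    the five lookbacks (a stray t6 observation, say) are rejected.  Blocks
    are concatenated in time order from t-16 to t0.
    """
    by_offset: dict[float, EhrObservation] = {}
    for obs in observations:
        if obs.time_offset_h not in LOOKBACK_OFFSETS_H:
            raise InputError(
                f"regular-space assembly accepts offsets {LOOKBACK_OFFSETS_H}, "
                f"got {obs.time_offset_h}"
            )
        by_offset[obs.time_offset_h] = obs
    carried_vitals = dict(config.vital_defaults)
    carried_urine = [config.urine_default]
    blocks = [
        _encode_block(by_offset.get(offset), config, carried_vitals, carried_urine)
        for offset in LOOKBACK_OFFSETS_H
    ]
    vector = np.concatenate(blocks)
    assert vector.size == REGULAR_EHR_LENGTH
    return vector


def assemble_privileged_ehr(
    observation: EhrObservation, config: OrdinalEncodingConfig
) -> np.ndarray:
    """The 23-value privileged-space EHR vector from the t6 observation."""
    if observation.time_offset_h != PRIVILEGED_OFFSET_H:
        raise InputError(
            f"privileged-space assembly requires the t+{PRIVILEGED_OFFSET_H:.0f}h "
            f"observation, got offset {observation.time_offset_h}"
        )
    carried_vitals = dict(config.vital_defaults)
    carried_urine = [config.urine_default]
    vector = _encode_block(observation, config, carried_vitals, carried_urine)
    assert vector.size == PRIVILEGED_EHR_LENGTH
    return vector
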