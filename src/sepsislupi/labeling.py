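"""qSOFA scoring and 6-hour-ahead deterioration labels.

The quick Sequential Organ Failure Assessment (qSOFA) score sums three
binary criteria, each boundary inclusive: Glasgow Coma Scale <= 13,
systolic blood pressure <= 100 mmHg, respiratory rate >= 22 /min.  An
instance is anchored at a time t0 where qSOFA equals 1; the prediction task
is whether the score reaches >= 2 at t6 = t0 + 6 h (label +1) or stays
below 2 (label -1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .ehr import EhrObservation, LOOKBACK_OFFSETS_H, PRIVILEGED_OFFSET_H
from .exceptions import InputError
from .signal_features import ECGSegment, QualityConfig, noise_fraction

__all__ = [
    "QsofaInputs",
    "PatientInstance",
    "RejectionReason",
    "InstanceRejection",
    "qsofa_score",
    "label_instance",
    "build_instance",
]

NOISE_THRESHOLD = 0.5  # segments at or above this noise fraction are discarded


@dataclass(frozen=True)
class QsofaInputs:
    """The three qSOFA inputs at one time point."""

    gcs: int  # Glasgow Coma Scale, 3..15 (taken as given, not recomputed)
    sbp: float  # systolic blood pressure, mmHg
    rr: float  # respiratory rate, breaths/min

    def __post_init__(self) -> None:
        if not 3 <= self.gcs <= 15:
            raise InputError(f"GCS must be in [3, 15], got {self.gcs}")
        if self.sbp <= 0:
            raise InputError(f"SBP must be positive, got {self.sbp}")
        if self.rr < 0:
            raise InputError(f"respiratory rate must be >= 0, got {self.rr}")


def qsofa_score(q: QsofaInputs) -> int:
    """Sum of the three criteria; each inclusive boundary contributes 1."""
    return int(q.gcs <= 13) + int(q.sbp <= 100.0) + int(q.rr >= 22.0)


def label_instance(score_t6: int) -> int:
    """+1 if qSOFA reached >= 2 at t6, else -1."""
    if not 0 <= score_t6 <= 3:
        raise InputError(f"qSOFA score must be in 0..3, got {score_t6}")
    return 1 if score_t6 >= 2 else -1


class RejectionReason(Enum):
    """Why a raw record could not become a usable instance."""

    MISSING_REGULAR_ECG = "missing regular ECG"
    MISSING_PRIVILEGED_ECG = "missing privileged ECG"
    MISSING_EHR = "missing EHR"
    NOISE = "ECG segment is >= 50% noise"
    QSOFA_T0_NOT_ONE = "qSOFA at t0 is not 1"


@dataclass(frozen=True)
class InstanceRejection:
    """A reason-coded rejection; records are never dropped silently."""

    patient_id: str
    reason: RejectionReason
    detail: str = ""


@dataclass(frozen=True)
class PatientInstance:
    """One labelled prediction instance on the t0/t6 timeline."""

    patient_id: str
    regular_ecg: ECGSegment  # 10 minutes ending at t0
    privileged_ecg: ECGSegment  # 10 minutes ending at t6
    ehr_observations: tuple[EhrObservation, ...]  # offsets -16..0 and +6 h
    qsofa_t0: QsofaInputs
    qsofa_t6: QsofaInputs
    label: int = field(init=False)

    def __post_init__(self) -> None:
        if qsofa_score(self.qsofa_t0) != 1:
            raise InputError("instance anchor requires qSOFA(t0) == 1")
        if self.regular_ecg.anchor != "t0" or self.privileged_ecg.anchor != "t6":
            raise InputError("ECG segments must be anchored at t0 and t6")
        object.__setattr__(self, "label", label_instance(qsofa_score(self.qsofa_t6)))

    @property
    def privileged_observation(self) -> EhrObservation | None:
        for obs in self.ehr_observations:
            if obs.time_offset_h == PRIVILEGED_OFFSET_H:
                return obs
        return None

    @property
    def regular_observations(self) -> tuple[EhrObservation, ...]:
        return tuple(
            obs for obs in self.ehr_observations if obs.time_offset_h in LOOKBACK_OFFSETS_H
        )


def build_instance(
    patient_id: str,
    regular_ecg: ECGSegment | None,
    privileged_ecg: ECGSegment | None,
    ehr_observations: Sequence[EhrObservation],
    qsofa_t0: QsofaInputs,
    qsofa_t6: QsofaInputs,
    quality: QualityConfig | None = None,
) -> PatientInstance | InstanceRejection:
    """Assemble a :class:`PatientInstance`, or reject with a reason code.

    Rejection reasons mirror the cohort construction rules: both 10-minute
    ECG windows must exist, at least one EHR observation must exist, both
    segments must be under 50% noise, and the anchor requires qSOFA(t0) = 1.
    """
    if regular_ecg is None:
        return InstanceRejection(patient_id, RejectionReason.MISSING_REGULAR_ECG)
    if privileged_ecg is None:
        return InstanceRejection(patient_id, RejectionReason.MISSING_PRIVILEGED_ECG)
    if not ehr_observations:
        return InstanceRejection(patient_id, RejectionReason.MISSING_EHR)
    if qsofa_score(qsofa_t0) != 1:
        return InstanceRejection(
            patient_id,
            RejectionReason.QSOFA_T0_NOT_ONE,
            detail=f"qSOFA(t0) = {qsofa_score(qsofa_t0)}",
        )
    for name, seg in (("regular", regular_ecg), ("privileged", privileged_ecg)):
        frac = noise_fraction(seg, quality)
        if frac >= NOISE_THRESHOLD:
            return InstanceRejection(
                patient_id,
                RejectionReason.NOISE,
                detail=f"{name} segment noise fraction {frac:.2f}",
            )
    return PatientInstance(
        patient_id=patient_id,
        regular_ecg=regular_ecg,
        privileged_ecg=privileged_ecg,
        ehr_observations=tuple(ehr_observations),
        qsofa_t0=qsofa_t0,
        qsofa_t6=qsofa_t6,
    )
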