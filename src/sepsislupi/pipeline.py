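"""Instance featurization: from patient timelines to model-ready matrices.

For each instance the regular space holds the 60-value taut-string ECG
tensor (2 windows x 5 epsilons x 6 features) and the 115-value EHR lookback
vector; the privileged space holds the 30-value TS-ECG bank, the 7-value
SF-ECG statistical set and the 23-value t6 EHR block.  ECG segments are
band-pass filtered before feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cohort import SyntheticPatient
from .ehr import (
    OrdinalEncodingConfig,
    PRIVILEGED_EHR_LENGTH,
    REGULAR_EHR_LENGTH,
    assemble_privileged_ehr,
    assemble_regular_ehr,
    default_encoding_config,
)
from .exceptions import InputError
from .labeling import PatientInstance
from .signal_features import (
    bandpass_filter,
    privileged_ecg_features,
    regular_ecg_features,
)
from .taut_string import DEFAULT_EPSILONS

__all__ = ["REGULAR_SPACES", "PI_TYPES", "FeaturizedCohort", "featurize_instances"]

REGULAR_SPACES = ("ecg", "ehr", "ecg_ehr")
PI_TYPES = ("none", "ts_ecg", "sf_ecg", "ehr")


@dataclass(frozen=True)
class FeaturizedCohort:
    """Row-aligned feature matrices for a cohort of instances."""

    patient_ids: np.ndarray  # (n,) str
    y: np.ndarray  # (n,) in {-1, +1}
    ecg: np.ndarray  # (n, 60) regular taut-string tensor, flattened
    ehr: np.ndarray  # (n, 115) regular EHR lookback vector
    pi_ts: np.ndarray  # (n, 30) privileged TS-ECG bank
    pi_sf: np.ndarray  # (n, 7) privileged SF-ECG statistics
    pi_ehr: np.ndarray  # (n, 23) privileged t6 EHR block

    def __len__(self) -> int:
        return self.y.size

    def regular(self, space: str) -> np.ndarray:
        """Regular-space design matrix for 'ecg', 'ehr' or 'ecg_ehr'."""
        if space == "ecg":
            return self.ecg
        if space == "ehr":
            return self.ehr
        if space == "ecg_ehr":
            return np.hstack([self.ecg, self.ehr])
        raise InputError(f"unknown regular space {space!r}; choose from {REGULAR_SPACES}")

    def privileged(self, pi_type: str) -> np.ndarray | None:
        """Privileged matrix for a PI type; None for the plain-SVM baseline."""
        if pi_type == "none":
            return None
        if pi_type == "ts_ecg":
            return self.pi_ts
        if pi_type == "sf_ecg":
            return self.pi_sf
        if pi_type == "ehr":
            return self.pi_ehr
        raise InputError(f"unknown PI type {pi_type!r}; choose from {PI_TYPES}")

    def subset(self, idx: np.ndarray) -> "FeaturizedCohort":
        return FeaturizedCohort(
            patient_ids=self.patient_ids[idx],
            y=self.y[idx],
            ecg=self.ecg[idx],
            ehr=self.ehr[idx],
            pi_ts=self.pi_ts[idx],
            pi_sf=self.pi_sf[idx],
            pi_ehr=self.pi_ehr[idx],
        )

    def to_frame(self):
        """All features in one labelled DataFrame (CSV-friendly)."""
        import pandas as pd

        cols: dict[str, np.ndarray] = {"patient_id": self.patient_ids, "label": self.y}
        for name, mat in (
            ("ecg", self.ecg),
            ("ehr", self.ehr),
            ("pi_ts", self.pi_ts),
            ("pi_sf", self.pi_sf),
            ("pi_ehr", self.pi_ehr),
        ):
            for j in range(mat.shape[1]):
                cols[f"{name}_{j:03d}"] = mat[:, j]
        return pd.DataFrame(cols)


def featurize_instances(
    instances: Iterable[PatientInstance | SyntheticPatient],
    encoding: OrdinalEncodingConfig | None = None,
    epsilons: Sequence[float] = DEFAULT_EPSILONS,
) -> FeaturizedCohort:
    """Featurize instances (or synthetic patients) into aligned matrices.

    Streams one instance at a time, so cohorts of full-length ECG segments
    never need to be held in memory at once.
    """
    encoding = encoding or default_encoding_config()
    ids: list[str] = []
    ys: list[int] = []
    ecg_rows: list[np.ndarray] = []
    ehr_rows: list[np.ndarray] = []
    ts_rows: list[np.ndarray] = []
    sf_rows: list[np.ndarray] = []
    pehr_rows: list[np.ndarray] = []
    for item in instances:
        inst = item.instance if isinstance(item, SyntheticPatient) else item
        reg = bandpass_filter(inst.regular_ecg)
        priv = bandpass_filter(inst.privileged_ecg)
        ecg_rows.append(regular_ecg_features(reg, epsilons).flatten())
        pfeat = privileged_ecg_features(priv, epsilons)
        ts_rows.append(pfeat.ts_vector())
        sf_rows.append(pfeat.sf_vector())
        ehr_rows.append(assemble_regular_ehr(inst.regular_observations, encoding))
        pobs = inst.privileged_observation
        if pobs is None:
            raise InputError(f"instance {inst.patient_id} lacks a t6 EHR observation")
        pehr_rows.append(assemble_privileged_ehr(pobs, encoding))
        ids.append(inst.patient_id)
        ys.append(inst.label)
    if not ids:
        raise InputError("no instances to featurize")
    cohort = FeaturizedCohort(
        patient_ids=np.array(ids),
        y=np.array(ys, dtype=np.int64),
        ecg=np.vstack(ecg_rows),
        ehr=np.vstack(ehr_rows),
        pi_ts=np.vstack(ts_rows),
        pi_sf=np.vstack(sf_rows),
        pi_ehr=np.vstack(pehr_rows),
    )
    assert cohort.ehr.shape[1] == REGULAR_EHR_LENGTH
    assert cohort.pi_ehr.shape[1] == PRIVILEGED_EHR_LENGTH
    return cohort
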