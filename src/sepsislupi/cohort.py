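"""Synthetic patient cohorts with the timeline structure the analysis assumes.

The generator emulates the study's input shape — a 10-minute lead-II ECG
segment at 240 Hz at each of two anchors (t0 and t6), EHR observations at
the five lookback times plus t6, and outcome labels produced strictly by
the qSOFA rules on the generated t6 vitals — so that every pipeline stage
and the SVM-vs-SVM+ comparison can be exercised without any clinical data.

Class structure:

* the ECG class signal is planted in beat-interval variability and additive
  noise amplitude (decompensation plausibly alters heart-rate variability),
  scaled by ``ecg_effect``;
* the EHR class signal is a drift of vitals and a shift of lab/infusion
  severity distributions, scaled by ``ehr_effect``;
* ``pi_informativeness`` in [0, 1] controls how strongly the t6 (privileged)
  data reflect the outcome: at 1 the generated t6 vitals reach qSOFA >= 2
  exactly for true positives; at 0 the t6 outcome is an independent coin
  with the cohort base rate.

Every effect vanishes when its scale is 0, so a fully null cohort carries
no learnable signal.  Default cohort shape mirrors the broader of the two
study cohorts (453 instances, 31.8% positive); ``cohort1_config`` mirrors
the small critically-ill cohort (106 instances, 55.7% positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .ehr import (
    EhrObservation,
    INFUSION_NAMES,
    LAB_NAMES,
    LOOKBACK_OFFSETS_H,
    OrdinalEncodingConfig,
    PRIVILEGED_OFFSET_H,
    default_encoding_config,
)
from .exceptions import InputError, ParameterError
from .labeling import PatientInstance, QsofaInputs, label_instance, qsofa_score
from .signal_features import ECGSegment

__all__ = [
    "CohortConfig",
    "SyntheticPatient",
    "cohort1_config",
    "cohort2_config",
    "generate_ecg_segment",
    "generate_ehr_timeline",
    "iter_cohort",
    "generate_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the simulated study conditions."""

    n_patients: int = 453
    positive_fraction: float = 0.318
    ecg_effect: float = 1.0
    ehr_effect: float = 1.0
    pi_informativeness: float = 0.8
    noise_sd: float = 0.05  # mV, additive ECG noise for the negative class
    seed: int = 0
    ecg_duration_s: float = 600.0
    sampling_rate: float = 240.0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ParameterError("n_patients must be >= 4")
        if not 0 < self.positive_fraction < 1:
            raise ParameterError("positive_fraction must be in (0, 1)")
        if self.ecg_effect < 0 or self.ehr_effect < 0 or self.noise_sd < 0:
            raise ParameterError("effect sizes and noise_sd must be >= 0")
        if not 0 <= self.pi_informativeness <= 1:
            raise ParameterError("pi_informativeness must be in [0, 1]")


def cohort1_config(**overrides) -> CohortConfig:
    """Shape of the small critically-ill cohort (106 instances, 59 positive)."""
    return replace(CohortConfig(n_patients=106, positive_fraction=0.557), **overrides)


def cohort2_config(**overrides) -> CohortConfig:
    """Shape of the broader cohort (453 instances, 144 positive)."""
    return replace(CohortConfig(), **overrides)


@dataclass(frozen=True)
class SyntheticPatient:
    """A generated instance plus its generating parameters (ground truth)."""

    instance: PatientInstance
    true_class: int  # +1 / -1, the planted class driving the effects
    heart_rate_bpm: float
    jitter_sd_s: float
    noise_sd_mv: float


def generate_ecg_segment(
    hr: float,
    noise_sd: float,
    duration_s: float,
    rng: np.random.Generator,
    rate: float = 240.0,
    anchor: str = "t0",
    jitter_sd: float = 0.04,
    qrs_width_s: float = 0.024,
    qrs_amplitude_mv: float = 1.1,
    wander_amplitude_mv: float = 0.08,
) -> ECGSegment:
    """A QRS-like periodic pulse train with jitter, wander and white noise.

    Each beat is a Gaussian bump of width ``qrs_width_s`` at intervals of
    60/hr seconds with Gaussian beat-to-beat jitter; a slow sinusoidal
    baseline wander and additive white noise complete the segment.
    Amplitudes are on the millivolt scale of lead II.
    """
    if not 30.0 <= hr <= 220.0:
        raise InputError(f"heart rate must be in [30, 220] bpm, got {hr}")
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)
    mean_rr = 60.0 / hr
    n_beats = int(duration_s / mean_rr) + 2
    intervals = np.full(n_beats, mean_rr)
    if jitter_sd > 0:
        intervals += jitter_sd * rng.standard_normal(n_beats)
    intervals = np.clip(intervals, 0.25, 2.0)
    centers = np.cumsum(intervals) - intervals[0] * 0.5
    half_support = 4.0 * qrs_width_s
    for c in centers:
        if c >= duration_s + half_support:
            break
        lo = max(int((c - half_support) * rate), 0)
        hi = min(int((c + half_support) * rate) + 1, n)
        if lo >= hi:
            continue
        dt = t[lo:hi] - c
        x[lo:hi] += qrs_amplitude_mv * np.exp(-0.5 * (dt / qrs_width_s) ** 2)
    if wander_amplitude_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += wander_amplitude_mv * np.sin(2 * np.pi * 0.3 * t + phase)
    if noise_sd > 0:
        x += noise_sd * rng.standard_normal(n)
    return ECGSegment(samples=x, anchor=anchor, sampling_rate=rate, duration_s=duration_s)


def _severity_raw_value(lab: str, severity: int, config: OrdinalEncodingConfig,
                        rng: np.random.Generator) -> float:
    """A raw lab value that the configured encoder maps to ``severity``."""
    enc = config.labs[lab]
    t1, t2, t3 = enc.thresholds
    bin_index = severity - 1 if enc.direction == "high" else 4 - severity
    edges = [t1 - 0.5 * abs(t1) - 0.1, t1, t2, t3, t3 + 0.5 * abs(t3) + 0.1]
    lo, hi = edges[bin_index], edges[bin_index + 1]
    v = rng.uniform(lo, hi)
    # keep off the boundary so encoding is unambiguous
    return float(np.clip(v, lo + 1e-6, hi - 1e-6))


def _class_severity(rng: np.random.Generator, shift: float) -> int:
    """Severity 1..4 from a distribution tilted upward by ``shift`` >= 0."""
    base = np.array([0.55, 0.25, 0.13, 0.07])
    tilt = np.array([-1.0, 0.0, 0.5, 1.0]) * shift
    p = base * np.exp(tilt)
    p /= p.sum()
    return int(rng.choice(4, p=p)) + 1


def _vitals_block(state: dict[str, float]) -> dict[str, float]:
    return {
        "temperature": state["temperature"],
        "spo2": state["spo2"],
        "heart_rate": state["heart_rate"],
        "mean_arterial_pressure": state["map"],
        "respiratory_rate": state["rr"],
    }


def generate_ehr_timeline(
    true_class: int,
    cfg: CohortConfig,
    rng: np.random.Generator,
    encoding: OrdinalEncodingConfig | None = None,
) -> tuple[list[EhrObservation], QsofaInputs, QsofaInputs]:
    """EHR observations at {-16, -12, -8, -4, 0, +6} h plus qSOFA inputs.

    The t0 vitals are constrained so qSOFA(t0) = 1 exactly (one criterion
    met, chosen at random).  The t6 qSOFA inputs are drawn so the score
    reaches >= 2 with probability pi * 1{positive} + (1 - pi) * base_rate,
    which makes the privileged data a perfect oracle at pi = 1 and
    outcome-independent at pi = 0.
    """
    encoding = encoding or default_encoding_config()
    pos = true_class > 0
    drift = cfg.ehr_effect * (1.0 if pos else 0.0)

    # vitals random walk across the lookbacks, drifting toward severity for
    # the positive class
    state = {
        "temperature": 37.0 + rng.normal(0, 0.3),
        "spo2": 97.0 + rng.normal(0, 1.0),
        "heart_rate": 82.0 + rng.normal(0, 6.0),
        "map": 88.0 + rng.normal(0, 5.0),
        "rr": 16.0 + rng.normal(0, 1.5),
        "urine": 62.0 + rng.normal(0, 8.0),
    }
    step_drift = {
        "temperature": 0.12 * drift,
        "spo2": -0.35 * drift,
        "heart_rate": 2.2 * drift,
        "map": -1.8 * drift,
        "rr": 0.9 * drift,
        "urine": -4.0 * drift,
    }
    step_sd = {
        "temperature": 0.12,
        "spo2": 0.5,
        "heart_rate": 2.0,
        "map": 2.0,
        "rr": 0.8,
        "urine": 3.5,
    }
    lab_presence = 0.7
    infusion_presence = min(0.08 * (1.0 + 1.5 * drift), 0.9)

    observations: list[EhrObservation] = []
    for offset in LOOKBACK_OFFSETS_H:
        if offset != LOOKBACK_OFFSETS_H[0]:
            for k in state:
                state[k] += step_drift[k] + step_sd[k] * rng.standard_normal()
        state["spo2"] = min(state["spo2"], 100.0)
        state["urine"] = max(state["urine"], 0.0)
        labs = {
            name: _severity_raw_value(name, _class_severity(rng, 0.8 * drift), encoding, rng)
            for name in LAB_NAMES
            if rng.random() < lab_presence
        }
        infusions = {
            name: _infusion_dose(name, _infusion_severity(rng, drift), encoding, rng)
            for name in INFUSION_NAMES
            if rng.random() < infusion_presence
        }
        observations.append(
            EhrObservation(
                time_offset_h=offset,
                vitals=_vitals_block(state),
                urine_output=state["urine"],
                labs=labs,
                infusions=infusions,
            )
        )

    # anchor condition: exactly one qSOFA criterion at t0
    criterion = int(rng.integers(3))
    gcs0, sbp0, rr0 = 15, float(rng.uniform(105, 135)), float(rng.uniform(12, 19))
    if criterion == 0:
        gcs0 = int(rng.integers(3, 14))
    elif criterion == 1:
        sbp0 = float(rng.uniform(80, 100))
    else:
        rr0 = float(rng.uniform(22, 30))
    qsofa_t0 = QsofaInputs(gcs=gcs0, sbp=sbp0, rr=rr0)
    # keep the observed t0 vitals consistent with the anchor
    obs_t0 = observations[-1]
    vit0 = dict(obs_t0.vitals)
    vit0["respiratory_rate"] = rr0
    vit0["mean_arterial_pressure"] = 0.7 * sbp0 + rng.normal(8.0, 2.0)
    observations[-1] = EhrObservation(
        time_offset_h=0.0,
        vitals=vit0,
        urine_output=obs_t0.urine_output,
        labs=obs_t0.labs,
        infusions=obs_t0.infusions,
    )

    # outcome at t6
    p_deteriorate = cfg.pi_informativeness * (1.0 if pos else 0.0) + (
        1.0 - cfg.pi_informativeness
    ) * cfg.positive_fraction
    deteriorate = rng.random() < p_deteriorate
    if deteriorate:
        gcs6 = int(rng.integers(6, 14)) if rng.random() < 0.5 else 15
        sbp6 = float(rng.uniform(70, 98))
        rr6 = float(rng.uniform(23, 32))
    else:
        gcs6 = 15
        if rng.random() < 0.5:  # qSOFA stays at 1
            sbp6, rr6 = float(rng.uniform(82, 100)), float(rng.uniform(10, 19))
        else:  # qSOFA falls to 0
            sbp6, rr6 = float(rng.uniform(104, 135)), float(rng.uniform(10, 19))
    qsofa_t6 = QsofaInputs(gcs=gcs6, sbp=sbp6, rr=rr6)

    # privileged-space observation: vitals continue the walk, pinned to the
    # drawn t6 outcome where they overlap with the qSOFA inputs
    sev6 = drift + (1.2 if deteriorate else 0.0) * cfg.ehr_effect
    state6 = dict(state)
    for k in state6:
        state6[k] += 1.5 * (step_drift[k] + step_sd[k] * rng.standard_normal())
    state6["rr"] = rr6
    state6["map"] = 0.7 * sbp6 + rng.normal(8.0, 2.0)
    state6["spo2"] = min(state6["spo2"] - 2.0 * (1.0 if deteriorate else 0.0) * cfg.ehr_effect, 100.0)
    state6["urine"] = max(state6["urine"], 0.0)
    labs6 = {
        name: _severity_raw_value(name, _class_severity(rng, 0.8 * sev6), encoding, rng)
        for name in LAB_NAMES
        if rng.random() < lab_presence
    }
    infusions6 = {
        name: _infusion_dose(name, _infusion_severity(rng, sev6), encoding, rng)
        for name in INFUSION_NAMES
        if rng.random() < min(0.08 * (1.0 + 1.5 * sev6), 0.9)
    }
    observations.append(
        EhrObservation(
            time_offset_h=PRIVILEGED_OFFSET_H,
            vitals=_vitals_block(state6),
            urine_output=state6["urine"],
            labs=labs6,
            infusions=infusions6,
        )
    )
    return observations, qsofa_t0, qsofa_t6


def _infusion_severity(rng: np.random.Generator, shift: float) -> int:
    base = np.array([0.6, 0.3, 0.1])
    p = base * np.exp(np.array([-1.0, 0.3, 1.0]) * shift)
    p /= p.sum()
    return int(rng.choice(3, p=p)) + 1


def _infusion_dose(name: str, severity: int, config: OrdinalEncodingConfig,
                   rng: np.random.Generator) -> float:
    t1, t2 = config.infusions[name].thresholds
    edges = [max(t1 * 0.1, 1e-4), t1, t2, t2 * 2.0]
    lo, hi = edges[severity - 1], edges[severity]
    return float(np.clip(rng.uniform(lo, hi), lo + 1e-9, hi - 1e-9))


def _ecg_params(true_class: int, label: int, cfg: CohortConfig,
                rng: np.random.Generator) -> tuple[dict, dict]:
    """(t0 params, t6 params): the class signal lives in rate, jitter, noise."""
    base_hr = float(rng.uniform(65, 95))
    base_jitter = 0.045
    e0 = cfg.ecg_effect * (1.0 if true_class > 0 else 0.0)
    t0 = dict(
        hr=np.clip(base_hr + 8.0 * e0, 30.0, 220.0),
        jitter_sd=base_jitter / (1.0 + 1.5 * e0),
        noise_sd=cfg.noise_sd * (1.0 + 1.2 * e0),
    )
    e6 = cfg.ecg_effect * cfg.pi_informativeness * (1.0 if label > 0 else 0.0)
    t6 = dict(
        hr=np.clip(base_hr + 10.0 * e6, 30.0, 220.0),
        jitter_sd=base_jitter / (1.0 + 1.5 * e6),
        noise_sd=cfg.noise_sd * (1.0 + 1.2 * e6),
    )
    return t0, t6


def iter_cohort(
    cfg: CohortConfig, encoding: OrdinalEncodingConfig | None = None
) -> Iterator[SyntheticPatient]:
    """Yield synthetic patients one at a time (memory-friendly).

    Labels are produced exclusively by the labeling rules applied to the
    generated t6 vitals; the planted ``true_class`` only drives effect
    sizes.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    encoding = encoding or default_encoding_config()
    for k in range(cfg.n_patients):
        true_class = 1 if rng.random() < cfg.positive_fraction else -1
        observations, q0, q6 = generate_ehr_timeline(true_class, cfg, rng, encoding)
        # the realized label (known to the generator only through the rules)
        label = label_instance(qsofa_score(q6))
        p0, p6 = _ecg_params(true_class, label, cfg, rng)
        seg0 = generate_ecg_segment(
            p0["hr"], p0["noise_sd"], cfg.ecg_duration_s, rng,
            rate=cfg.sampling_rate, anchor="t0", jitter_sd=p0["jitter_sd"],
        )
        seg6 = generate_ecg_segment(
            p6["hr"], p6["noise_sd"], cfg.ecg_duration_s, rng,
            rate=cfg.sampling_rate, anchor="t6", jitter_sd=p6["jitter_sd"],
        )
        instance = PatientInstance(
            patient_id=f"P{k:05d}",
            regular_ecg=seg0,
            privileged_ecg=seg6,
            ehr_observations=tuple(observations),
            qsofa_t0=q0,
            qsofa_t6=q6,
        )
        yield SyntheticPatient(
            instance=instance,
            true_class=true_class,
            heart_rate_bpm=p0["hr"],
            jitter_sd_s=p0["jitter_sd"],
            noise_sd_mv=p0["noise_sd"],
        )


def generate_cohort(
    cfg: CohortConfig, encoding: OrdinalEncodingConfig | None = None
) -> list[SyntheticPatient]:
    """Materialise the whole cohort as a list."""
    return list(iter_cohort(cfg, encoding))
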