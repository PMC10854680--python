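"""ECG preprocessing and feature tensors for the regular and privileged spaces.

The regular space is everything observable at prediction time t0: the 10
minutes of lead-II ECG ending at t0 are band-pass filtered, split into two
5-minute windows, and each window is summarised by the six taut-string
features at five tube widths — a 2 (window) x 5 (epsilon) x 6 (feature)
tensor per instance.

The privileged space is the 10 minutes ending at t6 (the outcome time, six
hours later), available only for training cases.  Two privileged ECG
summaries are computed on the unwindowed segment: the 5 x 6 taut-string bank
(TS-ECG) and seven statistical features (SF-ECG).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .exceptions import ConfigurationError, InputError
from .taut_string import DEFAULT_EPSILONS, TS_FEATURE_NAMES, TSFeatureSet, ts_feature_bank

__all__ = [
    "ECG_SAMPLING_RATE",
    "SEGMENT_DURATION_S",
    "SF_FEATURE_NAMES",
    "ECGSegment",
    "StatFeatureSet",
    "RegularEcgFeatures",
    "PrivilegedEcgFeatures",
    "QualityConfig",
    "bandpass_filter",
    "segment_windows",
    "regular_ecg_features",
    "statistical_features",
    "privileged_ecg_features",
    "noise_fraction",
]

ECG_SAMPLING_RATE = 240.0  # samples/second
SEGMENT_DURATION_S = 600.0  # ten minutes
_BAND_HZ = (0.5, 40.0)
_FILTER_ORDER = 2

SF_FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "median",
    "variance",
    "kurtosis",
    "skewness",
    "shannon_entropy",
    "mean_abs_fft",
)

_ENTROPY_BINS = 64


@dataclass(frozen=True)
class ECGSegment:
    """A 10-minute single-lead ECG segment anchored at t0 or t6."""

    samples: np.ndarray
    anchor: str  # "t0" (regular space) or "t6" (privileged space)
    sampling_rate: float = ECG_SAMPLING_RATE
    duration_s: float = SEGMENT_DURATION_S

    def __post_init__(self) -> None:
        samples = np.ascontiguousarray(self.samples, dtype=np.float64)
        if self.anchor not in ("t0", "t6"):
            raise InputError(f"anchor must be 't0' or 't6', got {self.anchor!r}")
        expected = self.duration_s * self.sampling_rate
        if abs(samples.size - expected) > 1.0:
            raise InputError(
                f"segment length {samples.size} inconsistent with duration "
                f"{self.duration_s} s at {self.sampling_rate} Hz"
            )
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class StatFeatureSet:
    """Seven statistical summaries of an ECG window (SF-ECG features).

    Conventions: variance with 1/n normalisation; skewness and kurtosis as
    standardised third/fourth moments (Pearson kurtosis, Gaussian -> 3),
    both defined as 0 for a zero-variance window; Shannon entropy in nats
    from a 64-bin equal-width amplitude histogram; mean absolute value of
    the unnormalised forward FFT over all bins.
    """

    mean: float
    median: float
    variance: float
    kurtosis: float
    skewness: float
    shannon_entropy: float
    mean_abs_fft: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.mean,
                self.median,
                self.variance,
                self.kurtosis,
                self.skewness,
                self.shannon_entropy,
                self.mean_abs_fft,
            ]
        )


@dataclass(frozen=True)
class RegularEcgFeatures:
    """The 2 x 5 x 6 (window, epsilon, feature) taut-string tensor."""

    tensor: np.ndarray
    epsilons: tuple[float, ...] = DEFAULT_EPSILONS

    def __post_init__(self) -> None:
        tensor = np.asarray(self.tensor, dtype=np.float64)
        if tensor.shape != (2, len(self.epsilons), len(TS_FEATURE_NAMES)):
            raise InputError(f"expected tensor shape (2, 5, 6), got {tensor.shape}")
        object.__setattr__(self, "tensor", tensor)

    def flatten(self) -> np.ndarray:
        """Window-major, then epsilon, then feature: a 60-vector."""
        return self.tensor.reshape(-1)


@dataclass(frozen=True)
class PrivilegedEcgFeatures:
    """Privileged-space ECG summaries of the 10 minutes ending at t6."""

    ts: np.ndarray  # 5 x 6 taut-string bank on the full segment
    sf: StatFeatureSet

    def __post_init__(self) -> None:
        ts = np.asarray(self.ts, dtype=np.float64)
        if ts.shape != (len(DEFAULT_EPSILONS), len(TS_FEATURE_NAMES)):
            raise InputError(f"expected TS bank shape (5, 6), got {ts.shape}")
        object.__setattr__(self, "ts", ts)

    def ts_vector(self) -> np.ndarray:
        return self.ts.reshape(-1)

    def sf_vector(self) -> np.ndarray:
        return self.sf.as_array()


def bandpass_filter(seg: ECGSegment) -> ECGSegment:
    """Zero-phase second-order Butterworth band-pass, 0.5-40 Hz.

    Applied forward-backward (``filtfilt``) so the QRS morphology is not
    phase-distorted; output length equals input length.
    """
    if seg.sampling_rate <= 2 * _BAND_HZ[1]:
        raise ConfigurationError(
            f"sampling rate {seg.sampling_rate} Hz must exceed twice the "
            f"upper cutoff {_BAND_HZ[1]} Hz"
        )
    sos = sp_signal.butter(
        _FILTER_ORDER, _BAND_HZ, btype="bandpass", fs=seg.sampling_rate, output="sos"
    )
    filtered = sp_signal.sosfiltfilt(sos, seg.samples)
    return ECGSegment(
        samples=filtered,
        anchor=seg.anchor,
        sampling_rate=seg.sampling_rate,
        duration_s=seg.duration_s,
    )


def segment_windows(seg: ECGSegment) -> tuple[np.ndarray, np.ndarray]:
    """Split a 10-minute segment into two contiguous 5-minute windows."""
    expected = SEGMENT_DURATION_S * seg.sampling_rate
    if abs(len(seg) - expected) > 1.0 or abs(seg.duration_s - SEGMENT_DURATION_S) > 1.0 / seg.sampling_rate:
        raise InputError(
            f"expected a {SEGMENT_DURATION_S:.0f}-second segment, got "
            f"{seg.duration_s} s ({len(seg)} samples)"
        )
    half = len(seg) // 2
    return seg.samples[:half], seg.samples[half:]


def regular_ecg_features(
    seg: ECGSegment, epsilons: Sequence[float] = DEFAULT_EPSILONS
) -> RegularEcgFeatures:
    """Taut-string tensor of a (filtered) regular-space segment ending at t0."""
    if seg.anchor != "t0":
        raise InputError("regular-space features require a segment anchored at t0")
    w1, w2 = _split_halves(seg)
    eps = tuple(epsilons)
    tensor = np.stack([_bank_matrix(w1, eps), _bank_matrix(w2, eps)])
    return RegularEcgFeatures(tensor=tensor, epsilons=eps)


def _split_halves(seg: ECGSegment) -> tuple[np.ndarray, np.ndarray]:
    """Two equal halves of any segment (the duration check lives in
    :func:`segment_windows`; featurization also supports scaled-down
    segments for simulation studies)."""
    half = len(seg) // 2
    return seg.samples[:half], seg.samples[half:]


def _bank_matrix(window: np.ndarray, epsilons: tuple[float, ...]) -> np.ndarray:
    bank = ts_feature_bank(window, epsilons)
    return np.stack([fs.as_array() for fs in bank])


def statistical_features(window: "np.ndarray | Sequence[float]") -> StatFeatureSet:
    """The seven SF-ECG statistical summaries of a sample window."""
    x = np.asarray(window, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise InputError("window must be one-dimensional with length >= 2")
    variance = float(np.var(x))
    if variance > 0:
        skewness = float(sp_stats.skew(x, bias=True))
        kurtosis = float(sp_stats.kurtosis(x, fisher=False, bias=True))
        counts, _ = np.histogram(x, bins=_ENTROPY_BINS)
        p = counts[counts > 0] / x.size
        entropy = float(-np.sum(p * np.log(p)))
    else:
        # degenerate constant window: moments undefined, flagged as 0
        skewness = 0.0
        kurtosis = 0.0
        entropy = 0.0
    return StatFeatureSet(
        mean=float(np.mean(x)),
        median=float(np.median(x)),
        variance=variance,
        kurtosis=kurtosis,
        skewness=skewness,
        shannon_entropy=entropy,
        mean_abs_fft=float(np.mean(np.abs(np.fft.fft(x)))),
    )


def privileged_ecg_features(
    seg: ECGSegment, epsilons: Sequence[float] = DEFAULT_EPSILONS
) -> PrivilegedEcgFeatures:
    """TS bank (5 x 6) and SF set (7) of the unwindowed privileged segment."""
    if seg.anchor != "t6":
        raise InputError("privileged-space features require a segment anchored at t6")
    eps = tuple(epsilons)
    return PrivilegedEcgFeatures(
        ts=_bank_matrix(seg.samples, eps), sf=statistical_features(seg.samples)
    )


@dataclass(frozen=True)
class QualityConfig:
    """Heuristic signal-quality rule used by :func:`noise_fraction`.

    A subwindow is flagged as noise when it is a flat line (peak-to-peak
    amplitude below ``flat_ptp``), pinned at amplitude rails (more than
    ``clip_fraction`` of samples within ``clip_tol`` of the subwindow
    extremes while spanning at least ``clip_min_range``), or outside the
    physiologic amplitude range ``amplitude_limit`` (mV).
    """

    subwindow_s: float = 10.0
    flat_ptp: float = 1e-4
    clip_fraction: float = 0.25
    clip_tol: float = 1e-6
    clip_min_range: float = 0.5
    amplitude_limit: float = 6.0


def noise_fraction(seg: ECGSegment, config: QualityConfig | None = None) -> float:
    """Fraction of 10-second subwindows flagged as noise, in [0, 1].

    Instances whose regular or privileged segment reaches 0.5 are discarded
    upstream during instance construction.
    """
    cfg = config or QualityConfig()
    step = max(int(round(cfg.subwindow_s * seg.sampling_rate)), 1)
    x = seg.samples
    n_windows = max(x.size // step, 1)
    flagged = 0
    for k in range(n_windows):
        w = x[k * step : (k + 1) * step] if k < n_windows - 1 else x[k * step :]
        lo, hi = float(np.min(w)), float(np.max(w))
        ptp = hi - lo
        if ptp < cfg.flat_ptp:
            flagged += 1
            continue
        if np.max(np.abs(w)) > cfg.amplitude_limit:
            flagged += 1
            continue
        if ptp >= cfg.clip_min_range:
            at_rail = np.mean(
                (np.abs(w - hi) <= cfg.clip_tol) | (np.abs(w - lo) <= cfg.clip_tol)
            )
            if at_rail > cfg.clip_fraction:
                flagged += 1
    return flagged / n_windows
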