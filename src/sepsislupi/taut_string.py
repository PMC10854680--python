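"""Taut-string approximation of discrete signals and its summary features.

Given a sampled signal ``f = (f_0, ..., f_n)`` and a tube half-width
``eps > 0``, the taut-string estimate is the function ``g`` with
``max_i |f_i - g_i| <= eps`` that minimises the squared gradient
``sum_i (g_{i+1} - g_i)^2``.  Geometrically ``g`` is the shape of a string
pulled tight through the corridor between ``f - eps`` and ``f + eps``; the
same curve simultaneously minimises every convex symmetric function of the
increments, including the path length and the total variation.  The residual
``f - g`` is a noise estimate.

Endpoints are left free inside their tube interval: the optimal string then
starts and ends with slope zero (it may slide on the vertical "gates" at both
ends), and when an entirely flat string fits in the tube the height is tied
to the midpoint of the feasible interval.

The solver is the linear-time funnel (channel shortest-path) walk over the
corridor; a dense QP is never formed, so 5-minute ECG windows (72,000
samples) are handled comfortably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import InputError, ParameterError

__all__ = [
    "DEFAULT_EPSILONS",
    "TS_FEATURE_NAMES",
    "DiscreteSignal",
    "TautStringEstimate",
    "TSFeatureSet",
    "taut_string_estimate",
    "ts_features",
    "ts_feature_bank",
    "feature_bank_to_frame",
]

#: Tube half-widths used for the ECG feature bank (signal units, mV).
DEFAULT_EPSILONS: tuple[float, ...] = (0.0100, 0.1575, 0.3050, 0.4525, 0.6000)

#: Column order of the six per-epsilon features.
TS_FEATURE_NAMES: tuple[str, ...] = (
    "n_line_segments",
    "n_inflection_segments",
    "tv_noise",
    "tv_denoised",
    "power_denoised",
    "power_noise",
)

_SLOPE_TOL = 1e-9  # slope units; below this two segments count as one


@dataclass(frozen=True)
class DiscreteSignal:
    """A finite, uniformly sampled real-valued signal."""

    samples: np.ndarray
    sampling_rate: float = 240.0

    def __post_init__(self) -> None:
        samples = np.ascontiguousarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 2:
            raise InputError("signal must be one-dimensional with length >= 2")
        if not np.all(np.isfinite(samples)):
            raise InputError("signal samples must all be finite")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class TautStringEstimate:
    """A taut-string fit ``g`` of a signal ``f`` inside an ``eps``-tube.

    ``noise`` is the exact residual ``f - g`` and ``knots`` are the indices
    where the slope of ``g`` changes (both endpoints included).
    """

    epsilon: float
    estimate: np.ndarray
    noise: np.ndarray
    knots: np.ndarray = field(repr=False)

    @property
    def signal(self) -> np.ndarray:
        """The original samples, reconstructed exactly as ``g + r``."""
        return self.estimate + self.noise


@dataclass(frozen=True)
class TSFeatureSet:
    """The six per-epsilon taut-string summary features.

    ``power`` is mean squared amplitude; ``tv`` is the sum of absolute first
    differences; inflection segments are interior knots where the slope sign
    flips (rising to falling or vice versa).
    """

    n_line_segments: int
    n_inflection_segments: int
    tv_noise: float
    tv_denoised: float
    power_denoised: float
    power_noise: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                float(self.n_line_segments),
                float(self.n_inflection_segments),
                self.tv_noise,
                self.tv_denoised,
                self.power_denoised,
                self.power_noise,
            ]
        )


def _funnel_core(lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Free-endpoint taut string through the corridor [lower, upper].

    Funnel walk: maintain the lower convex hull of pending ceiling contacts
    and the upper concave hull of pending floor contacts, both rooted at the
    current apex (last committed knot).  A new corridor point that cuts
    through the opposite hull forces the string to bend there; knots are
    emitted as the apex advances.  Before the first knot and after the last
    the optimal string is flat (free-gate boundary condition).
    """
    m = lower.shape[0]
    ux = np.empty(m + 1, dtype=np.int64)
    uv = np.empty(m + 1, dtype=np.float64)
    lx = np.empty(m + 1, dtype=np.int64)
    lv = np.empty(m + 1, dtype=np.float64)
    kx = np.empty(m + 2, dtype=np.int64)
    kv = np.empty(m + 2, dtype=np.float64)
    uh = 0
    ut = 0
    lh = 0
    lt = 0
    nk = 0
    ux[ut] = 0
    uv[ut] = upper[0]
    ut += 1
    lx[lt] = 0
    lv[lt] = lower[0]
    lt += 1
    ax = -1
    av = 0.0
    has_apex = False

    for i in range(1, m):
        # -- ceiling point (i, upper[i]); hull slopes must increase outward
        nv = upper[i]
        while ut - uh >= 2:
            x1 = ux[ut - 2]
            v1 = uv[ut - 2]
            x2 = ux[ut - 1]
            v2 = uv[ut - 1]
            if (v2 - v1) * (i - x2) >= (nv - v2) * (x2 - x1):
                ut -= 1
            else:
                break
        if ut - uh == 1:
            x2 = ux[ut - 1]
            v2 = uv[ut - 1]
            if has_apex:
                if (v2 - av) * (i - x2) >= (nv - v2) * (x2 - ax):
                    ut -= 1
            elif nv <= v2:  # flat start: only running minima of the ceiling bind
                ut -= 1
        if ut == uh:
            # the new ceiling cuts below the floor hull: bend at floor contacts
            while lt > lh:
                fx = lx[lh]
                fv = lv[lh]
                if has_apex:
                    bend = (nv - av) * (fx - ax) < (fv - av) * (i - ax)
                else:
                    bend = nv < fv
                if bend:
                    kx[nk] = fx
                    kv[nk] = fv
                    nk += 1
                    ax = fx
                    av = fv
                    has_apex = True
                    lh += 1
                else:
                    break
        ux[ut] = i
        uv[ut] = nv
        ut += 1

        # -- floor point (i, lower[i]); hull slopes must decrease outward
        nv = lower[i]
        while lt - lh >= 2:
            x1 = lx[lt - 2]
            v1 = lv[lt - 2]
            x2 = lx[lt - 1]
            v2 = lv[lt - 1]
            if (v2 - v1) * (i - x2) <= (nv - v2) * (x2 - x1):
                lt -= 1
            else:
                break
        if lt - lh == 1:
            x2 = lx[lt - 1]
            v2 = lv[lt - 1]
            if has_apex:
                if (v2 - av) * (i - x2) <= (nv - v2) * (x2 - ax):
                    lt -= 1
            elif nv >= v2:  # flat start: only running maxima of the floor bind
                lt -= 1
        if lt == lh:
            while ut > uh:
                fx = ux[uh]
                fv = uv[uh]
                if has_apex:
                    bend = (nv - av) * (fx - ax) > (fv - av) * (i - ax)
                else:
                    bend = nv > fv
                if bend:
                    kx[nk] = fx
                    kv[nk] = fv
                    nk += 1
                    ax = fx
                    av = fv
                    has_apex = True
                    uh += 1
                else:
                    break
        lx[lt] = i
        lv[lt] = nv
        lt += 1

    g = np.empty(m, dtype=np.float64)
    if not has_apex:
        # no bend anywhere: a flat string fits; tie-break to the tube midpoint
        lo = lower[0]
        hi = upper[0]
        for j in range(1, m):
            if lower[j] > lo:
                lo = lower[j]
            if upper[j] < hi:
                hi = upper[j]
        c = 0.5 * (lo + hi)
        for j in range(m):
            g[j] = c
        return g

    # free right gate: keep bending while the pending hulls still pull the
    # string away from horizontal, then finish flat.  Chain fronts at or
    # behind the apex are already satisfied by committed segments; drop them.
    while True:
        while lh < lt and lx[lh] <= ax:
            lh += 1
        while uh < ut and ux[uh] <= ax:
            uh += 1
        if lh < lt and lv[lh] > av:
            kx[nk] = lx[lh]
            kv[nk] = lv[lh]
            nk += 1
            ax = lx[lh]
            av = lv[lh]
            lh += 1
        elif uh < ut and uv[uh] < av:
            kx[nk] = ux[uh]
            kv[nk] = uv[uh]
            nk += 1
            ax = ux[uh]
            av = uv[uh]
            uh += 1
        else:
            break

    # piecewise-linear interpolation through the knots, flat outside them
    first_x = kx[0]
    for j in range(0, first_x + 1):
        g[j] = kv[0]
    for s in range(nk - 1):
        x0 = kx[s]
        y0 = kv[s]
        x1 = kx[s + 1]
        y1 = kv[s + 1]
        dx = x1 - x0
        slope = (y1 - y0) / dx
        for j in range(x0 + 1, x1 + 1):
            g[j] = y0 + slope * (j - x0)
    last_x = kx[nk - 1]
    for j in range(last_x + 1, m):
        g[j] = kv[nk - 1]
    return g


try:  # pragma: no cover - exercised implicitly by every call
    import numba

    _funnel_core = numba.njit(cache=True)(_funnel_core)
except ImportError:  # pragma: no cover
    pass


def _as_signal(f: "DiscreteSignal | Sequence[float] | np.ndarray") -> DiscreteSignal:
    if isinstance(f, DiscreteSignal):
        return f
    return DiscreteSignal(np.asarray(f, dtype=np.float64))


def taut_string_estimate(
    f: "DiscreteSignal | Sequence[float] | np.ndarray", epsilon: float
) -> TautStringEstimate:
    """Fit the taut string to ``f`` inside the ``epsilon``-tube.

    Parameters
    ----------
    f
        Signal samples (array-like) or a :class:`DiscreteSignal`.
    epsilon
        Tube half-width in signal units; must be strictly positive.

    Returns
    -------
    TautStringEstimate
        The piecewise-linear estimate ``g``, the residual ``f - g`` and the
        slope-change knot indices.
    """
    if not np.isfinite(epsilon) or epsilon <= 0:
        raise ParameterError(f"epsilon must be a positive real, got {epsilon!r}")
    sig = _as_signal(f)
    samples = sig.samples
    g = _funnel_core(samples - epsilon, samples + epsilon)
    # the corridor bounds are rounded floats; nudge contact values by ulps so
    # the tube constraint holds exactly in measured arithmetic
    noise = samples - g
    over = np.abs(noise) > epsilon
    while np.any(over):
        g[over] = np.nextafter(g[over], samples[over])
        noise = samples - g
        over = np.abs(noise) > epsilon
    return TautStringEstimate(
        epsilon=float(epsilon), estimate=g, noise=noise, knots=_knots_of(g)
    )


def _knots_of(g: np.ndarray) -> np.ndarray:
    """Indices where the slope of ``g`` changes, endpoints included."""
    slopes = np.diff(g)
    change = np.flatnonzero(np.abs(np.diff(slopes)) > _SLOPE_TOL) + 1
    return np.concatenate(([0], change, [g.size - 1]))


def ts_features(est: TautStringEstimate) -> TSFeatureSet:
    """The six summary features of one taut-string estimate."""
    g = est.estimate
    r = est.noise
    knots = est.knots
    slopes = (g[knots[1:]] - g[knots[:-1]]) / (knots[1:] - knots[:-1])
    n_segments = slopes.size
    # interior knots where the slope sign flips
    rising = slopes > _SLOPE_TOL
    falling = slopes < -_SLOPE_TOL
    n_inflection = int(
        np.sum((rising[:-1] & falling[1:]) | (falling[:-1] & rising[1:]))
    )
    return TSFeatureSet(
        n_line_segments=int(n_segments),
        n_inflection_segments=n_inflection,
        tv_noise=float(np.sum(np.abs(np.diff(r)))),
        tv_denoised=float(np.sum(np.abs(np.diff(g)))),
        power_denoised=float(np.mean(g * g)),
        power_noise=float(np.mean(r * r)),
    )


def ts_feature_bank(
    f: "DiscreteSignal | Sequence[float] | np.ndarray",
    epsilons: Sequence[float] = DEFAULT_EPSILONS,
) -> list[TSFeatureSet]:
    """Taut-string features of ``f`` for each tube width, in input order."""
    eps = list(epsilons)
    if not eps:
        raise ParameterError("epsilons must be non-empty")
    sig = _as_signal(f)
    return [ts_features(taut_string_estimate(sig, e)) for e in eps]


def feature_bank_to_frame(bank: Sequence[TSFeatureSet], epsilons: Sequence[float]):
    """Feature bank as a pandas DataFrame (one row per epsilon), for CSV export."""
    import pandas as pd

    rows = np.stack([fs.as_array() for fs in bank])
    frame = pd.DataFrame(rows, columns=list(TS_FEATURE_NAMES))
    frame.insert(0, "epsilon", list(epsilons))
    return frame


def read_signal_csv(path, column: str | int = 0, sampling_rate: float = 240.0) -> DiscreteSignal:
    """Load one signal column from a CSV file (header optional)."""
    import pandas as pd

    frame = pd.read_csv(path)
    series = frame[column] if isinstance(column, str) else frame.iloc[:, column]
    return DiscreteSignal(series.to_numpy(dtype=np.float64), sampling_rate=sampling_rate)
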