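"""Signal containers and preprocessing for neuronal and vascular traces.

Raw traces (dendritic Ca2+ fluorescence, capillary red-blood-cell velocity,
power-Doppler) arrive as possibly irregularly sampled time series.  Before a
transfer function can be fitted they are brought onto a uniform grid by
shape-preserving cubic (pchip) interpolation, baseline-normalized against the
5 s preceding stimulus onset, optionally median-filtered, and cut to the
fitting window (5–27 s for 30 s acquisitions, 5–59 s for 60 s ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import DegenerateBaselineError, InvalidInputError

__all__ = [
    "SignalKind",
    "RawTrace",
    "UniformSeries",
    "interpolate_uniform",
    "baseline_delta",
    "median_filter3",
    "cut_fit_window",
    "FIT_WINDOWS",
]

#: Fitting windows (lo, hi) in seconds from acquisition start, keyed by
#: acquisition length in seconds.
FIT_WINDOWS: dict[float, tuple[float, float]] = {30.0: (5.0, 27.0), 60.0: (5.0, 59.0)}


class SignalKind(str, Enum):
    CALCIUM = "calcium"
    RBC_VELOCITY = "rbc_velocity"
    POWER_DOPPLER = "power_doppler"
    GENERIC = "generic"


@dataclass(frozen=True)
class RawTrace:
    """A possibly irregularly sampled measurement trace.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing, length >= 2.
    values : array of float
        Signal values, same length as `times`.
    kind : SignalKind
        What the trace measures; informational only.
    """

    times: np.ndarray
    values: np.ndarray
    kind: SignalKind = SignalKind.GENERIC

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise InvalidInputError("times and values must be 1-D")
        if times.size != values.size:
            raise InvalidInputError("times and values must have equal length")
        if times.size < 2:
            raise InvalidInputError("a trace needs at least two samples")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(values)):
            raise InvalidInputError("trace contains non-finite entries")
        if not np.all(np.diff(times) > 0):
            raise InvalidInputError("times must be strictly increasing")

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class UniformSeries:
    """An evenly sampled series: values at t0 + k*dt, k = 0..n-1."""

    t0: float
    dt: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.dt <= 0:
            raise InvalidInputError("dt must be positive")
        if values.ndim != 1 or values.size == 0:
            raise InvalidInputError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("series contains non-finite values")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self))

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (len(self) - 1)

    def same_grid(self, other: "UniformSeries", rtol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and abs(self.t0 - other.t0) <= rtol * max(1.0, abs(self.t0))
            and abs(self.dt - other.dt) <= rtol * self.dt
        )

    def with_values(self, values: np.ndarray) -> "UniformSeries":
        return UniformSeries(self.t0, self.dt, np.asarray(values, dtype=float))


def interpolate_uniform(trace: RawTrace, dt: float) -> UniformSeries:
    """Resample a raw trace onto a uniform grid by pchip interpolation.

    Shape-preserving piecewise-cubic (monotone, non-overshooting)
    interpolation onto the grid ``trace.times[0] + k*dt`` covering the trace
    span.  No extrapolation: the grid stops at the last grid point that does
    not exceed the last raw sample time.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    if dt > trace.span:
        raise InvalidInputError(
            f"dt={dt} s exceeds trace span {trace.span} s"
        )
    t0 = float(trace.times[0])
    # small epsilon so a grid point equal to the final sample is retained
    n = int(np.floor(trace.span / dt + 1e-9)) + 1
    grid = t0 + dt * np.arange(n)
    interp = PchipInterpolator(trace.times, trace.values, extrapolate=False)
    values = interp(grid)
    # the last grid point can fall a rounding error past the final sample
    values = np.where(np.isnan(values), np.interp(grid, trace.times, trace.values), values)
    return UniformSeries(t0, dt, values)


def baseline_delta(
    series: UniformSeries,
    stimulus_onset: float,
    baseline_len: float = 5.0,
    relative: bool = False,
) -> UniformSeries:
    """Baseline-normalize a series against the pre-stimulus window.

    Subtracts the mean over ``[onset - baseline_len, onset)`` (the last
    ``baseline_len`` seconds of baseline); with ``relative=True`` it also
    divides by that mean, yielding a relative change (e.g. ΔRBC/RBC,
    ΔPD/PD).
    """
    if baseline_len <= 0:
        raise InvalidInputError("baseline_len must be positive")
    lo = stimulus_onset - baseline_len
    eps = 1e-9 * series.dt
    if lo < series.t0 - eps or stimulus_onset > series.t_end + series.dt + eps:
        raise InvalidInputError(
            f"baseline window [{lo}, {stimulus_onset}) outside series span "
            f"[{series.t0}, {series.t_end}]"
        )
    times = series.times
    mask = (times >= lo - eps) & (times < stimulus_onset - eps)
    if not np.any(mask):
        raise InvalidInputError("baseline window contains no samples")
    mean = float(series.values[mask].mean())
    if relative:
        if abs(mean) < 1e-300:
            raise DegenerateBaselineError("baseline mean is zero; relative change undefined")
        return series.with_values((series.values - mean) / mean)
    return series.with_values(series.values - mean)


def median_filter3(series: UniformSeries) -> UniformSeries:
    """3-point running median; endpoints are left unchanged.

    Used to attenuate overestimated RBC-velocity samples.
    """
    v = series.values
    if v.size < 3:
        raise InvalidInputError("median filter needs at least 3 samples")
    out = v.copy()
    stacked = np.stack([v[:-2], v[1:-1], v[2:]])
    out[1:-1] = np.median(stacked, axis=0)
    return series.with_values(out)


def cut_fit_window(
    series: UniformSeries,
    acquisition_len: float | None = None,
    window: tuple[float, float] | None = None,
) -> UniformSeries:
    """Restrict a series to the fitting window.

    The window is [5, 27] s for 30 s acquisitions and [5, 59] s for 60 s
    acquisitions (times from acquisition start); an explicit ``window``
    overrides.  The output grid starts at the smallest grid point >= lo and
    ends at the largest grid point <= hi.
    """
    if window is None:
        if acquisition_len is None:
            raise InvalidInputError("provide acquisition_len or an explicit window")
        try:
            window = FIT_WINDOWS[float(acquisition_len)]
        except KeyError:
            raise InvalidInputError(
                f"no standard window for acquisition_len={acquisition_len}; "
                "pass window=(lo, hi) explicitly"
            ) from None
    lo, hi = window
    if hi <= lo:
        raise InvalidInputError("window hi must exceed lo")
    eps = 1e-9 * series.dt
    if lo < series.t0 - eps or hi > series.t_end + eps:
        raise InvalidInputError(
            f"window [{lo}, {hi}] not contained in series span "
            f"[{series.t0}, {series.t_end}]"
        )
    k_lo = int(np.ceil((lo - series.t0) / series.dt - 1e-9))
    k_hi = int(np.floor((hi - series.t0) / series.dt + 1e-9))
    if k_hi < k_lo:
        raise InvalidInputError("window contains no grid points")
    return UniformSeries(
        series.t0 + k_lo * series.dt, series.dt, series.values[k_lo : k_hi + 1]
    )
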