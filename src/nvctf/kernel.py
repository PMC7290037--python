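"""The shifted-gamma transfer function and prediction machinery.

The impulse response linking a neuronal activity trace ("From") to a
vascular response trace ("To") is modeled as a gamma density with a pure
time shift::

    TF(t) = H(t - p3) * p4 * (t - p3)^(p1-1) * p2^p1 * exp(-p2 (t - p3)) / Gamma(p1)

with H the Heaviside step.  p1 (shape) and p2 (rate, 1/s) set the slope and
decay, p3 (s) is a vascular delay, and p4 scales the amplitude: because the
gamma density integrates to one, the kernel integrates to p4.  A vascular
prediction is the discrete causal convolution of the From signal with this
kernel (Riemann-sum convention, scaled by the sampling interval), resampled
onto the To grid, and finally amplitude-rescaled against the observation
over a short post-onset window — a step that leaves the Pearson coefficient
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import pearsonr as _scipy_pearsonr

from .errors import (
    DegenerateScaleError,
    InvalidInputError,
    InvalidParameterError,
    ModeAtOnsetError,
    UndefinedCorrelationError,
)
from .signals import UniformSeries

__all__ = [
    "TFParams",
    "Prediction",
    "evaluate_tf",
    "tf_peak_time",
    "convolve_predict",
    "rescale_amplitude",
    "pearson",
    "sum_squared_residuals",
]


@dataclass(frozen=True)
class TFParams:
    """The four parameters of one transfer function.

    p1: gamma shape (dimensionless, > 0; > 1 for a kernel that starts at 0)
    p2: gamma rate (1/s, > 0)
    p3: time shift (s, >= 0; the numerical floor 1e-3 stands in for 0)
    p4: amplitude scale (output units per unit input * second)
    """

    p1: float
    p2: float
    p3: float
    p4: float

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p4"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v}")
        if not np.isfinite(self.p3) or self.p3 < 0:
            raise InvalidParameterError(f"p3 must be finite and >= 0, got {self.p3}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "TFParams":
        return cls(*(float(x) for x in arr))


@dataclass(frozen=True)
class Prediction:
    """A vascular prediction on the observation grid."""

    series: UniformSeries
    scale: float = 1.0
    pearson_r: float | None = None


def evaluate_tf(params: TFParams, grid: np.ndarray) -> np.ndarray:
    """Evaluate the shifted-gamma kernel on a time grid.

    Exactly zero for t <= p3.  Computed through log-gamma for numerical
    stability across the bounded parameter box (1e-3..20).
    """
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise InvalidInputError("grid contains non-finite times")
    u = grid - params.p3
    out = np.zeros_like(u)
    pos = u > 0
    if np.any(pos):
        up = u[pos]
        log_pdf = (
            (params.p1 - 1.0) * np.log(up)
            + params.p1 * np.log(params.p2)
            - params.p2 * up
            - gammaln(params.p1)
        )
        out[pos] = params.p4 * np.exp(log_pdf)
    return out


def tf_peak_time(params: TFParams) -> float:
    """Closed-form peak time (p1 - 1)/p2 + p3 of the kernel; requires p1 > 1."""
    if params.p1 <= 1.0:
        raise ModeAtOnsetError(
            f"p1={params.p1} <= 1: kernel peaks at the onset, no interior mode"
        )
    return (params.p1 - 1.0) / params.p2 + params.p3


def _grid_times(t0: float, dt: float, n: int) -> np.ndarray:
    return t0 + dt * np.arange(n)


def convolve_predict(
    from_sig: UniformSeries,
    params: TFParams,
    to_grid: UniformSeries | tuple[float, float, int],
) -> Prediction:
    """Predict the To signal by causal convolution with the kernel.

    The From signal is treated as zero before its first sample
    (baseline-subtracted traces justify this).  The discrete convolution is
    (from ⊛ TF) * dt on the From grid, then linearly interpolated onto the
    To grid.  ``to_grid`` is either a UniformSeries (its grid is used) or a
    (t0, dt, n) triple.
    """
    if len(from_sig) == 0 or not np.any(np.isfinite(from_sig.values)):
        raise InvalidInputError("empty From signal")
    if isinstance(to_grid, UniformSeries):
        t0_to, dt_to, n_to = to_grid.t0, to_grid.dt, len(to_grid)
    else:
        t0_to, dt_to, n_to = to_grid
        n_to = int(n_to)
    dt = from_sig.dt
    n_from = len(from_sig)
    to_end = t0_to + dt_to * (n_to - 1)
    # kernel support: from 0 out to the latest lag that can matter
    lag_max = max(to_end - from_sig.t0, 0.0)
    n_kernel = int(np.ceil(lag_max / dt + 1e-9)) + 1
    kernel = evaluate_tf(params, dt * np.arange(n_kernel))
    full = np.convolve(from_sig.values, kernel)[: n_from + n_kernel - 1] * dt
    pred_times = _grid_times(from_sig.t0, dt, full.size)
    to_times = _grid_times(t0_to, dt_to, n_to)
    if to_times[0] < pred_times[0] - 1e-9 * dt or to_times[-1] > pred_times[-1] + 1e-9 * dt:
        raise InvalidInputError("to_grid extends beyond the span covered by the prediction")
    values = np.interp(to_times, pred_times, full)
    return Prediction(UniformSeries(t0_to, dt_to, values))


def pearson(a: UniformSeries, b: UniformSeries) -> float:
    """Product-moment correlation of two series on the same grid."""
    if not a.same_grid(b):
        raise InvalidInputError("pearson requires identical grids")
    if len(a) < 3:
        raise InvalidInputError("pearson requires at least 3 samples")
    if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    return float(_scipy_pearsonr(a.values, b.values).statistic)


def sum_squared_residuals(pred: Prediction | UniformSeries, observed: UniformSeries) -> float:
    """Sum of squared residuals between a prediction and an observation."""
    series = pred.series if isinstance(pred, Prediction) else pred
    if not series.same_grid(observed):
        raise InvalidInputError("residuals require identical grids")
    d = series.values - observed.values
    return float(d @ d)


def rescale_amplitude(
    pred: Prediction,
    observed: UniformSeries,
    stimulus_onset: float,
    window: tuple[float, float] = (2.0, 8.0),
) -> Prediction:
    """Amplitude-match a prediction to the observation post hoc.

    Finds the scalar k minimizing the squared residuals between k*prediction
    and the observation over [onset + window[0], onset + window[1]] with a
    derivative-free simplex search, and returns the rescaled prediction.
    This multiplicative step does not change the Pearson coefficient.
    """
    series = pred.series
    if not series.same_grid(observed):
        raise InvalidInputError("rescale requires prediction and observation on one grid")
    lo = stimulus_onset + window[0]
    hi = stimulus_onset + window[1]
    times = series.times
    eps = 1e-9 * series.dt
    mask = (times >= lo - eps) & (times <= hi + eps)
    if not np.any(mask):
        raise InvalidInputError(f"rescale window [{lo}, {hi}] has no samples on the grid")
    p = series.values[mask]
    o = observed.values[mask]
    if np.all(p == 0.0):
        raise DegenerateScaleError("prediction identically zero on the rescale window")

    def cost(k: np.ndarray) -> float:
        if k[0] <= 0:  # the post-hoc scale is positive by definition
            return np.inf
        r = k[0] * p - o
        return float(r @ r)

    res = minimize(cost, x0=[1.0], method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-15})
    k = float(res.x[0])
    return Prediction(series.with_values(k * series.values), scale=k * pred.scale,
                      pearson_r=pred.pearson_r)
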