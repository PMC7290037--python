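"""Cohort validation: self / leave-one-out prediction quality and voxel ranking.

Each subject contributes one fitted transfer function.  Self-validation
scores a subject's kernel on its own trial; leave-one-out cross-validation
scores it on every other subject's trial, yielding a full cross matrix of
Pearson coefficients.  The standard kernel for the cohort must perform well
on its own dataset *and* on the other subjects' datasets: it is the one
with the highest row-mean Pearson over all subjects (self included) and the
smallest coefficient of variability — the former preferred when no kernel
wins both.  Scoring the kernel on its own trial matters: a kernel fitted on
a corrupted recording can still predict clean subjects well, but it cannot
explain its own data, and the self term is what rules it out.  A separate
utility ranks power-Doppler voxels by the area under their response curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    DegenerateScaleError,
    InvalidInputError,
    UndefinedCorrelationError,
)
from .kernel import (
    Prediction,
    TFParams,
    convolve_predict,
    pearson,
    rescale_amplitude,
)
from .signals import UniformSeries
from .trials import TrialRecord

__all__ = [
    "CohortReport",
    "VoxelPanel",
    "predict_trial",
    "self_validate",
    "loo_cross_validate",
    "select_standard_tf",
    "rank_voxels_by_auc",
]


@dataclass(frozen=True)
class CohortReport:
    """Cross-validation summary for a cohort of fitted kernels.

    ``cross[i, j]`` is the Pearson coefficient of subject i's kernel
    predicting subject j's vascular trace; the diagonal holds the self
    predictions.  ``mean_cross`` and ``cv_cross`` (SD/mean) are computed
    over the off-diagonal entries of each row; ``selection_mean`` is the
    mean over the full row (self included), the quantity that drives
    standard-kernel selection.  Cells where a prediction degenerates (e.g.
    an amplitude-collapsed kernel yields an identically-zero prediction)
    hold NaN and are excluded from the row statistics.
    """

    subject_ids: tuple[str, ...]
    params: tuple[TFParams, ...]
    self_pearson: np.ndarray
    cross: np.ndarray
    mean_cross: np.ndarray
    cv_cross: np.ndarray
    selection_mean: np.ndarray
    selected_index: int | None = None
    self_only: bool = False

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@dataclass(frozen=True)
class VoxelPanel:
    """Labeled set of single-voxel ΔPD/PD series sharing one grid."""

    series: dict[str, UniformSeries]
    target: str
    response_window: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.series) < 1:
            raise InvalidInputError("panel must contain at least one voxel")
        if self.target not in self.series:
            raise InvalidInputError(f"target voxel {self.target!r} not in panel")
        ref = next(iter(self.series.values()))
        for label, s in self.series.items():
            if not s.same_grid(ref):
                raise InvalidInputError(f"voxel {label!r} not on the common grid")


def predict_trial(trial: TrialRecord, params: TFParams) -> Prediction:
    """Amplitude-rescaled prediction of a trial's vascular trace."""
    pred = convolve_predict(trial.from_sig, params, trial.to_sig)
    return rescale_amplitude(pred, trial.to_sig, trial.stimulus.onset)


def self_validate(trial: TrialRecord, params: TFParams) -> float:
    """Pearson coefficient of the rescaled prediction vs the trial's own trace."""
    pred = predict_trial(trial, params)
    return pearson(pred.series, trial.to_sig)


def loo_cross_validate(
    trials: list[TrialRecord], params_list: list[TFParams]
) -> CohortReport:
    """Score every subject's kernel on every subject's trial.

    With a single subject only the self prediction is computable; the
    report is flagged ``self_only`` and the cross statistics are NaN.
    Degenerate cells (identically-zero prediction or zero-variance input)
    are recorded as NaN rather than aborting the whole matrix.
    """
    if len(trials) != len(params_list) or not trials:
        raise InvalidInputError("need one fitted parameter set per trial")
    n = len(trials)
    cross = np.full((n, n), np.nan)
    for i, params in enumerate(params_list):
        for j, trial in enumerate(trials):
            try:
                cross[i, j] = self_validate(trial, params)
            except (DegenerateScaleError, UndefinedCorrelationError):
                pass  # leave the cell NaN
    self_pearson = np.diag(cross).copy()
    if n == 1:
        return CohortReport(
            subject_ids=tuple(t.subject_id for t in trials),
            params=tuple(params_list),
            self_pearson=self_pearson,
            cross=cross,
            mean_cross=np.array([np.nan]),
            cv_cross=np.array([np.nan]),
            selection_mean=self_pearson.copy(),
            selected_index=0,
            self_only=True,
        )
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean_cross = np.array([np.nanmean(cross[i, off[i]]) for i in range(n)])
        sd_cross = np.array([np.nanstd(cross[i, off[i]], ddof=0) for i in range(n)])
        cv_cross = np.abs(sd_cross / mean_cross)
        selection_mean = np.nanmean(cross, axis=1)
    report = CohortReport(
        subject_ids=tuple(t.subject_id for t in trials),
        params=tuple(params_list),
        self_pearson=self_pearson,
        cross=cross,
        mean_cross=mean_cross,
        cv_cross=cv_cross,
        selection_mean=selection_mean,
    )
    return replace(report, selected_index=select_standard_tf(report))


def select_standard_tf(report: CohortReport) -> int:
    """Pick the cohort's standard kernel.

    The winner is the kernel that performs best on its own dataset and on
    the other subjects' datasets: highest full-row mean Pearson (self term
    included) and smallest coefficient of variability; when no kernel
    satisfies both, the highest row-mean Pearson alone decides (ties fall
    to the lowest subject index).  Including the self term is essential —
    without it, a kernel fitted on one corrupted recording is never scored
    on the only data it fails to explain.
    """
    if report.n_subjects == 0:
        raise InvalidInputError("empty cohort report")
    if report.n_subjects == 1 or report.self_only:
        return 0
    # A kernel meeting both criteria is necessarily the row-mean argmax,
    # so the preferred (mean) criterion decides in either case; argmax breaks
    # exact ties toward the lowest subject index.
    return int(np.nanargmax(report.selection_mean))


def rank_voxels_by_auc(panel: VoxelPanel) -> tuple[dict[str, int], int]:
    """Dense-rank voxels by the area under their response curves.

    AUC is the trapezoidal integral of each ΔPD/PD series over the panel's
    response window; rank 1 goes to the largest AUC, equal AUCs share a
    rank.  Returns the full label -> rank mapping and the target voxel's
    rank.
    """
    if len(panel.series) < 2:
        raise InvalidInputError("ranking needs at least two voxels")
    lo, hi = panel.response_window
    ref = next(iter(panel.series.values()))
    eps = 1e-9 * ref.dt
    if lo < ref.t0 - eps or hi > ref.t_end + eps:
        raise InvalidInputError(
            f"response window [{lo}, {hi}] outside the voxel grid"
        )
    times = ref.times
    mask = (times >= lo - eps) & (times <= hi + eps)
    aucs = {
        label: float(np.trapezoid(s.values[mask], times[mask]))
        for label, s in panel.series.items()
    }
    distinct = sorted(set(aucs.values()), reverse=True)
    ranks = {label: distinct.index(a) + 1 for label, a in aucs.items()}
    return ranks, ranks[panel.target]
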