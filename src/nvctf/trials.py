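"""Trial records: one odor-stimulation acquisition per subject.

A trial pairs the neuronal "From" trace (e.g. dendritic Ca2+) with the
vascular "To" trace (RBC velocity, power-Doppler or reflectance) and the
stimulus metadata needed by the preprocessing and fitting pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidInputError
from .signals import UniformSeries


@dataclass(frozen=True)
class StimulusInfo:
    """Stimulus metadata attached to a trial."""

    onset: float
    duration: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.onset < 0 or self.duration < 0:
            raise InvalidInputError("stimulus onset and duration must be >= 0")


@dataclass(frozen=True)
class TrialRecord:
    """One stimulation trial of one subject."""

    subject_id: str
    from_sig: UniformSeries
    to_sig: UniformSeries
    stimulus: StimulusInfo
    acquisition_len: float
    ground_truth: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.acquisition_len <= 0:
            raise InvalidInputError("acquisition_len must be positive")


def cut_trial(
    trial: TrialRecord, window: tuple[float, float] | None = None
) -> TrialRecord:
    """Restrict both signals of a trial to the fitting window.

    Uses the standard window for the trial's acquisition length (5-27 s for
    30 s, 5-59 s for 60 s) unless an explicit window is given.
    """
    from dataclasses import replace

    from .signals import cut_fit_window

    return replace(
        trial,
        from_sig=cut_fit_window(trial.from_sig, trial.acquisition_len, window),
        to_sig=cut_fit_window(trial.to_sig, trial.acquisition_len, window),
    )
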