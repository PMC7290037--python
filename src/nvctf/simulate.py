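"""Synthetic stimulus-locked trials with known ground truth.

Emulates the study conditions: 30 s (or 60 s for strong stimuli)
acquisitions with stimulus onset at 10 s (hence a >= 5 s pre-stimulus
baseline), odor pulses of 0.12-5 s, a Ca2+ transient generated by
convolving the stimulus boxcar with a fast difference-of-exponentials
kernel (GCaMP6f-like: rise 0.1 s, decay 1 s), and a vascular trace
generated by convolving the Ca2+ trace with a known ground-truth transfer
function — optionally plus a delayed secondary component — with additive
i.i.d. Gaussian noise expressed as a fraction of the response peak.
Cohorts jitter the ground-truth kernel multiplicatively across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidKineticsError, JitterTooLargeError
from .kernel import TFParams, convolve_predict
from .signals import UniformSeries
from .trials import StimulusInfo, TrialRecord

__all__ = [
    "SimConfig",
    "make_stimulus",
    "make_calcium",
    "make_vascular",
    "make_trial",
    "make_cohort",
    "calcium_kernel_integral",
]

#: Standard kernel of the capillary (Ca2+ -> RBC velocity) pathway, used as
#: the default generative ground truth.
STANDARD_MICRO_TF = TFParams(1.3, 0.5, 0.27, 0.19)


@dataclass(frozen=True)
class SimConfig:
    """Conditions of one synthetic experiment."""

    acquisition_len: float = 30.0
    dt_from: float = 0.05
    dt_to: float = 0.05
    stimulus_onset: float = 10.0
    stimulus_duration: float = 5.0
    tau_on: float = 0.1
    tau_off: float = 1.0
    true_tf: TFParams = STANDARD_MICRO_TF
    secondary_tf: TFParams | None = None
    secondary_ratio: float = 0.0
    noise_sd_from: float = 0.0
    noise_sd_to: float = 0.0
    n_subjects: int = 1
    inter_subject_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stimulus_onset < 5.0:
            raise InvalidInputError("stimulus onset must leave >= 5 s of baseline")
        if self.dt_from <= 0 or self.dt_to <= 0:
            raise InvalidInputError("sampling intervals must be positive")
        if min(self.noise_sd_from, self.noise_sd_to, self.secondary_ratio) < 0:
            raise InvalidInputError("noise and amplitude ratios must be >= 0")
        if self.n_subjects < 1:
            raise InvalidInputError("n_subjects must be >= 1")
        if self.stimulus_onset + self.stimulus_duration > self.acquisition_len:
            raise InvalidInputError("stimulus extends past the acquisition")


def _from_grid(config: SimConfig) -> tuple[float, float, int]:
    n = int(round(config.acquisition_len / config.dt_from)) + 1
    return 0.0, config.dt_from, n


def make_stimulus(config: SimConfig) -> UniformSeries:
    """Boxcar of height 1 on [onset, onset + duration), zero elsewhere."""
    t0, dt, n = _from_grid(config)
    times = t0 + dt * np.arange(n)
    values = (
        (times >= config.stimulus_onset - 1e-9 * dt)
        & (times < config.stimulus_onset + config.stimulus_duration - 1e-9 * dt)
    ).astype(float)
    return UniformSeries(t0, dt, values)


def _calcium_kernel(config: SimConfig, times: np.ndarray) -> np.ndarray:
    if config.tau_on >= config.tau_off:
        raise InvalidKineticsError(
            f"tau_on={config.tau_on} must be < tau_off={config.tau_off}"
        )
    h = np.exp(-times / config.tau_off) - np.exp(-times / config.tau_on)
    t_peak = (
        np.log(config.tau_off / config.tau_on)
        * config.tau_on
        * config.tau_off
        / (config.tau_off - config.tau_on)
    )
    peak = np.exp(-t_peak / config.tau_off) - np.exp(-t_peak / config.tau_on)
    return h / peak


def calcium_kernel_integral(config: SimConfig) -> float:
    """Closed-form integral of the unit-peak Ca2+ kernel (plateau of a long pulse)."""
    t_peak = (
        np.log(config.tau_off / config.tau_on)
        * config.tau_on
        * config.tau_off
        / (config.tau_off - config.tau_on)
    )
    peak = np.exp(-t_peak / config.tau_off) - np.exp(-t_peak / config.tau_on)
    return (config.tau_off - config.tau_on) / peak


def make_calcium(
    stimulus: UniformSeries, config: SimConfig, seed: int | np.random.SeedSequence = 0
) -> UniformSeries:
    """Stimulus-locked Ca2+ transient: kernel convolution plus optional noise."""
    dt = stimulus.dt
    n = len(stimulus)
    kernel_times = dt * np.arange(n)
    kernel = _calcium_kernel(config, kernel_times)
    clean = np.convolve(stimulus.values, kernel)[:n] * dt
    peak = float(np.max(np.abs(clean))) if np.any(clean) else 1.0
    if config.noise_sd_from > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, config.noise_sd_from * peak, size=n)
    return UniformSeries(stimulus.t0, dt, clean)


def make_vascular(
    calcium: UniformSeries, config: SimConfig, seed: int | np.random.SeedSequence = 0
) -> UniformSeries:
    """Vascular trace: Ca2+ convolved with the ground-truth kernel(s) + noise."""
    n_to = int(round(config.acquisition_len / config.dt_to)) + 1
    to_grid = (0.0, config.dt_to, n_to)
    clean = convolve_predict(calcium, config.true_tf, to_grid).series.values
    if config.secondary_tf is not None and config.secondary_ratio > 0:
        clean = clean + config.secondary_ratio * convolve_predict(
            calcium, config.secondary_tf, to_grid
        ).series.values
    peak = float(np.max(np.abs(clean))) if np.any(clean) else 1.0
    if config.noise_sd_to > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, config.noise_sd_to * peak, size=clean.size)
    return UniformSeries(0.0, config.dt_to, clean)


def make_trial(
    config: SimConfig,
    subject_id: str = "sim-0",
    seed: int | np.random.SeedSequence | None = None,
    true_tf: TFParams | None = None,
) -> TrialRecord:
    """One full-acquisition trial with embedded ground truth.

    ``true_tf`` overrides the config's kernel (used for per-subject jitter).
    Noise for the From and To traces is drawn from independent streams of
    the given seed, so the trial is reproducible.
    """
    if true_tf is not None:
        config = _with_tf(config, true_tf)
    base = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(config.seed if seed is None else seed)
    )
    seed_from, seed_to = base.spawn(2)
    stimulus = make_stimulus(config)
    calcium = make_calcium(stimulus, config, seed_from)
    vascular = make_vascular(calcium, config, seed_to)
    return TrialRecord(
        subject_id=subject_id,
        from_sig=calcium,
        to_sig=vascular,
        stimulus=StimulusInfo(config.stimulus_onset, config.stimulus_duration, "synthetic"),
        acquisition_len=config.acquisition_len,
        ground_truth={
            "true_tf": config.true_tf,
            "secondary_tf": config.secondary_tf,
            "secondary_ratio": config.secondary_ratio,
        },
    )


def _with_tf(config: SimConfig, tf: TFParams) -> SimConfig:
    from dataclasses import replace

    return replace(config, true_tf=tf)


def _jitter_tf(
    tf: TFParams, jitter: float, rng: np.random.Generator, max_redraws: int = 100
) -> TFParams:
    """Multiplicative lognormal jitter on each parameter, kept valid (p1 > 1)."""
    if jitter == 0:
        return tf
    base = tf.as_array()
    for _ in range(max_redraws):
        cand = base * np.exp(jitter * rng.standard_normal(4))
        if cand[0] > 1.0 + 1e-6 and np.all(cand > 0) and np.all(np.isfinite(cand)):
            return TFParams.from_array(cand)
    raise JitterTooLargeError(
        f"jitter={jitter} failed to produce a valid kernel in {max_redraws} redraws"
    )


def make_cohort(config: SimConfig) -> list[TrialRecord]:
    """A cohort of subjects sharing one (jittered) ground-truth kernel."""
    master = np.random.SeedSequence(config.seed)
    jitter_rng = np.random.default_rng(master.spawn(1)[0])
    trial_seeds = master.spawn(config.n_subjects + 1)[1:]
    trials = []
    for i in range(config.n_subjects):
        tf_i = _jitter_tf(config.true_tf, config.inter_subject_jitter, jitter_rng)
        trials.append(
            make_trial(config, subject_id=f"sim-{i}", seed=trial_seeds[i], true_tf=tf_i)
        )
    return trials
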