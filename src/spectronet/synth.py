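"""Synthetic flanker-task cohorts, trial sequences and multi-channel ERP epochs.

This module generates data with a controllable group structure: a sustained
alpha-band oscillation that is attenuated in the ADHD group, a transient
delta-theta burst near 100 ms that is boosted in the ADHD group, an N100-like
deflection, and 1/f background noise.  Everything is deterministic given the
seeds carried by the parameter objects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CHANNELS",
    "SFREQ",
    "EPOCH_START_MS",
    "EPOCH_STOP_MS",
    "N_SAMPLES",
    "CohortSpec",
    "EffectSpec",
    "SubjectRecord",
    "TrialEvent",
    "EpochSet",
    "generate_cohort",
    "generate_trial_sequence",
    "synthesize_epochs",
    "synthesize_resting",
    "generate_reaction_times",
    "simulate_cohort",
]

#: Fixed montage order; every 3-D array in the pipeline uses this channel axis.
CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "F3", "Fz", "F4", "P3", "P4")

SFREQ: float = 500.0
EPOCH_START_MS: float = -200.0
EPOCH_STOP_MS: float = 800.0  # half-open: last sample at +798 ms
N_SAMPLES: int = 500

#: (flanker-alone ms, target ms) difficulty levels; one level is assigned per
#: subject to emulate the per-subject psychometric staircase.
FLANKER_TARGET_LEVELS: tuple[tuple[int, int], ...] = (
    (136, 62),
    (114, 52),
    (92, 42),
    (70, 32),
    (48, 22),
)
BLACK_SCREEN_MS = 500
FEEDBACK_MS = 300
FIXATION_CHOICES_MS = (200, 300, 400)

ADULT_AGE_FLOOR = 18.0


class ParameterError(ValueError):
    """Raised when a generator specification violates its invariants."""


@dataclass(frozen=True)
class CohortSpec:
    n_per_group: int = 20
    frames_per_subject: int = 140
    n_sessions: int = 3
    trials_per_session: int = 140
    age_mean_adhd: float = 43.85
    age_sd_adhd: float = 14.78
    age_mean_hc: float = 29.90
    age_sd_hc: float = 10.77
    rt_mean_adhd: float = 368.0
    rt_mean_hc: float = 321.0
    rt_shape: float = 16.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ParameterError("n_per_group must be >= 1")
        if self.frames_per_subject < 1:
            raise ParameterError("frames_per_subject must be >= 1")
        if self.n_sessions < 1:
            raise ParameterError("n_sessions must be >= 1")
        if self.age_sd_adhd <= 0 or self.age_sd_hc <= 0:
            raise ParameterError("age SDs must be > 0")
        if self.rt_shape <= 0:
            raise ParameterError("rt_shape must be > 0")


@dataclass(frozen=True)
class EffectSpec:
    """Group-effect parameters injected into the synthetic EEG.

    Attenuation/boost values are ADHD-minus-HC differences in dB of band
    power; amplitudes are in microvolts on unit-gain channels.
    """

    alpha_band: tuple[float, float] = (8.0, 12.0)
    alpha_attenuation: float = -3.0
    alpha_amp: float = 0.7
    theta_band: tuple[float, float] = (3.0, 7.0)
    theta_boost: float = 3.0
    theta_amp: float = 2.5
    theta_latency: float = 100.0
    theta_duration: float = 150.0
    n100_gain: float = 2.0
    n100_amp: float = 5.0
    n100_latency: float = 100.0
    n100_width: float = 25.0
    channel_gains: tuple[float, ...] = (0.4, 0.4, 1.0, 1.0, 1.0, 1.0, 1.0)
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    subject_sd: float = 1.5
    theta_subject_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for lo, hi in (self.alpha_band, self.theta_band):
            if not (1.0 <= lo < hi <= 20.0):
                raise ParameterError("effect bands must lie within [1, 20] Hz")
        if not (EPOCH_START_MS < self.theta_latency < EPOCH_STOP_MS):
            raise ParameterError("theta_latency must lie within the epoch window")
        if len(self.channel_gains) != len(CHANNELS):
            raise ParameterError(f"channel_gains must have length {len(CHANNELS)}")
        if self.noise_scale < 0 or self.subject_sd < 0 or self.theta_subject_sd < 0:
            raise ParameterError("noise_scale and subject SDs must be >= 0")

    def null(self) -> "EffectSpec":
        """Copy with all group-discriminating effects removed."""
        return replace(self, alpha_attenuation=0.0, theta_boost=0.0, n100_gain=1.0)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str  # "ADHD" or "HC"
    age: float
    alpha_offset_z: float = 0.0
    theta_offset_z: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("ADHD", "HC"):
            raise ParameterError(f"unknown group {self.group!r}")
        if self.age <= 0:
            raise ParameterError("age must be > 0")

    @property
    def is_adhd(self) -> bool:
        return self.group == "ADHD"


@dataclass(frozen=True)
class TrialEvent:
    trial_index: int
    congruency: str  # "congruent" or "incongruent"
    onset: float  # ms from session start
    flanker_ms: float
    target_ms: float
    fixation_ms: float
    response_time: float | None = None
    correct: bool = True


@dataclass
class EpochSet:
    """Trials x channels x samples voltage array for one subject."""

    data: np.ndarray  # (n_trials, 7, 500), microvolts
    time_ms: np.ndarray  # (500,), -200 .. +798 at 2 ms steps
    channel_names: tuple[str, ...]
    sfreq: float
    subject_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ParameterError("epoch data must be 3-D (trials, channels, samples)")
        if self.data.shape[1] != len(self.channel_names):
            raise ParameterError("channel axis does not match channel_names")
        if self.data.shape[2] != self.time_ms.size:
            raise ParameterError("sample axis does not match time_ms")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            time_ms=self.time_ms.copy(),
            channel_names=self.channel_names,
            sfreq=self.sfreq,
            subject_id=self.subject_id,
        )


def epoch_time_ms() -> np.ndarray:
    """Sample grid [-200, 800) ms, half-open, stamps at bin left edges."""
    return EPOCH_START_MS + 1000.0 / SFREQ * np.arange(N_SAMPLES)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float, size: int) -> np.ndarray:
    """Rejection-sample a normal truncated below at ``lower``."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        draw = draw[draw >= lower]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw per-group subject records with truncated-normal ages.

    Ages are truncated at 18 years (adult cohort), so the expected sample
    mean is the truncated-normal mean, slightly above the nominal one.
    """
    spec.validate()
    subjects: list[SubjectRecord] = []
    for gi, (group, mean, sd) in enumerate((
        ("ADHD", spec.age_mean_adhd, spec.age_sd_adhd),
        ("HC", spec.age_mean_hc, spec.age_sd_hc),
    )):
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, gi)))
        ages = _truncated_normal(rng, mean, sd, ADULT_AGE_FLOOR, spec.n_per_group)
        alpha_z = rng.normal(size=spec.n_per_group)
        theta_z = rng.normal(size=spec.n_per_group)
        subj_seeds = rng.integers(0, 2**31 - 1, size=spec.n_per_group)
        for i in range(spec.n_per_group):
            subjects.append(SubjectRecord(
                subject_id=f"{group.lower()}{i + 1:03d}",
                group=group,
                age=float(ages[i]),
                alpha_offset_z=float(alpha_z[i]),
                theta_offset_z=float(theta_z[i]),
                seed=int(subj_seeds[i]),
            ))
    return subjects


def generate_trial_sequence(n_trials: int, ratio_congruent: int = 2,
                            seed: int = 0,
                            level: int | None = None) -> list[TrialEvent]:
    """Randomized congruent/incongruent sequence with grid-sampled timing.

    The incongruent count is ``round(n_trials / (ratio_congruent + 1))``.
    One flanker/target duration level is used for the whole sequence,
    mirroring the per-subject psychometric adjustment.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    if ratio_congruent < 0:
        raise ParameterError("ratio_congruent must be >= 0")
    rng = np.random.default_rng(seed)
    n_incongruent = int(round(n_trials / (ratio_congruent + 1)))
    n_incongruent = min(max(n_incongruent, 0), n_trials)
    labels = np.array(["congruent"] * (n_trials - n_incongruent)
                      + ["incongruent"] * n_incongruent)
    rng.shuffle(labels)
    if level is None:
        level = int(rng.integers(0, len(FLANKER_TARGET_LEVELS)))
    flanker_ms, target_ms = FLANKER_TARGET_LEVELS[level]
    events: list[TrialEvent] = []
    onset = 0.0
    for idx, lab in enumerate(labels):
        fixation = float(rng.choice(FIXATION_CHOICES_MS))
        events.append(TrialEvent(
            trial_index=idx,
            congruency=str(lab),
            onset=onset,
            flanker_ms=float(flanker_ms),
            target_ms=float(target_ms),
            fixation_ms=fixation,
        ))
        onset += flanker_ms + target_ms + BLACK_SCREEN_MS + FEEDBACK_MS + fixation
    return events


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...],
                      n_samples: int, exponent: float, scale: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum over ``shape``
    leading axes, unit-variance before scaling.  Shaped in the frequency
    domain; flat below 1 Hz."""
    n = n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / SFREQ)
    amp = np.ones_like(freqs)
    nonzero = freqs >= 1.0
    amp[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    amp[0] = 0.0  # no DC
    white = rng.normal(size=shape + (freqs.size,)) \
        + 1j * rng.normal(size=shape + (freqs.size,))
    spectrum = white * amp
    noise = np.fft.irfft(spectrum, n=n, axis=-1)
    sd = noise.std()
    if sd > 0:
        noise *= scale / sd
    return noise


def _gaussian_envelope(t_ms: np.ndarray, centre_ms: float, sigma_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - centre_ms) / sigma_ms) ** 2)


def _synthesize(subject: SubjectRecord, n_epochs: int, effects: EffectSpec,
                event_locked: bool, seed: int | None) -> EpochSet:
    effects.validate()
    if n_epochs < 0:
        raise ParameterError("number of epochs must be >= 0")
    t_ms = epoch_time_ms()
    t_s = t_ms / 1000.0
    rng = np.random.default_rng(
        np.random.SeedSequence((subject.seed if seed is None else seed, effects.seed)))
    n_ch = len(CHANNELS)
    gains = np.asarray(effects.channel_gains)

    is_adhd = subject.is_adhd
    alpha_db = (effects.alpha_attenuation if is_adhd else 0.0) \
        + subject.alpha_offset_z * effects.subject_sd
    theta_db = (effects.theta_boost if is_adhd else 0.0) \
        + subject.theta_offset_z * effects.theta_subject_sd
    alpha_amp = effects.alpha_amp * 10.0 ** (alpha_db / 20.0)
    theta_amp = effects.theta_amp * 10.0 ** (theta_db / 20.0)
    n100_amp = effects.n100_amp * (effects.n100_gain if is_adhd else 1.0)

    data = _one_over_f_noise(rng, (n_epochs, n_ch), N_SAMPLES,
                             effects.noise_exponent, effects.noise_scale)

    # sustained alpha: one frequency/phase per trial, common across channels
    f_alpha = rng.uniform(*effects.alpha_band, size=n_epochs)
    ph_alpha = rng.uniform(0, 2 * np.pi, size=n_epochs)
    alpha = alpha_amp * np.cos(2 * np.pi * f_alpha[:, None] * t_s[None, :]
                               + ph_alpha[:, None])
    signal = alpha

    if event_locked:
        sigma = effects.theta_duration / 2.355  # FWHM -> sigma
        f_theta = rng.uniform(*effects.theta_band, size=n_epochs)
        ph_theta = rng.uniform(0, 2 * np.pi, size=n_epochs)
        burst = theta_amp * np.cos(2 * np.pi * f_theta[:, None] * t_s[None, :]
                                   + ph_theta[:, None])
        burst *= _gaussian_envelope(t_ms, effects.theta_latency, sigma)[None, :]
        n100 = -n100_amp * _gaussian_envelope(
            t_ms, effects.n100_latency, effects.n100_width)[None, :]
        signal = signal + burst + n100

    data += signal[:, None, :] * gains[None, :, None]
    return EpochSet(
        data=data,
        time_ms=t_ms,
        channel_names=CHANNELS,
        sfreq=SFREQ,
        subject_id=subject.subject_id,
    )


def synthesize_epochs(subject: SubjectRecord, events: Sequence[TrialEvent],
                      effects: EffectSpec, seed: int | None = None) -> EpochSet:
    """One event-locked epoch per incongruent trial in ``events``.

    Epochs contain 1/f background plus sustained alpha (attenuated for ADHD),
    a theta burst around the configured latency (boosted for ADHD) and an
    N100-like negative deflection, all scaled by the per-channel gains.
    """
    incongruent = [e for e in events if e.congruency == "incongruent"]
    return _synthesize(subject, len(incongruent), effects,
                       event_locked=True, seed=seed)


def synthesize_resting(subject: SubjectRecord, n_frames: int,
                       effects: EffectSpec, seed: int | None = None) -> EpochSet:
    """Eyes-closed frames: tonic alpha group effect only, no event-locked
    burst or evoked deflection."""
    return _synthesize(subject, n_frames, effects, event_locked=False, seed=seed)


def generate_reaction_times(group: str, n: int, spec: CohortSpec,
                            seed: int = 0) -> np.ndarray:
    """Gamma-distributed reaction times with the group-specific mean (ms)."""
    if group not in ("ADHD", "HC"):
        raise ParameterError(f"unknown group {group!r}")
    if n < 0:
        raise ParameterError("n must be >= 0")
    spec.validate()
    mean = spec.rt_mean_adhd if group == "ADHD" else spec.rt_mean_hc
    rng = np.random.default_rng(seed)
    return rng.gamma(shape=spec.rt_shape, scale=mean / spec.rt_shape, size=n)


def simulate_cohort(spec: CohortSpec, effects: EffectSpec,
                    resting: bool = False
                    ) -> tuple[list[SubjectRecord], dict[str, EpochSet]]:
    """Full synthetic dataset: cohort plus per-subject epochs.

    Task mode pools incongruent trials across ``n_sessions`` sessions and
    truncates/pads to exactly ``frames_per_subject`` epochs per subject;
    resting mode draws the same number of frames directly.
    """
    spec.validate()
    effects.validate()
    subjects = generate_cohort(spec)
    epochs: dict[str, EpochSet] = {}
    for subject in subjects:
        if resting:
            epochs[subject.subject_id] = synthesize_resting(
                subject, spec.frames_per_subject, effects)
            continue
        pooled: list[TrialEvent] = []
        session = 0
        # pool incongruent trials across sessions; add sessions if padding
        # is ever required to reach frames_per_subject
        while True:
            for s in range(spec.n_sessions):
                events = generate_trial_sequence(
                    spec.trials_per_session, ratio_congruent=2,
                    seed=subject.seed + 7919 * (session + s))
                pooled.extend(e for e in events if e.congruency == "incongruent")
            session += spec.n_sessions
            if len(pooled) >= spec.frames_per_subject:
                break
        es = synthesize_epochs(subject, pooled[:spec.frames_per_subject], effects)
        epochs[subject.subject_id] = es
    return subjects, epochs
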