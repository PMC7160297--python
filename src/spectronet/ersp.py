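"""Single-trial Morlet-wavelet spectrograms (ERSP stacks).

Each 1 s epoch is convolved with complex Morlet wavelets on a log-spaced
frequency grid with a linearly increasing cycle count, squared-magnitude
power is averaged inside equal-width post-stimulus time bins, and the result
is expressed in dB re 1 uV^2 with a hard floor.  The stack orientation is
(frequency, time, channel).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import signal as _sig

from .synth import CHANNELS, EpochSet, ParameterError, SubjectRecord

__all__ = [
    "ErspParams",
    "SpectrogramFrame",
    "FrameSet",
    "log_spaced_freqs",
    "cycles_for_freqs",
    "morlet_kernel",
    "single_trial_ersp",
    "dataset_ersp",
]

#: Gaussian support half-width of the wavelet kernels, in standard deviations.
KERNEL_SUPPORT_SD = 3.5


@dataclass(frozen=True)
class ErspParams:
    f_min: float = 3.0
    f_max: float = 20.0
    n_freqs: int = 22
    cycles_min: float = 1.0
    cycles_max: float = 10.0
    t_window: tuple[float, float] = (0.0, 800.0)
    n_times: int = 20
    power_floor: float = -100.0  # dB re 1 uV^2

    def validate(self) -> None:
        if not (0 < self.f_min < self.f_max):
            raise ParameterError("need 0 < f_min < f_max")
        if self.n_freqs < 2:
            raise ParameterError("n_freqs must be >= 2")
        if not (0 < self.cycles_min <= self.cycles_max):
            raise ParameterError("need 0 < cycles_min <= cycles_max")
        if self.n_times < 1:
            raise ParameterError("n_times must be >= 1")
        t0, t1 = self.t_window
        if t0 >= t1:
            raise ParameterError("t_window must have positive length")


@dataclass
class SpectrogramFrame:
    """One trial's dB power stack, shape (n_freqs, n_times, n_channels)."""

    power: np.ndarray
    freqs: np.ndarray
    time_centres: np.ndarray
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.ndim != 3:
            raise ParameterError("frame power must be 3-D (freq, time, channel)")
        if not np.all(np.isfinite(self.power)):
            raise ParameterError("frame power must be finite")


@dataclass
class FrameSet:
    """Stack of spectrogram frames plus per-frame labels.

    ``frames`` has shape (n_frames, n_freqs, n_times, n_channels); ``labels``
    holds group strings and ``subject_ids`` the originating subject of each
    frame.
    """

    frames: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    freqs: np.ndarray
    time_centres: np.ndarray
    channel_names: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        n = self.frames.shape[0]
        if not (len(self.labels) == len(self.subject_ids) == n):
            raise ParameterError("labels/subject_ids must match frame count")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __iter__(self) -> Iterator[SpectrogramFrame]:
        for i in range(len(self)):
            yield SpectrogramFrame(
                power=self.frames[i], freqs=self.freqs,
                time_centres=self.time_centres,
                subject_id=str(self.subject_ids[i]), group=str(self.labels[i]))

    def subset_subjects(self, ids: Sequence[str]) -> "FrameSet":
        mask = np.isin(self.subject_ids, list(ids))
        return FrameSet(self.frames[mask], self.labels[mask],
                        self.subject_ids[mask], self.freqs,
                        self.time_centres, self.channel_names)

    def select_channels(self, names: Sequence[str]) -> "FrameSet":
        idx = [self.channel_names.index(n) for n in names]
        return FrameSet(self.frames[..., idx], self.labels, self.subject_ids,
                        self.freqs, self.time_centres, tuple(names))


def log_spaced_freqs(params: ErspParams) -> np.ndarray:
    """Geometric frequency grid from f_min to f_max inclusive."""
    params.validate()
    return np.geomspace(params.f_min, params.f_max, params.n_freqs)


def cycles_for_freqs(freqs: np.ndarray, params: ErspParams) -> np.ndarray:
    """Cycle counts linear in bin index from cycles_min to cycles_max."""
    freqs = np.asarray(freqs)
    if freqs.size == 0:
        raise ParameterError("empty frequency list")
    if freqs.size == 1:
        return np.array([params.cycles_min])
    idx = np.arange(freqs.size)
    return params.cycles_min + (params.cycles_max - params.cycles_min) \
        * idx / (freqs.size - 1)


def morlet_kernel(freq: float, n_cycles: float, sfreq: float) -> np.ndarray:
    """Complex Morlet kernel normalized to unit gain for a unit-amplitude
    sinusoid at its centre frequency (so power reads in uV^2)."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(KERNEL_SUPPORT_SD * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    envelope = np.exp(-0.5 * (t / sigma_t) ** 2)
    kernel = envelope * np.exp(2j * np.pi * freq * t)
    return kernel / (envelope.sum() / 2.0)


def _time_bin_slices(time_ms: np.ndarray, params: ErspParams
                     ) -> tuple[list[np.ndarray], np.ndarray]:
    t0, t1 = params.t_window
    width = (t1 - t0) / params.n_times
    masks = []
    for b in range(params.n_times):
        lo = t0 + b * width
        hi = lo + width
        mask = (time_ms >= lo - 1e-9) & (time_ms < hi - 1e-9)
        if not mask.any():
            raise ParameterError("a time bin contains no samples")
        masks.append(np.flatnonzero(mask))
    centres = t0 + width * (np.arange(params.n_times) + 0.5)
    return masks, centres


def _wavelet_power(data: np.ndarray, time_ms: np.ndarray, sfreq: float,
                   params: ErspParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned wavelet power for (n_trials, n_channels, n_samples) data.

    Returns (power[n_trials, n_freqs, n_times, n_channels], freqs, centres).
    The epoch is mirror-padded so that every time bin has full wavelet
    support even at the lowest frequency.
    """
    freqs = log_spaced_freqs(params)
    cycles = cycles_for_freqs(freqs, params)
    kernels = [morlet_kernel(f, c, sfreq) for f, c in zip(freqs, cycles)]
    pad = max(len(k) // 2 for k in kernels)
    n_trials, n_ch, n_samp = data.shape
    padded = np.pad(data, ((0, 0), (0, 0), (pad, pad)), mode="reflect")
    masks, centres = _time_bin_slices(time_ms, params)

    out = np.empty((n_trials, params.n_freqs, params.n_times, n_ch))
    chunk = max(1, int(2**24 // max(1, n_ch * n_samp)))
    for start in range(0, n_trials, chunk):
        block = padded[start:start + chunk]
        for fi, kernel in enumerate(kernels):
            conv = _sig.fftconvolve(block, kernel[None, None, :], mode="same")
            power = np.abs(conv[:, :, pad:pad + n_samp]) ** 2
            for b, idx in enumerate(masks):
                out[start:start + chunk, fi, b, :] = power[:, :, idx].mean(axis=-1).real
    return out, freqs, centres


def _to_db(power: np.ndarray, floor_db: float) -> np.ndarray:
    floor = 10.0 ** (floor_db / 10.0)
    return 10.0 * np.log10(np.maximum(power, floor))


def single_trial_ersp(epochs: EpochSet, trial: int = 0,
                      params: ErspParams = ErspParams()) -> SpectrogramFrame:
    """Spectrogram stack for one trial of an EpochSet."""
    params.validate()
    data = epochs.data[trial:trial + 1]
    power, freqs, centres = _wavelet_power(data, epochs.time_ms, epochs.sfreq, params)
    return SpectrogramFrame(
        power=_to_db(power[0], params.power_floor),
        freqs=freqs, time_centres=centres, subject_id=epochs.subject_id)


def dataset_ersp(epoch_sets: Mapping[str, EpochSet],
                 subjects: Sequence[SubjectRecord],
                 params: ErspParams = ErspParams()) -> FrameSet:
    """One spectrogram frame per trial across a cohort, labels carried through."""
    params.validate()
    by_id = {s.subject_id: s for s in subjects}
    frames, labels, ids = [], [], []
    freqs = centres = None
    for sid in sorted(epoch_sets):
        if sid not in by_id:
            raise ParameterError(f"no subject record for epochs of {sid!r}")
        es = epoch_sets[sid]
        if es.channel_names != CHANNELS:
            raise ParameterError("channel order mismatch")
        power, freqs, centres = _wavelet_power(
            es.data, es.time_ms, es.sfreq, params)
        frames.append(_to_db(power, params.power_floor))
        labels.extend([by_id[sid].group] * es.n_trials)
        ids.extend([sid] * es.n_trials)
    if not frames:
        raise ParameterError("no epochs supplied")
    return FrameSet(np.concatenate(frames, axis=0), np.array(labels),
                    np.array(ids), freqs, centres)
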