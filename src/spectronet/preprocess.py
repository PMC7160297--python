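"""Band-pass filtering and baseline correction of epoched EEG."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synth import EpochSet, ParameterError

__all__ = ["FilterSpec", "BaselineSpec", "bandpass", "baseline_correct", "remove_artifacts"]


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase band-pass specification.

    A 4th-order Butterworth (per pass) is applied forward-backward.  The
    design corners are widened slightly relative to the nominal band
    (``low_margin``/``high_margin``) so that the double pass keeps the
    passband ripple below 1 dB up to 0.9x the nominal high edge while still
    attenuating >= 20 dB one octave out.
    """

    band: tuple[float, float] = (1.0, 20.0)
    order: int = 4
    low_margin: float = 0.95
    high_margin: float = 1.2

    def validate(self, sfreq: float) -> None:
        low, high = self.band
        nyq = sfreq / 2.0
        if not (0.0 < low < high < nyq):
            raise ParameterError(
                f"band {self.band} must satisfy 0 < low < high < Nyquist ({nyq})")
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")

    def sos(self, sfreq: float) -> np.ndarray:
        self.validate(sfreq)
        low, high = self.band
        corners = (low * self.low_margin, min(high * self.high_margin, sfreq / 2 * 0.99))
        return signal.butter(self.order, corners, btype="bandpass",
                             fs=sfreq, output="sos")


@dataclass(frozen=True)
class BaselineSpec:
    window: tuple[float, float] = (-200.0, 0.0)

    def validate(self, time_ms: np.ndarray) -> None:
        lo, hi = self.window
        if lo >= hi:
            raise ParameterError("baseline window must have positive length")
        if lo < time_ms[0] or hi > time_ms[-1] + 1e-9 + (time_ms[1] - time_ms[0]):
            raise ParameterError("baseline window lies outside the epoch span")
        if not np.any((time_ms >= lo) & (time_ms < hi)):
            raise ParameterError("baseline window contains no samples")


def bandpass(epochs: EpochSet, spec: FilterSpec = FilterSpec()) -> EpochSet:
    """Zero-phase band-pass along the sample axis; shape-preserving."""
    sos = spec.sos(epochs.sfreq)
    out = epochs.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=-1)
    return out


def baseline_correct(epochs: EpochSet,
                     spec: BaselineSpec = BaselineSpec()) -> EpochSet:
    """Subtract the pre-stimulus mean from each epoch and channel."""
    spec.validate(epochs.time_ms)
    lo, hi = spec.window
    mask = (epochs.time_ms >= lo) & (epochs.time_ms < hi)
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=-1, keepdims=True)
    return out


def remove_artifacts(epochs: EpochSet) -> EpochSet:
    """Artifact-removal hook; identity here (synthetic data is artifact-free).

    A real-data pipeline can substitute an ICA-based cleaner with the same
    signature.
    """
    return epochs.copy()
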