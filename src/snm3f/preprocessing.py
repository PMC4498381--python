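"""Raw EMG to model input: envelope -> time normalization -> amplitude
normalization.

Raw surface EMG is band-limited noise whose amplitude modulation carries
the motor command; the standard envelope is full-wave rectification
followed by zero-phase low-pass filtering (Butterworth, 3 Hz cut-off by
default). Trials of different durations are mapped onto a common
normalized movement time by linear interpolation (50 steps by default),
and each muscle is scaled by its maximum over the whole experiment so
muscles with different gains become comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .model import EMGDataset

__all__ = ["RawTrial", "envelope", "time_normalize", "amplitude_normalize"]


@dataclass
class RawTrial:
    """One raw EMG recording: (L, M) signal (any sign) at ``fs`` Hz."""

    signal: np.ndarray
    fs: float
    label: int | None = None

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape[0] < 2:
            raise ValueError("raw trial must have at least 2 samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")


def envelope(trial: RawTrial, cutoff_hz: float = 3.0, order: int = 4) -> np.ndarray:
    """EMG envelope: full-wave rectify, then zero-phase low-pass filter.

    The filter is an ``order``-th order Butterworth applied forward and
    backward (zero phase distortion). Filtering can undershoot slightly,
    so the output is clipped at zero.
    """
    if cutoff_hz >= trial.fs / 2.0:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency "
            f"({trial.fs / 2.0} Hz)"
        )
    rectified = np.abs(trial.signal)
    b, a = scipy.signal.butter(order, cutoff_hz, btype="low", fs=trial.fs)
    filtered = scipy.signal.filtfilt(b, a, rectified, axis=0)
    return np.clip(filtered, 0.0, None)


def time_normalize(env: np.ndarray, T: int = 50) -> np.ndarray:
    """Resample an (L, M) envelope to T evenly spaced points over [0, L-1]
    by per-muscle linear interpolation; first and last rows are preserved."""
    env = np.atleast_2d(np.asarray(env, dtype=float))
    L = env.shape[0]
    if L < 2:
        raise ValueError("need at least 2 time samples to normalize duration")
    grid = np.linspace(0.0, L - 1.0, T)
    src = np.arange(L, dtype=float)
    return np.column_stack([np.interp(grid, src, env[:, m]) for m in range(env.shape[1])])


def amplitude_normalize(dataset: EMGDataset) -> EMGDataset:
    """Divide each muscle by its maximum over all trials and time steps.

    After normalization every muscle's maximum is exactly 1, except
    identically-zero muscles, which are left unscaled with a warning.
    """
    maxima = dataset.data.max(axis=(0, 1))
    zero = maxima <= 0.0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} identically-zero muscle(s) left unscaled",
            RuntimeWarning,
            stacklevel=2,
        )
    scale = np.where(zero, 1.0, maxima)
    return EMGDataset(dataset.data / scale, dataset.labels, dataset.muscle_names)
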