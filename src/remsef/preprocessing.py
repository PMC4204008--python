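"""Resampling, band-limiting and epoch segmentation.

The processing chain mirrors a wearable-oriented front end: resample to
256 Hz, remove DC with a first-order 0.16 Hz high-pass, band-limit with a
second-order 50 Hz Butterworth low-pass (both causal, single pass), then
cut the signal into 30-s epochs of fifteen non-overlapping 2-s subepochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io import EEGRecord, Hypnogram

__all__ = ["EpochGrid", "resample_to_256", "bandlimit", "segment",
           "TARGET_FS", "EPOCH_SECONDS", "SUBEPOCH_SECONDS"]

TARGET_FS = 256
EPOCH_SECONDS = 30
SUBEPOCH_SECONDS = 2
SUBEPOCHS_PER_EPOCH = EPOCH_SECONDS // SUBEPOCH_SECONDS  # 15
SUBEPOCH_SAMPLES = SUBEPOCH_SECONDS * TARGET_FS          # 512
EPOCH_SAMPLES = EPOCH_SECONDS * TARGET_FS                # 7680


@dataclass
class EpochGrid:
    """Segmented EEG: ``epochs[i]`` is one contiguous 30-s sample block.

    Each epoch holds exactly ``subepochs_per_epoch * subepoch_samples``
    samples; subepochs are non-overlapping and contiguous.
    """

    epochs: np.ndarray  # shape (n_epochs, EPOCH_SAMPLES)
    subepochs_per_epoch: int = SUBEPOCHS_PER_EPOCH
    subepoch_samples: int = SUBEPOCH_SAMPLES

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        expected = self.subepochs_per_epoch * self.subepoch_samples
        if self.epochs.ndim != 2 or self.epochs.shape[1] != expected:
            raise ValueError(
                f"epochs must be (n, {expected}), got {self.epochs.shape}")

    def __len__(self) -> int:
        return len(self.epochs)

    def subepochs(self, i: int) -> np.ndarray:
        """Epoch ``i`` reshaped to (subepochs_per_epoch, subepoch_samples)."""
        return self.epochs[i].reshape(self.subepochs_per_epoch,
                                      self.subepoch_samples)


def resample_to_256(record: EEGRecord) -> EEGRecord:
    """Resample to 256 Hz by polyphase rational-ratio filtering.

    The anti-aliasing low-pass is the resampler's built-in Kaiser design.
    A signal already at 256 Hz is returned unchanged.
    """
    if not record.fs > 0:
        raise ValueError("sampling rate must be positive")
    if record.fs == TARGET_FS:
        return record
    ratio = Fraction(TARGET_FS) / Fraction(record.fs).limit_denominator(10**6)
    out = sps.resample_poly(record.samples, ratio.numerator,
                            ratio.denominator)
    return EEGRecord(samples=out, fs=float(TARGET_FS), channel=record.channel)


def bandlimit(record: EEGRecord) -> EEGRecord:
    """Remove DC and band-limit a 256 Hz signal.

    Applies a first-order Butterworth high-pass at 0.16 Hz followed by a
    second-order Butterworth low-pass at 50 Hz, both causally (single
    pass, zero initial state).
    """
    if record.fs != TARGET_FS:
        raise ValueError(
            f"bandlimit expects fs={TARGET_FS} Hz (resample first), "
            f"got {record.fs}")
    b_hp, a_hp = sps.butter(1, 0.16, btype="highpass", fs=TARGET_FS)
    b_lp, a_lp = sps.butter(2, 50.0, btype="lowpass", fs=TARGET_FS)
    x = sps.lfilter(b_hp, a_hp, record.samples)
    x = sps.lfilter(b_lp, a_lp, x)
    return EEGRecord(samples=x, fs=record.fs, channel=record.channel)


def segment(record: EEGRecord,
            hypnogram: Hypnogram) -> tuple[EpochGrid, tuple[str, ...]]:
    """Cut a 256 Hz recording into 30-s epochs aligned to the hypnogram.

    Epochs start at sample 0; a trailing partial epoch is discarded. When
    the signal and hypnogram disagree on epoch count, both are truncated
    to the shorter with a warning. Returns the grid and the aligned stage
    labels.
    """
    if record.fs != TARGET_FS:
        raise ValueError(f"segment expects fs={TARGET_FS} Hz")
    n_signal_epochs = len(record.samples) // EPOCH_SAMPLES
    if n_signal_epochs == 0:
        raise ValueError("recording shorter than one 30-s epoch")
    leftover = len(record.samples) - n_signal_epochs * EPOCH_SAMPLES
    if leftover:
        warnings.warn(
            f"discarding trailing partial epoch of "
            f"{leftover / TARGET_FS:.1f} s", stacklevel=2)
    n = min(n_signal_epochs, len(hypnogram))
    if n_signal_epochs != len(hypnogram):
        warnings.warn(
            f"signal has {n_signal_epochs} epochs but hypnogram has "
            f"{len(hypnogram)}; truncating both to {n}", stacklevel=2)
    grid = EpochGrid(record.samples[: n * EPOCH_SAMPLES]
                     .reshape(n, EPOCH_SAMPLES))
    return grid, hypnogram.stages[:n]
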