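"""Spectral features: SEF50/SEF95, SEFd, absolute and relative band power.

Each 2-s subepoch is transformed with a 512-point FFT (0.5 Hz bins).
Per epoch, three features are derived in a configurable band (8-16 Hz by
default):

* ``SEFd`` — mean over the fifteen subepochs of (SEF95 − SEF50), where
  SEFxx is the lowest in-band frequency below which xx% of the band
  power lies; the per-epoch series is smoothed with a 9-point centered
  moving average.
* ``AP`` — absolute band power, ``20·log10(Σ band |mag|)`` per subepoch,
  averaged over the epoch (dB).
* ``RP`` — relative band power, ``20·log10(Σ band |mag| / Σ full |mag|)``
  per subepoch, averaged over the epoch (dB, ≤ 0). The full-spectrum sum
  excludes the DC bin, which the 0.16 Hz high-pass removes anyway.

During REM sleep the 8-16 Hz power concentrates near the band edges
(reduced 9-15 Hz activity with a rise near 15 Hz), which depresses SEF50
and raises SEF95 — SEFd is therefore largest in REM, the discriminative
effect the detector exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocessing import EpochGrid, SUBEPOCH_SAMPLES, TARGET_FS

__all__ = [
    "BandConfig", "SubepochSpectrum", "EpochFeatures",
    "compute_spectrum", "compute_sef", "compute_sefd_epoch", "smooth_sefd",
    "compute_ap_epoch", "compute_rp_epoch", "extract_features",
]

FFT_SIZE = 512
N_BINS = FFT_SIZE // 2 + 1            # 257 one-sided bins
BIN_HZ = TARGET_FS / FFT_SIZE         # 0.5 Hz resolution


@dataclass(frozen=True)
class BandConfig:
    """Analysis band [f1, f2] Hz, inclusive on both edges of the 0.5 Hz grid."""

    f1: float = 8.0
    f2: float = 16.0

    def __post_init__(self) -> None:
        if not 0 <= self.f1 < self.f2 <= TARGET_FS / 2:
            raise ValueError(f"invalid band [{self.f1}, {self.f2}]")
        for edge in (self.f1, self.f2):
            if (edge / BIN_HZ) != int(edge / BIN_HZ):
                raise ValueError(
                    f"band edge {edge} Hz not on the {BIN_HZ} Hz bin grid")

    @property
    def slice(self) -> slice:
        """Index slice of the in-band bins (inclusive edges)."""
        return slice(int(self.f1 / BIN_HZ), int(self.f2 / BIN_HZ) + 1)

    @property
    def n_bins(self) -> int:
        s = self.slice
        return s.stop - s.start


@dataclass
class SubepochSpectrum:
    """One-sided FFT magnitude spectrum of a single 2-s subepoch."""

    mag: np.ndarray
    freq: np.ndarray

    def __post_init__(self) -> None:
        self.mag = np.asarray(self.mag, dtype=np.float64)
        self.freq = np.asarray(self.freq, dtype=np.float64)
        if self.mag.shape != self.freq.shape:
            raise ValueError("mag and freq must have the same shape")
        if np.any(self.mag < 0):
            raise ValueError("magnitudes must be non-negative")
        if np.any(np.diff(self.freq) <= 0):
            raise ValueError("frequencies must be strictly increasing")


@dataclass
class EpochFeatures:
    """Per-epoch feature vector; ``valid`` is False for zero-power epochs."""

    sefd: float
    ap: float
    rp: float
    valid: bool = True


def compute_spectrum(subepoch: np.ndarray) -> SubepochSpectrum:
    """One-sided magnitude spectrum of one 512-sample subepoch.

    The subepoch mean is removed before the transform (no taper).
    Magnitudes carry the energy-preserving one-sided scaling: bins 1..255
    are scaled by sqrt(2/N) and the DC/Nyquist bins by sqrt(1/N), so that
    ``Σ mag²`` equals the time-domain energy ``Σ x²`` (Parseval).
    """
    x = np.asarray(subepoch, dtype=np.float64)
    if x.shape != (FFT_SIZE,):
        raise ValueError(f"subepoch must have {FFT_SIZE} samples, "
                         f"got {x.shape}")
    spec = np.fft.rfft(x - x.mean())
    scale = np.full(N_BINS, math.sqrt(2.0 / FFT_SIZE))
    scale[0] = scale[-1] = math.sqrt(1.0 / FFT_SIZE)
    mag = np.abs(spec) * scale
    freq = np.fft.rfftfreq(FFT_SIZE, d=1.0 / TARGET_FS)
    return SubepochSpectrum(mag=mag, freq=freq)


def compute_sef(spec: SubepochSpectrum, fraction: float,
                band: BandConfig) -> float:
    """Spectral edge frequency at ``fraction`` of the band power.

    Returns the lowest in-band bin frequency x such that the cumulative
    power ``Σ_{i≤x} mag²`` reaches ``fraction`` of the total band power
    (ties resolve to the lower frequency). Raises on zero band power.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    power = spec.mag[band.slice] ** 2
    total = power.sum()
    if total <= 0:
        raise ValueError("zero power in band; SEF undefined")
    cum = np.cumsum(power)
    # tolerance guards against cumsum rounding just below fraction*total
    idx = int(np.searchsorted(cum, fraction * total * (1 - 1e-12)))
    return float(spec.freq[band.slice][idx])


def compute_sefd_epoch(subepoch_sefs) -> float:
    """Mean of the fifteen per-subepoch (SEF95 − SEF50) differences, Hz."""
    pairs = list(subepoch_sefs)
    if len(pairs) != 15:
        raise ValueError(f"expected 15 (SEF50, SEF95) pairs, got {len(pairs)}")
    return float(np.mean([s95 - s50 for s50, s95 in pairs]))


def smooth_sefd(series, valid=None) -> np.ndarray:
    """Centered 9-point moving average across the per-epoch SEFd series.

    Near the edges the window shrinks symmetrically, so a constant series
    is preserved and the output length equals the input length. Entries
    flagged invalid are excluded from their neighbours' windows and are
    passed through unchanged.
    """
    x = np.asarray(series, dtype=np.float64)
    n = len(x)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
    out = x.copy()
    for i in range(n):
        if not valid[i]:
            continue
        half = min(4, i, n - 1 - i)
        window = slice(i - half, i + half + 1)
        m = valid[window]
        out[i] = x[window][m].mean()
    return out


def _band_sums(spectra, band: BandConfig):
    mags = np.stack([s.mag for s in spectra])
    return mags[:, band.slice].sum(axis=1), mags[:, 1:].sum(axis=1)


def compute_ap_epoch(subepoch_spectra, band: BandConfig) -> float:
    """Absolute band power of one epoch in dB.

    Per subepoch ``20·log10`` of the in-band magnitude sum, averaged over
    the fifteen subepochs. Raises if any subepoch has zero band magnitude.
    """
    band_sum, _ = _band_sums(subepoch_spectra, band)
    if np.any(band_sum <= 0):
        raise ValueError("zero band magnitude; AP undefined")
    return float(np.mean(20.0 * np.log10(band_sum)))


def compute_rp_epoch(subepoch_spectra, band: BandConfig) -> float:
    """Relative band power of one epoch in dB (≤ 0 for an in-range band).

    Per subepoch ``20·log10`` of (in-band magnitude sum / full-spectrum
    magnitude sum excluding DC), averaged over the fifteen subepochs.
    """
    band_sum, full_sum = _band_sums(subepoch_spectra, band)
    if np.any(full_sum <= 0):
        raise ValueError("zero full-spectrum magnitude; RP undefined")
    return float(np.mean(20.0 * np.log10(band_sum / full_sum)))


def extract_features(grid: EpochGrid,
                     band: BandConfig | None = None) -> list[EpochFeatures]:
    """Per-epoch SEFd (series-smoothed), AP and RP for a segmented recording.

    Epochs whose band power vanishes in any subepoch are flagged invalid
    (NaN features) and skipped by the SEFd smoother; the run continues.
    """
    if band is None:
        band = BandConfig()
    if len(grid) == 0:
        raise ValueError("empty epoch grid")
    sefd_raw, ap, rp, valid = [], [], [], []
    for i in range(len(grid)):
        spectra = [compute_spectrum(se) for se in grid.subepochs(i)]
        try:
            pairs = [(compute_sef(s, 0.50, band), compute_sef(s, 0.95, band))
                     for s in spectra]
            sefd_raw.append(compute_sefd_epoch(pairs))
            ap.append(compute_ap_epoch(spectra, band))
            rp.append(compute_rp_epoch(spectra, band))
            valid.append(True)
        except ValueError:
            sefd_raw.append(np.nan)
            ap.append(np.nan)
            rp.append(np.nan)
            valid.append(False)
    sefd = smooth_sefd(sefd_raw, valid)
    return [EpochFeatures(sefd=float(d), ap=float(a), rp=float(r), valid=v)
            for d, a, r, v in zip(sefd, ap, rp, valid)]
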