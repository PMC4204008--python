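"""Signal and annotation I/O: EDF signals, hypnograms, feature tables.

EDF reading is delegated to MNE. Writing uses a minimal EDF encoder
(16-bit, single data-record duration of one second) sufficient for
round-tripping synthetic recordings through the full pipeline.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecord",
    "Hypnogram",
    "STAGES",
    "UnknownChannelError",
    "HypnogramParseError",
    "read_edf_signal",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram",
    "write_features",
    "read_features",
]

#: Canonical sleep-stage labels (AASM stages plus bookkeeping labels).
STAGES = ("W", "N1", "N2", "N3", "REM", "UNSCORED", "MOVEMENT")

#: Default symbol -> stage mapping for plain-text hypnograms. Covers AASM
#: letters and R&K digits (S3/S4 collapse onto N3 under AASM rules).
DEFAULT_STAGE_MAP: dict[str, str] = {
    "W": "W", "N1": "N1", "N2": "N2", "N3": "N3", "R": "REM", "REM": "REM",
    "0": "W", "1": "N1", "2": "N2", "3": "N3", "4": "N3", "5": "REM",
    "MT": "MOVEMENT", "M": "MOVEMENT", "?": "UNSCORED", "U": "UNSCORED",
    "UNSCORED": "UNSCORED", "MOVEMENT": "MOVEMENT",
}

#: Default EDF+ annotation description -> stage mapping (Sleep-EDF style).
DEFAULT_EDFPLUS_MAP: dict[str, str] = {
    "Sleep stage W": "W",
    "Sleep stage 1": "N1",
    "Sleep stage 2": "N2",
    "Sleep stage 3": "N3",
    "Sleep stage 4": "N3",
    "Sleep stage N1": "N1",
    "Sleep stage N2": "N2",
    "Sleep stage N3": "N3",
    "Sleep stage R": "REM",
    "Sleep stage ?": "UNSCORED",
    "Movement time": "MOVEMENT",
}


class UnknownChannelError(KeyError):
    """Requested channel label is not present in the EDF file."""


class HypnogramParseError(ValueError):
    """A hypnogram file contains a symbol with no stage mapping."""


@dataclass
class EEGRecord:
    """A uniformly sampled single-channel EEG signal.

    Parameters
    ----------
    samples : ndarray
        Signal samples in microvolts.
    fs : float
        Sampling rate in Hz; must be positive.
    channel : str
        Channel label, e.g. ``"Fp1-A2"``.
    """

    samples: np.ndarray
    fs: float
    channel: str = "EEG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage labels.

    ``stages`` holds one canonical label per scoring epoch, in recording
    order; ``epoch_seconds`` is the scoring-epoch duration (30 s standard).
    """

    stages: tuple[str, ...]
    epoch_seconds: float = 30.0

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        if not self.epoch_seconds > 0:
            raise ValueError("epoch_seconds must be positive")
        bad = sorted({s for s in self.stages} - set(STAGES))
        if bad:
            raise ValueError(f"unknown stage labels: {bad}")

    def __len__(self) -> int:
        return len(self.stages)

    def binary_rem(self) -> np.ndarray:
        """Boolean array, True where the reference stage is REM."""
        return np.array([s == "REM" for s in self.stages], dtype=bool)


# ---------------------------------------------------------------------------
# EDF writing (minimal encoder) and reading (MNE)
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _ascii_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {value!r} > {width}")
    return b.ljust(width)


def _format_phys(value: float) -> str:
    """Render a physical-range bound in <= 8 ASCII chars."""
    for fmt in ("%.6g", "%.4g", "%.1e"):
        s = fmt % value
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot format {value} in 8 chars")


def write_edf(records: EEGRecord | Sequence[EEGRecord], path) -> None:
    """Write one or more equally sampled channels to a minimal EDF file.

    Samples are quantized to 16 bits over a symmetric physical range
    chosen per channel; the quantization step is ``2*max|x| / 65535``.
    The signal is zero-padded to a whole number of one-second records.
    """
    if isinstance(records, EEGRecord):
        records = [records]
    if not records:
        raise ValueError("no channels to write")
    fs = records[0].fs
    n = len(records[0].samples)
    if any(r.fs != fs or len(r.samples) != n for r in records):
        raise ValueError("all channels must share sampling rate and length")
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_records = int(np.ceil(n / fs)) if n else 0
    if n_records == 0:
        raise ValueError("cannot write an empty signal")

    ns = len(records)
    header = b"".join([
        _ascii_field("0", 8),
        _ascii_field("X X X X", 80),
        _ascii_field("Startdate X X X X", 80),
        _ascii_field("01.01.00", 8),
        _ascii_field("00.00.00", 8),
        _ascii_field(str(256 * (ns + 1)), 8),
        _ascii_field("", 44),
        _ascii_field(str(n_records), 8),
        _ascii_field("1", 8),
        _ascii_field(str(ns), 4),
    ])

    phys: list[tuple[float, float]] = []
    for r in records:
        pm = float(np.max(np.abs(r.samples))) if n else 1.0
        pm = float(_format_phys(pm if pm > 0 else 1.0))
        phys.append((-pm, pm))

    def sig_fields(fmt, width):
        return b"".join(_ascii_field(fmt(r, p), width)
                        for r, p in zip(records, phys))

    header += sig_fields(lambda r, p: r.channel, 16)
    header += sig_fields(lambda r, p: "", 80)                 # transducer
    header += sig_fields(lambda r, p: "uV", 8)                # phys dim
    header += sig_fields(lambda r, p: _format_phys(p[0]), 8)  # phys min
    header += sig_fields(lambda r, p: _format_phys(p[1]), 8)  # phys max
    header += sig_fields(lambda r, p: str(_EDF_DIG_MIN), 8)
    header += sig_fields(lambda r, p: str(_EDF_DIG_MAX), 8)
    header += sig_fields(lambda r, p: "", 80)                 # prefiltering
    header += sig_fields(lambda r, p: str(fs), 8)             # samples/record
    header += sig_fields(lambda r, p: "", 32)

    digital = []
    for r, (pmin, pmax) in zip(records, phys):
        x = np.zeros(n_records * fs)
        x[:n] = r.samples
        gain = (pmax - pmin) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
        d = np.clip(np.rint((x - pmin) / gain) + _EDF_DIG_MIN,
                    _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")
        digital.append(d.reshape(n_records, fs))

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for d in digital:
                fh.write(d[rec].tobytes())


def read_edf_signal(path, channel: str) -> EEGRecord:
    """Read one channel from an EDF/EDF+ file.

    Returns the samples in microvolts together with the recorded sampling
    rate. Raises :class:`FileNotFoundError` for a missing file and
    :class:`UnknownChannelError` when the label is absent.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channel not in raw.ch_names:
        raise UnknownChannelError(
            f"channel {channel!r} not in file (available: {raw.ch_names})")
    try:
        data = raw.get_data(picks=[channel], units="uV")
    except (ValueError, KeyError):
        # channel without a voltage dimension: take values as stored
        data = raw.get_data(picks=[channel])
    return EEGRecord(samples=data[0], fs=float(raw.info["sfreq"]),
                     channel=channel)


# ---------------------------------------------------------------------------
# Hypnograms
# ---------------------------------------------------------------------------

def read_hypnogram(path, dialect: str = "plain",
                   stage_map: Mapping[str, str] | None = None,
                   epoch_seconds: float = 30.0) -> Hypnogram:
    """Read a reference hypnogram.

    ``plain`` dialect: one stage symbol per line, mapped to the canonical
    stage set through ``stage_map`` (defaults cover AASM letters and R&K
    digits). ``edfplus`` dialect: EDF+ annotations whose descriptions are
    mapped through ``stage_map`` (defaults cover Sleep-EDF descriptions)
    and expanded into fixed-length epochs.
    """
    if dialect == "plain":
        mapping = dict(DEFAULT_STAGE_MAP)
        if stage_map:
            mapping.update(stage_map)
        stages = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                sym = line.strip()
                if not sym:
                    continue
                if sym not in mapping:
                    raise HypnogramParseError(
                        f"{path}: line {lineno}: unknown stage symbol {sym!r}")
                stages.append(mapping[sym])
        return Hypnogram(tuple(stages), epoch_seconds)
    if dialect == "edfplus":
        import mne

        mapping = dict(DEFAULT_EDFPLUS_MAP)
        if stage_map:
            mapping.update(stage_map)
        ann = mne.read_annotations(path)
        stages = []
        for desc, dur in zip(ann.description, ann.duration):
            if desc not in mapping:
                raise HypnogramParseError(
                    f"{path}: unknown annotation description {desc!r}")
            stages.extend([mapping[desc]] * int(round(dur / epoch_seconds)))
        return Hypnogram(tuple(stages), epoch_seconds)
    raise ValueError(f"unknown hypnogram dialect {dialect!r}")


def write_hypnogram(hyp: Hypnogram, path) -> None:
    """Write a hypnogram in the plain dialect (one canonical label per line)."""
    with open(path, "w") as fh:
        for s in hyp.stages:
            fh.write(s + "\n")


# ---------------------------------------------------------------------------
# Feature / result tables
# ---------------------------------------------------------------------------

def write_features(features, path, predictions=None, reference=None) -> None:
    """Write per-epoch features (and optional labels) as CSV.

    ``features`` is a sequence of :class:`~remsef.features.EpochFeatures`.
    Values are written with six decimals; empty input is an error.
    """
    features = list(features)
    if not features:
        raise ValueError("no features to write")
    table = {
        "epoch": np.arange(len(features)),
        "sefd": [f.sefd for f in features],
        "ap": [f.ap for f in features],
        "rp": [f.rp for f in features],
        "valid": [bool(f.valid) for f in features],
    }
    if predictions is not None:
        table["predicted"] = list(predictions)
    if reference is not None:
        table["reference"] = list(reference)
    pd.DataFrame(table).to_csv(path, index=False, float_format="%.6f")


def read_features(path) -> pd.DataFrame:
    """Read a feature CSV back into a DataFrame."""
    return pd.read_csv(path)
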