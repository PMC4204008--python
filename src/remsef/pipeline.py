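"""End-to-end convenience wrappers: raw record -> features -> detections."""

from __future__ import annotations

from .detector import DetectionResult, Thresholds, DEFAULT_THRESHOLDS, \
    detect_recording
from .features import BandConfig, extract_features
from .io import EEGRecord, Hypnogram
from .preprocessing import bandlimit, resample_to_256, segment

__all__ = ["extract_recording_features", "detect_in_record"]


def extract_recording_features(record: EEGRecord, hypnogram: Hypnogram,
                               band: BandConfig | None = None):
    """Resample, filter, segment and featurize one labelled recording.

    Returns (features, aligned_stages): one EpochFeatures and one
    reference stage label per scored 30-s epoch.
    """
    rec = bandlimit(resample_to_256(record))
    grid, stages = segment(rec, hypnogram)
    return extract_features(grid, band), stages


def detect_in_record(record: EEGRecord, hypnogram: Hypnogram,
                     thresholds: Thresholds = DEFAULT_THRESHOLDS,
                     band: BandConfig | None = None
                     ) -> tuple[DetectionResult, list, tuple]:
    """Run the full detection pipeline on one recording.

    Returns (detections, features, aligned_stages).
    """
    features, stages = extract_recording_features(record, hypnogram, band)
    return detect_recording(features, thresholds), features, stages
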