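"""Round-trip the file-based workflow: EDF + hypnogram on disk.

Writes a synthetic recording as a 16-bit EDF with a plain-text
hypnogram, reads both back, and scores detections with calibrated
thresholds — the same path the ``remsef`` command line uses.
"""

import tempfile
from pathlib import Path

import numpy as np

from remsef import (calibrate_thresholds, confusion, detect_recording,
                    extract_recording_features, metrics, read_edf_signal,
                    read_hypnogram, write_edf, write_hypnogram)
from remsef.synth import sample_hypnogram, synthesize_recording

workdir = Path(tempfile.mkdtemp())
hyp = sample_hypnogram(60, seed=3, ensure_stages=("REM", "N2"))
record, hyp = synthesize_recording(hyp, seed=3)
write_edf(record, workdir / "night.edf")
write_hypnogram(hyp, workdir / "night.txt")

loaded = read_edf_signal(workdir / "night.edf", "synthetic")
loaded_hyp = read_hypnogram(workdir / "night.txt")
quant_step = 2 * np.max(np.abs(record.samples)) / 65535
err = np.max(np.abs(loaded.samples - record.samples))
print(f"EDF round trip: {len(loaded)} samples at {loaded.fs:.0f} Hz, "
      f"max quantization error {err:.4f} uV (step {quant_step:.4f} uV)")

features, stages = extract_recording_features(loaded, loaded_hyp)
th = calibrate_thresholds(features, np.array([s == "REM" for s in stages]))
m = metrics(confusion(detect_recording(features, th).predictions, stages))
print(f"resubstitution check on the loaded file: "
      f"Sen {m['sensitivity']:.1f}% Spe {m['specificity']:.1f}%")
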