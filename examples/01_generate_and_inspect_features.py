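"""Generate a synthetic night of EEG and look at the per-stage features.

Builds an 80-epoch labelled recording from the stage templates, runs the
resample/filter/segment/FFT pipeline, and prints the median SEFd, AP and
RP per sleep stage. REM should show the largest SEFd (its 8-16 Hz power
sits at the band edges) and the lowest in-band absolute power.
"""

import numpy as np

from remsef import extract_recording_features
from remsef.synth import sample_hypnogram, synthesize_recording

hyp = sample_hypnogram(80, seed=7, ensure_stages=("REM", "N2", "W"))
record, hyp = synthesize_recording(hyp, seed=7)
features, stages = extract_recording_features(record, hyp)

print(f"recording: {record.duration:.0f} s at {record.fs:.0f} Hz, "
      f"{len(features)} epochs")
print(f"{'stage':>6} {'n':>4} {'SEFd (Hz)':>10} {'AP (dB)':>8} {'RP (dB)':>8}")
for stage in ("W", "N1", "N2", "N3", "REM"):
    rows = [f for f, s in zip(features, stages) if s == stage]
    if not rows:
        continue
    print(f"{stage:>6} {len(rows):>4} "
          f"{np.median([f.sefd for f in rows]):>10.2f} "
          f"{np.median([f.ap for f in rows]):>8.1f} "
          f"{np.median([f.rp for f in rows]):>8.1f}")
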