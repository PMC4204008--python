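"""Calibrate thresholds on one recording, detect REM on another.

The ROC sweep picks the SEFd threshold closest to the perfect corner of
the curve; a quantile grid search then sets the AP ceiling and RP
window on the stage-1 candidates. Thresholds are frozen before touching
the test recording, so the reported sensitivity/specificity measure
generalisation, not fit.
"""

import numpy as np

from remsef import (calibrate_thresholds, confusion, detect_recording,
                    extract_recording_features, metrics)
from remsef.synth import sample_hypnogram, synthesize_recording

train_hyp = sample_hypnogram(100, seed=0, ensure_stages=("REM", "N2"))
train_rec, train_hyp = synthesize_recording(train_hyp, seed=1000)
train_feats, train_stages = extract_recording_features(train_rec, train_hyp)
th = calibrate_thresholds(
    train_feats, np.array([s == "REM" for s in train_stages]))
print(f"calibrated: SEFd >= {th.sefd_th:.2f} Hz, AP <= {th.ap_max:.1f} dB, "
      f"RP in [{th.rp_min:.1f}, {th.rp_max:.1f}] dB")

test_hyp = sample_hypnogram(100, seed=500, ensure_stages=("REM", "N2"))
test_rec, test_hyp = synthesize_recording(test_hyp, seed=2000)
test_feats, test_stages = extract_recording_features(test_rec, test_hyp)
result = detect_recording(test_feats, th)
m = metrics(confusion(result.predictions, test_stages))
print(f"held-out recording: sensitivity {m['sensitivity']:.1f}%, "
      f"specificity {m['specificity']:.1f}%, accuracy {m['accuracy']:.1f}%")
print(f"stage-1 candidates: {int(result.stage1_candidates.sum())} of "
      f"{len(result)} epochs (stage 2 only runs on these)")
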