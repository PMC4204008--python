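"""Subject-level five-fold cross-validation on synthetic subjects.

Ten synthetic subjects are partitioned into five folds; each fold's
thresholds are fitted on the other subjects only. The per-fold means
show how stable the calibrated operating point is across subjects.
"""

import numpy as np

from remsef import crossvalidate, extract_recording_features
from remsef.synth import sample_hypnogram, synthesize_recording

recordings = []
for subject in range(10):
    hyp = sample_hypnogram(60, seed=subject, ensure_stages=("REM", "N2"))
    rec, hyp = synthesize_recording(hyp, seed=100 + subject)
    feats, stages = extract_recording_features(rec, hyp)
    recordings.append((feats, np.array([s == "REM" for s in stages])))

report = crossvalidate(recordings, k=5, seed=1)
for fold in report["folds"]:
    print(f"fold {fold['fold']}: subjects {fold['test_subjects']}, "
          f"Sen {fold['sensitivity']:.1f}% Spe {fold['specificity']:.1f}% "
          f"(SEFd_th {fold['thresholds']['sefd_th']:.2f} Hz)")
m = report["mean"]
print(f"mean over folds: Sen {m['sensitivity']:.1f}% "
      f"Spe {m['specificity']:.1f}% Sel {m['selectivity']:.1f}% "
      f"Acc {m['accuracy']:.1f}%")
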