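# Methods

## Signal model and preprocessing

The detector assumes a single uniformly sampled EEG channel in
microvolts. Input is resampled to 256 Hz by polyphase rational-ratio
filtering (`scipy.signal.resample_poly`, Kaiser anti-alias design); a
signal already at 256 Hz passes through untouched. Band-limiting uses a
first-order Butterworth high-pass at 0.16 Hz (DC rejection) and a
second-order Butterworth low-pass at 50 Hz. Both filters run causally
in a single pass (zero initial state): the detector is meant for
real-time, wearable-style operation, where zero-phase double filtering
is unavailable. Epochs of 30 s start at sample 0 with no offset; a
trailing partial epoch is discarded with a warning, and a signal/
hypnogram epoch-count mismatch truncates both to the shorter side
rather than failing the run.

## Spectral features

Each of an epoch's fifteen 2-s subepochs is transformed with a
512-point FFT after mean removal, with no taper. Magnitudes carry the
energy-preserving one-sided scaling (interior bins ×√(2/N), DC and
Nyquist ×√(1/N)) so Σ mag² equals the time-domain energy; this scaling
is uniform across the 8–16 Hz analysis band, so it shifts AP by a
constant and leaves SEF and RP unchanged relative to unscaled
magnitudes.

Conventions that the formulas leave open were fixed as follows:

* Band edges are inclusive on the 0.5 Hz grid: 8–16 Hz spans 17 bins.
* SEF at fraction q is the lowest band frequency whose cumulative
  power reaches q of the band total; ties resolve to the lower
  frequency. A relative tolerance of 1e−12 guards the comparison
  against cumulative-sum rounding.
* AP and RP use 20·log₁₀ of magnitude *sums*, not squared power — the
  formulas are implemented exactly as stated even though the quantities
  are called powers.
* The RP denominator is the one-sided spectrum excluding the DC bin
  (the high-pass removes DC anyway), so RP ≤ 0 whenever the band is a
  subset of the spectrum.
* Only SEFd is smoothed (9-point centered moving average across the
  epoch series); AP and RP are subepoch-averaged but not
  series-smoothed. At the series edges the window shrinks
  symmetrically, preserving constants and length. Invalid epochs are
  excluded from their neighbours' windows and pass through as NaN.
* An epoch with zero band (or full-spectrum) magnitude in any subepoch
  is flagged invalid and classified non-REM downstream — a fail-safe
  default rather than a guess.

## Classifier

Stage 1 marks an epoch as a candidate when `SEFd ≥ SEFd_th`; stage 2
confirms REM when `AP ≤ AP_max` and `RP_min ≤ RP ≤ RP_max`. All
inequalities are inclusive, exactly as the decision rules are written.
The stage split is not just organisational: AP/RP are only evaluated
for candidates, the property that makes the algorithm cheap on
low-power hardware. The shipped defaults
(4.54 Hz, 15.5 dB, [−13.03, −6.08] dB) are the fixed operating point
for recordings on the original training data's amplitude scale; any
other source — the synthetic generator included — needs recalibration,
since AP is scale-dependent.

## Calibration

Stage 1 sweeps every observed SEFd value as a threshold
(`value ≥ threshold` → REM), builds the ROC curve (scikit-learn,
`drop_intermediate=False`) and selects the point with minimal Euclidean
distance to the ideal (0, 1) corner — equal weighting of sensitivity
and specificity. Ties break toward higher specificity, then the lower
threshold. AUC is the trapezoidal area, which the tests pin to the
brute-force pairwise-concordance probability.

Stage 2 searches (AP_max, RP_min, RP_max) over quantile grids (41
points by default) of the stage-1 candidates' AP and RP values, with
RP_min < RP_max, scoring each triple by the same corner distance of
the full two-stage classifier over *all* epochs. Two deliberate
choices:

* The grids are padded one step beyond the candidate extremes (25% of
  the observed range, at least 0.5 dB). Padded bounds cost nothing on
  the training sweep, but via the tie-break they leave margin for the
  feature spread of unseen recordings.
* Ties break toward higher specificity, then the most permissive
  triple (widest RP window, loosest AP ceiling). Narrow interior
  windows that merely shave training outliers would otherwise win ties
  and generalise poorly.

Whether the original calibration swept the RP pair jointly or fixed
one bound while sweeping the other is not specified anywhere; the
joint quantile grid is this package's choice. A per-recording
("patient-specific") calibration simply applies `calibrate_thresholds`
per subject; `crossvalidate` partitions *subjects*, never epochs, so no
subject leaks across a fold boundary.

## Evaluation

REM is the positive class. Sensitivity TP/(TP+FN), specificity
TN/(TN+FP), selectivity TP/(TP+FP) and accuracy (TP+TN)/N are reported
as percentages; a zero-denominator metric is reported as undefined
(None), never as 0, so recording averages are not silently deflated.
Multi-recording summaries are unweighted means over recordings, with
pooled-count variants alongside. Cohen's kappa is computed on the
binary REM/non-REM task and labelled as such in reports. MOVEMENT
reference epochs are rescored as Wake by default (AASM practice) and
UNSCORED epochs are excluded; both policies are configurable. The
per-stage breakdown attributes each false positive to its reference
stage and is conserved by construction: the stage counts always sum to
the total FP. The Wald binomial interval uses the normal approximation
via statsmodels.

## Synthetic data

The generator exists so that every claim the test suite makes can be
checked against known ground truth. Each stage has a target magnitude
spectrum on the 0.5 Hz grid (0.5–50 Hz): a 1/f background plus
Gaussian bumps — Wake an alpha peak near 10 Hz, N1 theta with residual
low-alpha, N2 a 12–14 Hz spindle elevation, N3 delta dominance, REM a
bump just above 8 Hz, 9–15 Hz suppression and a rise near 15 Hz. By
construction REM has the greatest template SEFd (8.0 Hz vs ≤ 1.5 Hz)
and the lowest 8–16 Hz power, with Wake/N1 above it. Signals are sums
of bin-aligned sinusoids (random phases, 10% per-bin amplitude jitter,
small white-noise floor), so the 512-point analysis FFT recovers the
template almost exactly — that alignment is what makes tight spectral
oracles possible. Amplitudes are artifact parameters chosen for the
ordering constraints, not claims about real microvolt levels.

Stage sequences are drawn bout-wise with per-stage bout-length ranges
(REM 16–48 epochs, N2 10–40, N3 10–30, W 4–20, N1 2–8), reflecting
that real stages persist for minutes. This matters: the 9-point SEFd
smoother dilutes the first and last epochs of every REM bout, and
one-epoch REM bouts — common under an i.i.d. stage draw, rare in real
hypnograms — would be unrecoverable by the method itself.

What the generator does *not* emulate: movement and muscle artefacts,
inter-subject amplitude variability, stage transitions with mixed
character, and any waveform morphology (spindle envelopes, K-complexes,
sawtooth waves). Passing synthetic tests therefore demonstrates the
pipeline's correctness and the method's behaviour under its own
assumptions, not clinical-grade performance on real polysomnography.

## Problem sizes

The synthetic studies use 100-epoch recordings (50 min) for the
calibrate-then-detect experiment, 60–100 epochs elsewhere, and 20
replicates of 400 feature samples for the threshold-recovery study —
sizes at which every quantity of interest is stable while the full
suite runs in seconds. The designed-boundary recovery study places the
two classes' SEFd distributions symmetrically about 4.5 Hz
(±0.6 Hz, σ = 0.45 Hz) so the optimal separating threshold is the
boundary itself, and asks the calibrated threshold to land within
±0.25 Hz.

## Known limitations

* AP thresholds are amplitude-scale-dependent; there is no automatic
  gain normalisation, matching the original fixed-threshold design.
* The EDF writer is minimal (16-bit, one-second records, uV only); it
  exists for round-tripping synthetic data and is not a general EDF+
  annotation writer.
* Epoch geometry is fixed at 30 s / 2 s / 256 Hz; other grids are
  rejected at configuration time rather than approximated.
* No contextual smoothing of the predicted hypnogram and no artefact
  rejection stage — both are outside the algorithm by design.
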