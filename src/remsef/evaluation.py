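"""Scoring against reference hypnograms.

REM is the positive class throughout. Sensitivity, specificity,
selectivity (positive predictive value) and accuracy are reported as
percentages; metrics with a zero denominator are reported as undefined
(None), never as zero. Cohen's kappa is computed on the binary
REM/non-REM task. A per-stage breakdown attributes every false positive
to the reference stage (W, N1, N2, N3) it came from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = ["ConfusionCounts", "confusion", "confusion_from_binary",
           "metrics", "cohens_kappa", "stage_fp_breakdown",
           "wald_interval", "filter_scorable"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Epoch counts of the binary REM/non-REM confusion table."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def filter_scorable(predictions, reference_stages,
                    exclude_unscored: bool = True,
                    movement_as_wake: bool = True):
    """Apply the evaluation exclusion policy to aligned label sequences.

    MOVEMENT reference epochs are rescored as Wake by default (AASM
    practice); UNSCORED epochs are excluded by default. Returns the
    filtered (predictions, reference_stages) pair.
    """
    preds, stages = list(predictions), list(reference_stages)
    if len(preds) != len(stages):
        raise ValueError("predictions and reference must have equal length")
    out_p, out_s = [], []
    for p, s in zip(preds, stages):
        if s == "MOVEMENT" and movement_as_wake:
            s = "W"
        if s == "UNSCORED" and exclude_unscored:
            continue
        out_p.append(p)
        out_s.append(s)
    return out_p, out_s


def confusion_from_binary(pred_rem, ref_rem) -> ConfusionCounts:
    """Confusion counts from aligned boolean REM indicators."""
    pred_rem = np.asarray(pred_rem, dtype=bool)
    ref_rem = np.asarray(ref_rem, dtype=bool)
    if pred_rem.shape != ref_rem.shape:
        raise ValueError("length mismatch between predictions and reference")
    return ConfusionCounts(
        tp=int((pred_rem & ref_rem).sum()),
        fp=int((pred_rem & ~ref_rem).sum()),
        tn=int((~pred_rem & ~ref_rem).sum()),
        fn=int((~pred_rem & ref_rem).sum()),
    )


def confusion(predictions, reference_stages, **policy) -> ConfusionCounts:
    """Confusion counts of REM predictions against a stage reference.

    ``predictions`` are "REM"/"NONREM" labels (or booleans); the
    reference carries full stage labels, filtered through
    :func:`filter_scorable` first.
    """
    preds, stages = filter_scorable(predictions, reference_stages, **policy)
    pred_rem = np.array([p in ("REM", True) for p in preds], dtype=bool)
    ref_rem = np.array([s == "REM" for s in stages], dtype=bool)
    return confusion_from_binary(pred_rem, ref_rem)


def metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, selectivity, accuracy in percent.

    A metric whose denominator is zero is returned as None (undefined)
    rather than zero, so averages over recordings are not silently
    deflated.
    """
    def pct(num, den):
        return 100.0 * num / den if den > 0 else None

    return {
        "sensitivity": pct(c.tp, c.tp + c.fn),
        "specificity": pct(c.tn, c.tn + c.fp),
        "selectivity": pct(c.tp, c.tp + c.fp),
        "accuracy": pct(c.tp + c.tn, c.total),
    }


def cohens_kappa(predictions, reference) -> float | None:
    """Chance-corrected agreement on the binary REM/non-REM task.

    κ = (p_o − p_e)/(1 − p_e) with the chance agreement p_e from the two
    raters' marginals. Returns None when both raters are constant
    (p_e = 1, κ undefined).
    """
    pred = np.array([p in ("REM", True) for p in predictions], dtype=bool)
    ref = np.array([r in ("REM", True) for r in reference], dtype=bool)
    if pred.shape != ref.shape or len(pred) == 0:
        raise ValueError("non-empty aligned label sequences required")
    n = len(pred)
    p_o = float((pred == ref).mean())
    p_e = (pred.mean() * ref.mean()
           + (1 - pred.mean()) * (1 - ref.mean()))
    if p_e >= 1.0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


def kappa_from_counts(c: ConfusionCounts) -> float | None:
    """Binary Cohen's kappa computed directly from confusion counts."""
    n = c.total
    if n == 0:
        raise ValueError("empty confusion table")
    p_o = (c.tp + c.tn) / n
    pred_pos = (c.tp + c.fp) / n
    ref_pos = (c.tp + c.fn) / n
    p_e = pred_pos * ref_pos + (1 - pred_pos) * (1 - ref_pos)
    if p_e >= 1.0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


def stage_fp_breakdown(predictions, reference_stages, **policy) -> dict:
    """Per-stage false-positive attribution.

    For each non-REM stage (W, N1, N2, N3) counts the reference epochs
    of that stage predicted REM, alongside the stage's epoch total. The
    per-stage false positives always sum to the overall FP count.
    """
    preds, stages = filter_scorable(predictions, reference_stages, **policy)
    out = {}
    total_fp = 0
    for stage in ("W", "N1", "N2", "N3"):
        in_stage = [p for p, s in zip(preds, stages) if s == stage]
        fp = sum(1 for p in in_stage if p in ("REM", True))
        out[stage] = {"fp": fp, "total": len(in_stage)}
        total_fp += fp
    out["total_fp"] = total_fp
    return out


def wald_interval(proportion: float, n: int,
                  confidence: float = 0.95) -> tuple[float, float]:
    """Wald (normal-approximation) binomial confidence interval.

    ``proportion`` on [0, 1]; returns (lower, upper) on the same scale.
    """
    if not 0 <= proportion <= 1:
        raise ValueError("proportion must be in [0, 1]")
    if n <= 0:
        raise ValueError("n must be positive")
    lo, hi = proportion_confint(proportion * n, n, alpha=1 - confidence,
                                method="normal")
    return float(lo), float(hi)
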