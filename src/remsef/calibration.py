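"""Threshold calibration: ROC sweeps, operating-point selection, k-fold CV.

Stage 1 tunes the SEFd threshold from a ROC curve (decision rule
``value >= threshold`` → REM), choosing the point closest to the ideal
(0, 1) corner — equal weighting of sensitivity and specificity. Stage 2
grid-searches the AP ceiling and RP window over quantiles of the
candidate epochs' AP/RP values, minimising the same corner distance of
the full two-stage classifier evaluated over all epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skm

from .detector import Thresholds
from .evaluation import confusion_from_binary, metrics as eval_metrics

__all__ = ["ROCResult", "roc_curve", "optimal_operating_point",
           "calibrate_thresholds", "crossvalidate"]


@dataclass
class ROCResult:
    """A swept ROC curve with its AUC and chosen operating point."""

    points: np.ndarray        # columns: (1-specificity, sensitivity, threshold)
    auc: float
    optimal_threshold: float
    optimal_distance: float


def _corner_distance(fpr: np.ndarray, tpr: np.ndarray) -> np.ndarray:
    return np.sqrt(fpr ** 2 + (1.0 - tpr) ** 2)


def roc_curve(values, labels) -> ROCResult:
    """ROC curve of a single feature against binary REM labels.

    Sweeps every observed value as a threshold (``value >= threshold`` is
    a positive call). AUC is the trapezoidal area, which equals the
    probability of pairwise concordance with ties counted half.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to sweep a ROC curve")
    fpr, tpr, thr = skm.roc_curve(labels, values, drop_intermediate=False)
    # drop sklearn's synthetic (max+1) starting point; keep finite sweeps
    finite = np.isfinite(thr)
    fpr, tpr, thr = fpr[finite], tpr[finite], thr[finite]
    order = np.argsort(thr)
    fpr, tpr, thr = fpr[order], tpr[order], thr[order]
    auc = float(skm.roc_auc_score(labels, values))
    opt_thr, opt_dist = _pick_operating_point(fpr, tpr, thr)
    return ROCResult(points=np.column_stack([fpr, tpr, thr]), auc=auc,
                     optimal_threshold=opt_thr, optimal_distance=opt_dist)


def _pick_operating_point(fpr, tpr, thr) -> tuple[float, float]:
    dist = _corner_distance(fpr, tpr)
    # ties: prefer higher specificity (lower fpr), then lower threshold
    key = np.lexsort((thr, fpr, dist))
    best = key[0]
    return float(thr[best]), float(dist[best])


def optimal_operating_point(roc: ROCResult) -> float:
    """Threshold of the ROC point closest to the (0, 1) corner."""
    if len(roc.points) == 0:
        raise ValueError("empty ROC curve")
    fpr, tpr, thr = roc.points.T
    return _pick_operating_point(fpr, tpr, thr)[0]


def _stage2_grid_search(sefd, ap, rp, labels, sefd_th,
                        n_quantiles: int = 41) -> tuple[float, float, float]:
    """Search (ap_max, rp_min, rp_max) over candidate-epoch quantile grids.

    Fully vectorised: boolean count matrices are built by matrix products
    so the whole (41 x 820) triple grid is scored at once.
    """
    candidate = sefd >= sefd_th
    if candidate.sum() == 0:
        raise ValueError(
            "no stage-1 candidates at the tuned SEFd threshold; "
            "inspect the stage-1 ROC before stage-2 calibration")
    q = np.linspace(0.0, 1.0, n_quantiles)
    ap_grid = np.unique(np.quantile(ap[candidate], q))
    rp_grid = np.unique(np.quantile(rp[candidate], q))
    # pad each grid beyond the observed candidate range: padded bounds
    # cost nothing on the training sweep but, via the permissive
    # tie-break, leave margin for unseen recordings' feature spread
    ap_pad = max(0.25 * np.ptp(ap_grid), 0.5)
    rp_pad = max(0.25 * np.ptp(rp_grid), 0.5)
    ap_grid = np.append(ap_grid, ap_grid[-1] + ap_pad)
    rp_grid = np.concatenate([[rp_grid[0] - rp_pad], rp_grid,
                              [rp_grid[-1] + rp_pad]])
    lo_idx, hi_idx = np.triu_indices(len(rp_grid), k=1)
    rp_lo, rp_hi = rp_grid[lo_idx], rp_grid[hi_idx]

    ap_ok = ap[:, None] <= ap_grid[None, :]                  # (n, A)
    rp_ok = ((rp[:, None] >= rp_lo[None, :])
             & (rp[:, None] <= rp_hi[None, :]))              # (n, P)
    pos = labels & candidate
    neg = ~labels & candidate
    tp = (ap_ok & pos[:, None]).T.astype(float) @ rp_ok      # (A, P)
    fp = (ap_ok & neg[:, None]).T.astype(float) @ rp_ok
    n_pos, n_neg = labels.sum(), (~labels).sum()
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    dist = np.sqrt((1 - spec) ** 2 + (1 - sens) ** 2)
    # deterministic tie-break: higher specificity, then the most
    # permissive triple (widest RP window, loosest AP ceiling) so that
    # equally scoring operating points do not overfit the training RP/AP
    # spread
    width = np.broadcast_to((rp_hi - rp_lo)[None, :], dist.shape)
    ap_b = np.broadcast_to(ap_grid[:, None], dist.shape)
    flat = np.lexsort((-ap_b.ravel(), -width.ravel(),
                       (1 - spec).ravel(), dist.ravel()))
    a, p = np.unravel_index(flat[0], dist.shape)
    return float(ap_grid[a]), float(rp_lo[p]), float(rp_hi[p])


def calibrate_thresholds(features, labels,
                         n_quantiles: int = 41) -> Thresholds:
    """Fit the four classifier thresholds from labelled epoch features.

    ``features`` is a sequence of EpochFeatures (or an (n, 3) array of
    SEFd/AP/RP columns); ``labels`` are binary REM indicators. Invalid
    epochs are dropped before fitting.
    """
    sefd, ap, rp, labels = _feature_arrays(features, labels)
    roc = roc_curve(sefd, labels)
    sefd_th = roc.optimal_threshold
    ap_max, rp_min, rp_max = _stage2_grid_search(
        sefd, ap, rp, labels, sefd_th, n_quantiles)
    return Thresholds(sefd_th=sefd_th, ap_max=ap_max,
                      rp_max=rp_max, rp_min=rp_min)


def _feature_arrays(features, labels):
    labels = np.asarray(labels, dtype=bool)
    if hasattr(features[0], "sefd"):
        valid = np.array([f.valid for f in features], dtype=bool)
        arr = np.array([[f.sefd, f.ap, f.rp] for f in features])
    else:
        arr = np.asarray(features, dtype=np.float64)
        valid = np.ones(len(arr), dtype=bool)
    if len(arr) != len(labels):
        raise ValueError("features and labels must align")
    arr, labels = arr[valid], labels[valid]
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present for calibration")
    return arr[:, 0], arr[:, 1], arr[:, 2], labels


def crossvalidate(recordings, k: int, seed: int) -> dict:
    """Subject-level k-fold cross-validation.

    ``recordings`` is a sequence of (features, labels) pairs, one per
    subject; folds partition subjects (never epochs), so no subject
    contributes to both the training and the held-out side of a fold.
    Returns per-fold and averaged Sen/Spe/Sel/Acc (percent).
    """
    from .detector import detect_recording

    n = len(recordings)
    if k < 2 or k > n:
        raise ValueError(f"fold count k={k} must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    per_fold = []
    for fold_idx, test_subjects in enumerate(folds):
        train_subjects = np.setdiff1d(order, test_subjects)
        train_feats = [f for s in train_subjects for f in recordings[s][0]]
        train_labels = np.concatenate(
            [np.asarray(recordings[s][1], dtype=bool)
             for s in train_subjects])
        th = calibrate_thresholds(train_feats, train_labels)
        subj_metrics = []
        for s in test_subjects:
            feats, labels = recordings[s]
            pred = detect_recording(feats, th).binary()
            c = confusion_from_binary(pred, np.asarray(labels, dtype=bool))
            subj_metrics.append(eval_metrics(c))
        fold_mean = {m: float(np.mean([sm[m] for sm in subj_metrics
                                       if sm[m] is not None]))
                     for m in ("sensitivity", "specificity",
                               "selectivity", "accuracy")}
        per_fold.append({"fold": fold_idx,
                         "test_subjects": [int(s) for s in test_subjects],
                         "thresholds": th.to_dict(), **fold_mean})
    mean = {m: float(np.mean([f[m] for f in per_fold]))
            for m in ("sensitivity", "specificity", "selectivity",
                      "accuracy")}
    return {"folds": per_fold, "mean": mean, "k": k, "seed": seed}
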