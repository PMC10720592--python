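"""Salient-event-onset detection and ROC evaluation.

Rather than predicting a continuous salience curve, the detector answers a
binary question per 1 s segment of a scene: did a salient-event onset occur
inside it?  The model is a constrained linear-sigmoid readout of
first-differenced features: a single temporal weight vector shared across
features, combined with per-feature weights and a bias,

    score = sigmoid( w_time' X w_feat + b ),    X in R^(lags x features)

trained by plain stochastic gradient descent on a cross-entropy loss
(mini-batch 200, learning rate 0.01, 100 epochs, lowest-training-loss
snapshot kept).  The acoustic variant (A) sees the 1 s segment; the
acoustic-semantic variant (A-S) appends a 3 s past context and the surprisal
columns.  Baselines evaluated through the same ROC harness: the posterior
change-detection signal of an audio tagger, and the interobserver agreement
(count of participants switching toward the scene per segment), an
empirical ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavioral import GRID_STEP, TrialResponse, _shift_earlier
from .semantic import PosteriorTable, posterior_change_signal

__all__ = [
    "DetectionDataset",
    "DetectionModel",
    "ROCResult",
    "make_detection_dataset",
    "fit_detector",
    "roc",
    "interobserver_signal",
    "baseline_posterior_change",
]


@dataclass
class DetectionDataset:
    """Labeled 1 s segments with windowed first-differenced features."""

    X: np.ndarray  # (n_segments, n_lags, n_features)
    labels: np.ndarray  # (n_segments,) in {0, 1}
    starts: np.ndarray  # segment start times, s
    scene_ids: list
    variant: str  # "A" | "A-S"
    seg_len: float = 1.0
    frame_step: float = GRID_STEP


@dataclass
class DetectionModel:
    w_time: np.ndarray
    w_feat: np.ndarray
    b: float
    variant: str
    best_loss: float = np.nan

    def scores(self, X: np.ndarray) -> np.ndarray:
        z = np.einsum("nlf,l,f->n", X, self.w_time, self.w_feat) + self.b
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class ROCResult:
    thresholds: np.ndarray
    hit_rates: np.ndarray
    fa_rates: np.ndarray
    auroc: float


def make_detection_dataset(
    features: np.ndarray,
    surprisal: np.ndarray | None,
    onsets: list[float],
    scene_id: str = "scene",
    frame_step: float = GRID_STEP,
    seg_len: float = 1.0,
    past_context: float = 0.0,
) -> DetectionDataset:
    """Cut a scene into labeled non-overlapping 1 s detection segments.

    Features (and surprisal columns, if given) are first-differenced along
    time, then windowed: each segment's input covers ``past_context`` +
    ``seg_len`` seconds ending at the segment end.  A segment is positive
    iff at least one onset falls in its half-open interval [start, end).
    Segments without full past context are dropped.
    """
    cols = [np.asarray(features, dtype=float)]
    if surprisal is not None:
        cols.append(np.asarray(surprisal, dtype=float))
    Xfull = np.concatenate(cols, axis=1)
    dX = np.vstack([np.zeros((1, Xfull.shape[1])), np.diff(Xfull, axis=0)])
    T = len(dX)
    n_seg_frames = int(round(seg_len / frame_step))
    n_ctx_frames = int(round(past_context / frame_step))
    window = n_seg_frames + n_ctx_frames
    if T < window:
        raise ValueError("scene shorter than one detection window (segment + context)")
    onsets = np.asarray(onsets, dtype=float)
    segs, labels, starts = [], [], []
    i0 = n_ctx_frames  # first segment with full context
    while i0 + n_seg_frames <= T:
        t_start = i0 * frame_step
        t_end = (i0 + n_seg_frames) * frame_step
        segs.append(dX[i0 - n_ctx_frames : i0 + n_seg_frames])
        labels.append(int(np.any((onsets >= t_start) & (onsets < t_end))))
        starts.append(t_start)
        i0 += n_seg_frames
    variant = "A" if surprisal is None else "A-S"
    return DetectionDataset(
        np.stack(segs), np.asarray(labels), np.asarray(starts),
        [scene_id] * len(segs), variant, seg_len, frame_step,
    )


def concat_datasets(datasets: list[DetectionDataset]) -> DetectionDataset:
    first = datasets[0]
    return DetectionDataset(
        np.concatenate([d.X for d in datasets]),
        np.concatenate([d.labels for d in datasets]),
        np.concatenate([d.starts for d in datasets]),
        sum((d.scene_ids for d in datasets), []),
        first.variant, first.seg_len, first.frame_step,
    )


def fit_detector(
    dataset: DetectionDataset,
    lr: float = 0.01,
    batch_size: int = 200,
    epochs: int = 100,
    seed: int = 0,
) -> DetectionModel:
    """Train the shared-temporal-weight sigmoid detector by plain SGD.

    Cross-entropy loss, seeded shuffling each epoch, no momentum.  The
    parameter snapshot with the lowest full-training-set loss across epochs
    is returned.
    """
    y = dataset.labels.astype(float)
    if len(np.unique(dataset.labels)) < 2:
        raise ValueError("detector training needs both positive and negative segments")
    X = dataset.X
    n, n_lags, n_feat = X.shape
    rng = np.random.default_rng(seed)
    w_t = rng.normal(0, 0.1, n_lags)
    w_f = rng.normal(0, 0.1, n_feat)
    b = 0.0

    def full_loss() -> float:
        z = np.einsum("nlf,l,f->n", X, w_t, w_f) + b
        # stable binary cross-entropy
        return float(np.mean(np.logaddexp(0, z) - y * z))

    best = (full_loss(), w_t.copy(), w_f.copy(), b)
    for _ in range(epochs):
        order = rng.permutation(n)
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            Xb, yb = X[idx], y[idx]
            z = np.einsum("nlf,l,f->n", Xb, w_t, w_f) + b
            err = 1.0 / (1.0 + np.exp(-z)) - yb  # d loss / d z
            g_t = np.einsum("n,nlf,f->l", err, Xb, w_f) / len(idx)
            g_f = np.einsum("n,nlf,l->f", err, Xb, w_t) / len(idx)
            g_b = float(err.mean())
            w_t -= lr * g_t
            w_f -= lr * g_f
            b -= lr * g_b
        loss = full_loss()
        if loss < best[0]:
            best = (loss, w_t.copy(), w_f.copy(), b)
    loss, w_t, w_f, b = best
    return DetectionModel(w_t, w_f, float(b), dataset.variant, best_loss=loss)


def roc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Threshold sweep over unique scores; trapezoidal AUROC.

    Equivalent to the normalized Mann-Whitney U statistic (ties handled by
    the trapezoid over tied thresholds).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative segment")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    hits = np.array([(scores[labels] >= th).mean() for th in thresholds])
    fas = np.array([(scores[~labels] >= th).mean() for th in thresholds])
    auroc = float(np.trapezoid(hits, fas))
    return ROCResult(thresholds, hits, fas, auroc)


def interobserver_signal(
    trials: list[TrialResponse],
    starts: np.ndarray,
    seg_len: float = 1.0,
    rt_shift: float = 1.0,
) -> np.ndarray:
    """Participants switching toward the scene per segment (detection ceiling).

    Counts, for each segment, the participants with a 0 -> 1 transition
    inside [start, start + seg_len) on the reaction-time-shifted timeline
    (the timeline event onsets live on).  Counts are integers bounded by the
    cohort size.
    """
    counts = np.zeros(len(starts))
    for trial in trials:
        shifted = _shift_earlier(trial.trace.astype(np.int8), int(round(rt_shift / trial.dt)))
        switch_t = (np.flatnonzero(np.diff(shifted) == 1) + 1) * trial.dt
        for i, s in enumerate(starts):
            if np.any((switch_t >= s) & (switch_t < s + seg_len)):
                counts[i] += 1
    return counts


def baseline_posterior_change(
    posteriors: PosteriorTable,
    starts: np.ndarray,
    labels: np.ndarray,
    seg_len: float = 1.0,
    threshold: float = 0.5,
    median_win: float = 1.0,
) -> ROCResult:
    """ROC of the audio-tagging posterior change signal as an onset detector.

    The per-frame class-change signal is max-pooled within each 1 s segment
    (onset pulses are sparse, so the max is the natural pooled score) and
    swept through the shared ROC harness.
    """
    signal = posterior_change_signal(posteriors, threshold, median_win)
    step = posteriors.frame_step
    scores = np.array(
        [
            signal[int(round(s / step)) : max(int(round((s + seg_len) / step)), int(round(s / step)) + 1)].max()
            for s in starts
        ]
    )
    return roc(scores, labels)
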