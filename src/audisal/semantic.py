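"""Semantic characterization of scenes from deep-embedding streams.

A pluggable *embedding provider* maps a waveform to per-layer hidden-vector
time series (an :class:`EmbeddingStream`) and optionally to a table of
audio-class posterior probabilities.  Because intermediate layers are very
high-dimensional, each layer is compressed to a one-dimensional *surprisal*:
the Euclidean distance between the current hidden vector and its mean over
the preceding 4 s.  Surprisal rises whenever the network's representation of
the scene changes, serving as a proxy for contextual/semantic novelty.

Class posteriors support two further operations: labeling a segment with a
dominant top-level class by belief propagation over a leaf-to-root ontology
mapping, and a change-detection baseline signal built from thresholded,
median-filtered posterior trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "EmbeddingStream",
    "SurprisalMatrix",
    "PosteriorTable",
    "EmbeddingProvider",
    "ROOT_CLASSES",
    "layer_surprisal",
    "dominant_class",
    "posterior_change_signal",
    "validate_stream",
]

#: Top-level ontology roots used for dominant-class labeling.
ROOT_CLASSES = ("Animals", "Background", "Human", "Music", "Things")


@dataclass
class EmbeddingStream:
    """Per-layer hidden-vector time series for one scene.

    ``layers[l]`` has shape (T, K_l): T frames shared across layers, K_l the
    flattened dimension of layer l.
    """

    scene_id: str
    layers: list[np.ndarray]
    frame_step: float

    def __post_init__(self) -> None:
        self.layers = [np.atleast_2d(np.asarray(a, dtype=float)) for a in self.layers]
        if not self.layers:
            raise ValueError("stream must contain at least one layer")
        T = self.layers[0].shape[0]
        for i, a in enumerate(self.layers):
            if a.shape[0] != T:
                raise ValueError(f"layer {i} has {a.shape[0]} frames, expected {T}")
            if a.shape[1] < 1:
                raise ValueError(f"layer {i} has non-positive dimension")
        if self.frame_step <= 0:
            raise ValueError("frame_step must be positive")

    @property
    def n_frames(self) -> int:
        return self.layers[0].shape[0]

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass
class SurprisalMatrix:
    """Layer-wise surprisal, one non-negative column per layer."""

    scene_id: str
    frame_step: float
    values: np.ndarray  # (T, L), >= 0
    warmup: np.ndarray = field(default=None)  # bool mask of frames with partial history

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(self.values < -1e-12):
            raise ValueError("surprisal values must be non-negative")
        if self.warmup is None:
            self.warmup = np.zeros(self.values.shape[0], dtype=bool)


@dataclass
class PosteriorTable:
    """Per-frame class posteriors plus a leaf -> root ontology mapping."""

    scene_id: str
    class_ids: list[str]
    values: np.ndarray  # (T, C) in [0, 1]
    frame_step: float
    root_map: dict  # leaf id -> one of ROOT_CLASSES

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.class_ids):
            raise ValueError("posterior column count must match class_ids")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("posteriors must lie in [0, 1]")
        for leaf in self.class_ids:
            root = self.root_map.get(leaf)
            if root not in ROOT_CLASSES:
                raise ValueError(f"leaf {leaf!r} maps to unknown root {root!r}")


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract for any backend producing embedding streams for a waveform.

    Implementations return an :class:`EmbeddingStream` (equal frame count
    across layers) and may also expose ``posteriors``.  The repository ships
    only a synthetic provider; any audio-tagging network satisfying this
    protocol can be plugged in.
    """

    def embed(self, waveform: np.ndarray, sample_rate: float) -> EmbeddingStream: ...


def validate_stream(stream: EmbeddingStream, expected_frame_step: float | None = None) -> None:
    """Reject ragged or misconfigured provider output."""
    T = stream.layers[0].shape[0]
    if any(a.shape[0] != T for a in stream.layers):
        raise ValueError("provider returned ragged frame counts across layers")
    if expected_frame_step is not None and not np.isclose(stream.frame_step, expected_frame_step):
        raise ValueError(
            f"provider frame_step {stream.frame_step} does not match configured {expected_frame_step}"
        )


def layer_surprisal(stream: EmbeddingStream, past: float = 4.0) -> SurprisalMatrix:
    """Euclidean distance between each frame and its mean over the past window.

    For layer l and frame t, surprisal is ||y_{l,t} - mean(y_{l,t-W..t-1})||_2
    with W = past / frame_step; the current frame is excluded from the mean.
    Frames with fewer than W past frames use the history available and are
    flagged as warm-up; frame 0, with no history at all, gets surprisal 0.
    """
    W = int(round(past / stream.frame_step))
    if W < 2:
        raise ValueError("past window must span at least 2 frames")
    T = stream.n_frames
    if T <= 1:
        raise ValueError("stream must have more than one frame")
    out = np.zeros((T, stream.n_layers))
    for li, y in enumerate(stream.layers):
        csum = np.vstack([np.zeros((1, y.shape[1])), np.cumsum(y, axis=0)])
        t = np.arange(1, T)
        lo = np.maximum(t - W, 0)
        counts = (t - lo).astype(float)[:, None]
        past_mean = (csum[t] - csum[lo]) / counts
        out[1:, li] = np.linalg.norm(y[1:] - past_mean, axis=1)
    warmup = np.arange(T) < W
    return SurprisalMatrix(stream.scene_id, stream.frame_step, out, warmup)


def dominant_class(
    posteriors: PosteriorTable, segment: tuple[float, float], top_k: int = 10
) -> tuple[str, bool]:
    """Dominant top-level class of a segment via belief propagation.

    Leaf posteriors are averaged over the half-open segment [start, end); the
    ``top_k`` leaves by average posterior become candidates, their posteriors
    are summed into their ontology roots, and the root with the highest total
    wins.  Ties (in candidate selection and in the root argmax) are broken by
    lexicographic class id so the labeling is deterministic.  Returns
    (root, degenerate) where ``degenerate`` flags an all-zero segment.
    """
    start, end = segment
    i0 = int(np.floor(start / posteriors.frame_step))
    i1 = int(np.ceil(end / posteriors.frame_step))
    if i0 < 0 or i1 > posteriors.values.shape[0] or i1 <= i0:
        raise ValueError(f"segment {segment} outside posterior stream")
    avg = posteriors.values[i0:i1].mean(axis=0)
    # sort by (-posterior, class id): deterministic top-k under ties
    order = sorted(range(len(avg)), key=lambda c: (-avg[c], posteriors.class_ids[c]))
    candidates = order[: min(top_k, len(avg))]
    degenerate = bool(np.all(avg[candidates] == 0))
    belief = {r: 0.0 for r in ROOT_CLASSES}
    for c in candidates:
        belief[posteriors.root_map[posteriors.class_ids[c]]] += float(avg[c])
    best = max(sorted(belief), key=lambda r: belief[r])
    return best, degenerate


def posterior_change_signal(
    posteriors: PosteriorTable, threshold: float = 0.5, median_win: float = 1.0
) -> np.ndarray:
    """Class-change detection signal from thresholded posteriors.

    Each class trajectory is binarized at ``threshold``, median-filtered with
    a window of ``median_win`` seconds (rounded to an odd number of frames),
    first-differenced, and the absolute differences are summed across classes
    per frame.  Isolated blips shorter than half the median window vanish.
    """
    win = max(1, int(round(median_win / posteriors.frame_step)))
    if win % 2 == 0:
        win += 1
    binary = (posteriors.values > threshold).astype(float)
    filtered = median_filter(binary, size=(win, 1), mode="nearest")
    diff = np.abs(np.diff(filtered, axis=0)).sum(axis=1)
    return np.concatenate([[0.0], diff])
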