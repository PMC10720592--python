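"""Salient events: extraction from salience maps, attributes, and matching.

A salient event marks a moment where attention collectively switches toward a
scene.  Onsets are local maxima of the first-order difference of the average
behavioral salience; each onset's offset is the immediately following local
minimum of that derivative.  Events carry four attributes: the *slope*
(derivative value at onset, in salience units per frame), the *absolute
consensus* (peak salience inside the event, i.e. the fraction of participants
attending), the *duration*, and a *strength* defined corpus-wide as
slope + consensus * P75(all onset slopes).

Forward and time-reversed presentations of the same scene are compared by
reversing the backward events onto the forward time axis and computing, for
each reference event, its maximum interval overlap with any counterpart
event, normalized by the reference duration.  Events exceeding 50% overlap
strictly are *matched*; the rest are *mismatched*.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .behavioral import SalienceMap

__all__ = [
    "SalientEvent",
    "MatchResult",
    "extract_events",
    "event_strength",
    "assign_strengths",
    "reverse_events",
    "match_events",
    "compare_event_groups",
]


@dataclass
class SalientEvent:
    scene_id: str
    direction: str
    onset: float  # s
    offset: float  # s
    slope: float  # derivative at onset (salience units per frame)
    consensus: float  # max salience within [onset, offset]
    strength: float = np.nan  # assigned once corpus slopes are known
    closed_at_end: bool = False  # offset forced to scene end (no minimum followed)

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("event offset must follow its onset")
        if not (0 <= self.consensus <= 1):
            raise ValueError("consensus must lie in [0, 1]")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class MatchResult:
    event: SalientEvent
    best_overlap: float  # s
    overlap_score: float  # fraction of the event's duration
    label: str  # "match" | "mismatch"


def _plateau_local_extrema(d: np.ndarray, kind: str) -> np.ndarray:
    """Indices of strict local maxima/minima, first sample of a plateau wins."""
    sign = 1 if kind == "max" else -1
    x = sign * d
    # compress plateaus: direction of last nonzero change before/after each run
    idx = []
    i = 0
    n = len(x)
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        rising_before = i > 0 and x[i - 1] < x[i]
        falling_after = j + 1 < n and x[j + 1] < x[i]
        if rising_before and falling_after:
            idx.append(i)  # first sample of the plateau
        i = j + 1
    return np.asarray(idx, dtype=int)


def extract_events(
    salience: SalienceMap, min_slope: float = 1e-6, rel_floor: float = 0.05
) -> list[SalientEvent]:
    """Extract salient events from a salience map via its first difference.

    Onsets are strict local maxima of the derivative; each is paired with the
    next local minimum of the derivative.  Candidate maxima must exceed both
    ``min_slope`` (absolute numerical-ripple floor) and ``rel_floor`` times
    the map's peak derivative — the relative floor separates collective
    attention switches from the shallow ripples that spurious individual
    switches leave on the averaged map.  Onsets after the last minimum are
    closed at scene end and flagged.  A constant map yields no events.
    """
    v = np.asarray(salience.values, dtype=float)
    if len(v) < 3:
        raise ValueError("salience map must have at least 3 samples")
    d = np.diff(v)
    step = salience.grid_step
    # quantize at 1e-9 relative so float rounding on an exact ramp does not
    # shatter a derivative plateau into spurious strict extrema
    scale = np.max(np.abs(d))
    dq = np.round(d / (scale * 1e-9)) if scale > 0 else d
    maxima = _plateau_local_extrema(dq, "max")
    floor = max(min_slope, rel_floor * (d.max() if d.size else 0.0))
    maxima = maxima[d[maxima] > floor]
    minima = _plateau_local_extrema(dq, "min")
    events: list[SalientEvent] = []
    for m in maxima:
        following = minima[minima > m]
        if following.size:
            off_idx, closed = int(following[0]), False
        else:
            off_idx, closed = len(d) - 1, True
        if off_idx <= m:
            continue
        # derivative index i describes the rise between samples i and i+1;
        # event boundaries are placed at the later sample.
        onset_t = (m + 1) * step
        offset_t = (off_idx + 1) * step
        consensus = float(np.max(v[m : off_idx + 2]))
        events.append(
            SalientEvent(
                salience.scene_id,
                salience.direction,
                onset_t,
                offset_t,
                float(d[m]),
                min(consensus, 1.0),
                closed_at_end=closed,
            )
        )
    return sorted(events, key=lambda e: e.onset)


def event_strength(event: SalientEvent, all_slopes: np.ndarray) -> float:
    """Strength = slope + consensus * 75th percentile of corpus onset slopes."""
    all_slopes = np.asarray(all_slopes, dtype=float)
    if all_slopes.size == 0:
        raise ValueError("corpus onset slopes are required before computing strength")
    p75 = float(np.percentile(all_slopes, 75))
    return float(event.slope + event.consensus * p75)


def assign_strengths(events: list[SalientEvent], all_slopes: np.ndarray | None = None) -> list[SalientEvent]:
    """Return events with strengths computed against the corpus slope P75.

    If ``all_slopes`` is omitted the slopes of ``events`` themselves are the
    corpus (the usual case when all scenes' events are passed together).
    """
    if all_slopes is None:
        all_slopes = np.array([e.slope for e in events])
    return [replace(e, strength=event_strength(e, all_slopes)) for e in events]


def reverse_events(events: list[SalientEvent], scene_duration: float) -> list[SalientEvent]:
    """Map events of a time-reversed presentation onto the forward time axis.

    new onset = duration - old offset, new offset = duration - old onset;
    the involution property (reversing twice is the identity) holds exactly.
    """
    out = []
    for e in events:
        if e.onset < 0 or e.offset > scene_duration:
            raise ValueError(f"event [{e.onset}, {e.offset}] outside scene of {scene_duration}s")
        out.append(
            replace(e, onset=scene_duration - e.offset, offset=scene_duration - e.onset)
        )
    return sorted(out, key=lambda e: e.onset)


def match_events(
    ref_events: list[SalientEvent],
    other_events: list[SalientEvent],
    threshold: float = 0.5,
) -> list[MatchResult]:
    """Label each reference event matched/mismatched by normalized overlap.

    For each reference event the maximum interval intersection with any
    counterpart event is normalized by the reference event's duration; the
    label is "match" iff the score exceeds ``threshold`` strictly (a score of
    exactly 0.5 at the default threshold is a mismatch).
    """
    results = []
    for e in ref_events:
        if e.duration <= 0:
            raise ValueError("zero-duration reference event")
        best = 0.0
        for o in other_events:
            best = max(best, min(e.offset, o.offset) - max(e.onset, o.onset))
        best = max(best, 0.0)
        score = best / e.duration
        results.append(MatchResult(e, best, score, "match" if score > threshold else "mismatch"))
    return results


_ATTRIBUTE_GETTERS = {
    "duration": lambda e: e.duration,
    "strength": lambda e: e.strength,
    "slope": lambda e: e.slope,
    "consensus": lambda e: e.consensus,
}


def compare_event_groups(
    groups: dict[str, list[SalientEvent]],
    attributes: tuple[str, ...] = ("duration", "strength", "slope", "consensus"),
) -> pd.DataFrame:
    """Group means and two-sided Wilcoxon rank-sum tests per attribute.

    Pairs of labeled groups (e.g. matched vs mismatched) are compared for
    each requested attribute; groups with fewer than 2 events are flagged and
    their test skipped.
    """
    names = list(groups)
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("every group must contain at least one event")
    rows = []
    for attr in attributes:
        get = _ATTRIBUTE_GETTERS[attr]
        vals = {g: np.array([get(e) for e in groups[g]]) for g in names}
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                row = {
                    "attribute": attr,
                    "group_a": a,
                    "group_b": b,
                    "mean_a": float(np.mean(vals[a])),
                    "mean_b": float(np.mean(vals[b])),
                    "n_a": len(vals[a]),
                    "n_b": len(vals[b]),
                }
                if len(vals[a]) < 2 or len(vals[b]) < 2:
                    row.update(statistic=np.nan, p=np.nan, skipped=True)
                else:
                    s, p = stats.ranksums(vals[a], vals[b])
                    row.update(statistic=float(s), p=float(p), skipped=False)
                rows.append(row)
    return pd.DataFrame(rows)
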