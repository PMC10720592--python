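"""Behavioral analysis of dichotic-listening attention traces.

Participants listening to two competing scenes report, continuously, which
side holds their attention.  A trial trace is a binary time series that is 1
while the participant attends the scene under analysis and 0 otherwise.  This
module turns collections of such traces into quality-controlled *average
behavioral salience* maps: each trace is shifted earlier by an average
reaction-time delay, resampled to a common grid, averaged across participants
and smoothed with three moving-average passes.  It also provides per-
participant reaction-time summaries and forward/backward agreement measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

__all__ = [
    "TrialResponse",
    "SalienceMap",
    "QCReport",
    "switching_rate",
    "quality_control",
    "average_behavioral_salience",
    "individual_reaction_times",
    "fwd_bwd_agreement",
    "noise_floor",
    "GRID_STEP",
]

#: Pipeline-wide analysis grid step in seconds (shared with the acoustic and
#: semantic feature pipelines).
GRID_STEP = 0.064


@dataclass
class TrialResponse:
    """One participant's binary attention trace toward one scene in one trial."""

    participant_id: str
    scene_id: str
    direction: str  # "fwd" or "bwd"
    opposing_scene_id: str
    trace: np.ndarray  # values in {0, 1}, uniform time step
    dt: float  # time step of ``trace`` in seconds

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace)
        if self.trace.ndim != 1:
            raise ValueError("trace must be one-dimensional")
        vals = np.unique(self.trace)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("trace values must be binary (0/1)")
        if self.direction not in ("fwd", "bwd"):
            raise ValueError(f"direction must be 'fwd' or 'bwd', got {self.direction!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def duration(self) -> float:
        return len(self.trace) * self.dt


@dataclass
class SalienceMap:
    """Average behavioral salience for one scene/direction on a uniform grid."""

    scene_id: str
    direction: str
    grid_step: float
    values: np.ndarray  # in [0, 1]
    n_participants: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9):
            raise ValueError("salience values must lie in [0, 1]")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.grid_step

    @property
    def duration(self) -> float:
        return len(self.values) * self.grid_step


@dataclass
class QCReport:
    """Outcome of the switching-rate quality control."""

    rates: dict  # (participant_id, scene_id) -> switches/s
    lo_threshold: float
    hi_threshold: float
    abnormal_trials: dict  # participant_id -> number of abnormal trials
    excluded: list  # participant ids removed
    max_abnormal: int = 5

    def surviving(self, trials: list[TrialResponse]) -> list[TrialResponse]:
        """Return the trials whose participant was not excluded."""
        bad = set(self.excluded)
        return [t for t in trials if t.participant_id not in bad]


def switching_rate(trial: TrialResponse) -> float:
    """Number of 0<->1 attention switches per second of trial duration."""
    if len(trial.trace) == 0 or trial.duration <= 0:
        raise ValueError("cannot compute switching rate of an empty trace")
    n_switch = int(np.count_nonzero(np.diff(trial.trace.astype(np.int8))))
    return n_switch / trial.duration


def quality_control(
    trials: list[TrialResponse],
    hi_pct: float = 90.0,
    lo_pct: float = 10.0,
    max_abnormal: int = 5,
) -> QCReport:
    """Flag abnormal trials by switching rate and exclude outlier participants.

    Percentile thresholds are computed over the switching rates of *all*
    trials; a trial is abnormal when its rate falls strictly outside the open
    interval (lo, hi).  Participants with more than ``max_abnormal`` abnormal
    trials are excluded.  With a degenerate all-equal rate distribution the
    open bounds exclude no one.
    """
    if len(trials) < 2:
        raise ValueError("quality control needs at least two trials")
    rates = {(t.participant_id, t.scene_id): switching_rate(t) for t in trials}
    all_rates = np.array(list(rates.values()))
    lo = float(np.percentile(all_rates, lo_pct))
    hi = float(np.percentile(all_rates, hi_pct))
    abnormal: dict[str, int] = {}
    for (pid, _), r in rates.items():
        if r > hi or r < lo:
            abnormal[pid] = abnormal.get(pid, 0) + 1
    excluded = sorted(p for p, n in abnormal.items() if n > max_abnormal)
    return QCReport(rates, lo, hi, abnormal, excluded, max_abnormal)


def _shift_earlier(trace: np.ndarray, n: int) -> np.ndarray:
    """Shift a trace earlier by ``n`` samples, edge-replicating the tail."""
    if n <= 0:
        return trace
    out = np.empty_like(trace)
    out[: len(trace) - n] = trace[n:]
    out[len(trace) - n :] = trace[-1]
    return out


def _resample_zoh(trace: np.ndarray, dt: float, grid_step: float, n_out: int) -> np.ndarray:
    """Zero-order-hold resampling onto the analysis grid."""
    idx = np.floor(np.arange(n_out) * grid_step / dt).astype(int)
    idx = np.clip(idx, 0, len(trace) - 1)
    return trace[idx]


def smooth_map(values: np.ndarray, grid_step: float, smooth_len: float, passes: int) -> np.ndarray:
    """Apply ``passes`` centered moving-average windows of ``smooth_len`` seconds.

    Window length is rounded to the nearest odd sample count so the filter is
    exactly centered; edges are handled by replication.
    """
    win = max(1, int(round(smooth_len / grid_step)))
    if win % 2 == 0:
        win += 1
    out = values.astype(float)
    for _ in range(passes):
        out = uniform_filter1d(out, size=win, mode="nearest")
    return out


def average_behavioral_salience(
    trials: list[TrialResponse],
    rt_shift: float = 1.0,
    smooth_len: float = 1.5,
    smooth_passes: int = 3,
    grid_step: float = GRID_STEP,
) -> SalienceMap:
    """Average participants' traces into a smoothed behavioral salience map.

    Each trace is shifted earlier by ``rt_shift`` seconds (the average
    reaction-time delay), resampled to the analysis grid by zero-order hold,
    averaged across participants, and box-smoothed ``smooth_passes`` times
    with a ``smooth_len``-second window.
    """
    if not trials:
        raise ValueError("need at least one surviving trial")
    scene_ids = {t.scene_id for t in trials}
    directions = {t.direction for t in trials}
    if len(scene_ids) > 1 or len(directions) > 1:
        raise ValueError(f"mixed scenes/directions: {scene_ids} / {directions}")
    duration = min(t.duration for t in trials)
    n_out = int(round(duration / grid_step))
    acc = np.zeros(n_out)
    for t in sorted(trials, key=lambda tr: tr.participant_id):
        shifted = _shift_earlier(t.trace.astype(float), int(round(rt_shift / t.dt)))
        acc += _resample_zoh(shifted, t.dt, grid_step, n_out)
    avg = acc / len(trials)
    smoothed = smooth_map(avg, grid_step, smooth_len, smooth_passes)
    return SalienceMap(scene_ids.pop(), directions.pop(), grid_step, np.clip(smoothed, 0.0, 1.0), len(trials))


def individual_reaction_times(
    trials_by_participant: dict[str, list[TrialResponse]],
    events_by_scene: dict[str, list],
    window: float = 1.0,
    rt_shift: float = 1.0,
) -> dict[str, dict]:
    """Per-participant mean reaction time relative to salient-event onsets.

    Onsets live on the already reaction-time-shifted salience timeline, so
    each trace is shifted by the same ``rt_shift`` before comparison.  For
    each (participant, event) the reaction time is the first switch *toward*
    the scene within ``[onset - window, onset + window]``, minus the onset;
    events with no switch in the window are counted as non-responsive.
    """
    out: dict[str, dict] = {}
    for pid, trials in trials_by_participant.items():
        rts: list[float] = []
        n_events = 0
        for trial in trials:
            events = events_by_scene.get(trial.scene_id, [])
            shifted = _shift_earlier(trial.trace.astype(np.int8), int(round(rt_shift / trial.dt)))
            switch_idx = np.flatnonzero(np.diff(shifted) == 1) + 1
            switch_t = switch_idx * trial.dt
            for ev in events:
                n_events += 1
                onset = ev.onset if hasattr(ev, "onset") else float(ev)
                in_win = switch_t[(switch_t >= onset - window) & (switch_t <= onset + window)]
                if in_win.size:
                    rts.append(float(in_win[0] - onset))
        out[pid] = {
            "mean_rt": float(np.mean(rts)) if rts else np.nan,
            "n_responsive": len(rts),
            "n_events": n_events,
            "responsive": bool(rts),
        }
    return out


def fwd_bwd_agreement(fwd_map: SalienceMap, bwd_map: SalienceMap) -> tuple[float, float]:
    """Spearman correlation between a fwd map and the time-reversed bwd map."""
    if fwd_map.scene_id != bwd_map.scene_id:
        raise ValueError("maps are for different scenes")
    rev = bwd_map.values[::-1]
    n = min(len(fwd_map.values), len(rev))
    if abs(len(fwd_map.values) - len(rev)) > 1:
        raise ValueError("map lengths differ by more than one grid step")
    rho, p = stats.spearmanr(fwd_map.values[:n], rev[:n])
    return float(rho), float(p)


def noise_floor(
    fwd_maps: dict[str, SalienceMap],
    bwd_maps: dict[str, SalienceMap],
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """Noise floor for fwd/bwd agreement from shuffled scene pairings.

    Each permutation pairs every fwd scene with a *different* scene's bwd map
    (a derangement) and records the Spearman correlation.  Zero-variance maps
    make the correlation undefined; such pairs are excluded and counted.
    """
    scenes = sorted(set(fwd_maps) & set(bwd_maps))
    if len(scenes) < 2:
        raise ValueError("noise floor requires at least two scenes")
    rng = np.random.default_rng(seed)
    rhos: list[float] = []
    n_excluded = 0
    for _ in range(n_perm):
        while True:  # rejection-sample a derangement
            perm = rng.permutation(len(scenes))
            if not np.any(perm == np.arange(len(scenes))):
                break
        for i, j in enumerate(perm):
            f, b = fwd_maps[scenes[i]], bwd_maps[scenes[j]]
            rev = b.values[::-1]
            n = min(len(f.values), len(rev))
            x, y = f.values[:n], rev[:n]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                n_excluded += 1
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho, _ = stats.spearmanr(x, y)
            rhos.append(float(rho))
    return {
        "mean": float(np.mean(rhos)) if rhos else np.nan,
        "std": float(np.std(rhos)) if rhos else np.nan,
        "n_pairs": len(rhos),
        "n_excluded": n_excluded,
    }
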