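"""File formats: WAV scenes, CSV trial logs, salience maps, and event tables.

Conventions: WAV is 16-bit PCM; CSV is UTF-8, comma-separated, '.' decimal,
header row mandatory; event times are written with 3-decimal precision;
ground truth travels as a JSON sidecar next to each synthetic artifact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .behavioral import TrialResponse, SalienceMap
from .events import SalientEvent, MatchResult

__all__ = [
    "write_wav",
    "read_wav",
    "write_trial_log",
    "read_trial_log",
    "validate_trial_log",
    "write_salience_map",
    "read_salience_map",
    "write_events",
    "read_events",
    "write_matches",
]

TRIAL_COLUMNS = ["participant_id", "scene_id", "direction", "opposing_scene_id", "t", "attending"]


def write_wav(path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write a float waveform as 16-bit PCM, clipping to [-1, 1]."""
    x = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(sample_rate), (x * 32767).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, int]:
    sr, data = wavfile.read(path)
    if data.ndim > 1:
        raise ValueError(f"{path}: stereo WAV; mix down or split before analysis")
    if data.dtype == np.int16:
        data = data.astype(float) / 32767.0
    else:
        data = data.astype(float)
    return data, int(sr)


def write_trial_log(path, trials: list[TrialResponse]) -> None:
    frames = []
    for tr in trials:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": tr.participant_id,
                    "scene_id": tr.scene_id,
                    "direction": tr.direction,
                    "opposing_scene_id": tr.opposing_scene_id,
                    "t": np.round(np.arange(len(tr.trace)) * tr.dt, 6),
                    "attending": tr.trace.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trial_log(path) -> list[TrialResponse]:
    df = pd.read_csv(path)
    trials = []
    for (pid, sid, direction, opp), sub in df.groupby(
        ["participant_id", "scene_id", "direction", "opposing_scene_id"], sort=True
    ):
        sub = sub.sort_values("t")
        t = sub["t"].to_numpy()
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.05
        trials.append(
            TrialResponse(str(pid), str(sid), str(direction), str(opp),
                          sub["attending"].to_numpy().astype(np.int8), dt)
        )
    return trials


def validate_trial_log(path) -> dict:
    """Schema and sanity report for a trial-log CSV; errors carry row numbers."""
    df = pd.read_csv(path)
    errors: list[str] = []
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        errors.append(f"missing columns: {missing}")
        return {"valid": False, "errors": errors, "n_rows": len(df)}
    bad = df.index[~df["attending"].isin((0, 1))]
    errors.extend(f"row {i}: non-binary attending value {df.loc[i, 'attending']!r}" for i in bad[:20])
    duplicates = []
    for (pid, sid), sub in df.groupby(["participant_id", "scene_id"]):
        t = sub["t"].to_numpy()
        if np.any(np.diff(t) < 0):
            errors.append(f"participant {pid} scene {sid}: time column not monotone")
        if sub["t"].duplicated().any():
            duplicates.append((pid, sid))
    return {
        "valid": not errors,
        "errors": errors,
        "duplicate_trials": duplicates,
        "n_rows": int(len(df)),
        "n_participants": int(df["participant_id"].nunique()),
        "n_scenes": int(df["scene_id"].nunique()),
    }


def write_salience_map(path, m: SalienceMap) -> None:
    pd.DataFrame(
        {
            "scene_id": m.scene_id,
            "direction": m.direction,
            "t": np.round(m.times, 6),
            "value": m.values,
        }
    ).to_csv(path, index=False)


def read_salience_map(path) -> SalienceMap:
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    step = float(np.median(np.diff(t)))
    return SalienceMap(str(df["scene_id"].iloc[0]), str(df["direction"].iloc[0]),
                       step, df["value"].to_numpy(), 0)


def write_events(path, events: list[SalientEvent]) -> None:
    pd.DataFrame(
        [
            {
                "scene_id": e.scene_id,
                "direction": e.direction,
                "onset": round(e.onset, 3),
                "offset": round(e.offset, 3),
                "slope": e.slope,
                "consensus": e.consensus,
                "strength": e.strength,
                "duration": round(e.duration, 3),
                "closed_at_end": e.closed_at_end,
            }
            for e in events
        ]
    ).to_csv(path, index=False)


def read_events(path) -> list[SalientEvent]:
    df = pd.read_csv(path)
    return [
        SalientEvent(
            str(r.scene_id), str(r.direction), float(r.onset), float(r.offset),
            float(r.slope), float(r.consensus), float(r.strength),
            bool(r.closed_at_end),
        )
        for r in df.itertuples()
    ]


def write_matches(path, matches: list[MatchResult]) -> None:
    pd.DataFrame(
        [
            {
                "scene_id": m.event.scene_id,
                "direction": m.event.direction,
                "onset": round(m.event.onset, 3),
                "offset": round(m.event.offset, 3),
                "best_overlap": round(m.best_overlap, 3),
                "overlap_score": m.overlap_score,
                "label": m.label,
            }
            for m in matches
        ]
    ).to_csv(path, index=False)
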