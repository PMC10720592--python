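"""Experiment configuration: every analysis constant in one place.

Defaults are the study's stated analysis constants: 1 s reaction-time shift,
three 1.5 s smoothing passes, 90/10 switching-rate percentiles with a
five-abnormal-trial cutoff, 50% strict matching overlap, a 64 ms grid,
8 s / 4 s evaluation segments, 0.5 s and 4 s context caps, a 4 s surprisal
past window, and 1 s detection segments with 3 s A-S context trained with
batch 200 / learning rate 0.01 / 100 epochs.  Problem-size fields (scene
count, duration, cohort size) control the synthetic demonstration corpus.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["ExperimentConfig"]


@dataclass
class ExperimentConfig:
    # analysis grid and behavioral pipeline
    grid_step: float = 0.064
    rt_shift: float = 1.0
    smooth_len: float = 1.5
    smooth_passes: int = 3
    qc_hi_pct: float = 90.0
    qc_lo_pct: float = 10.0
    qc_max_abnormal: int = 5
    match_threshold: float = 0.5
    # regression
    a_only_cap: float = 0.5
    context_cap: float = 4.0
    lam_a: float = 1.0
    lam_s: float = 1.0
    seg_len: float = 8.0
    seg_hop: float = 4.0
    seg_edge: float = 1.0
    # semantic
    surprisal_past: float = 4.0
    embedding_provider: str = "synthetic"  # "synthetic" | "none"
    n_layers: int = 6
    layer_dim: int = 8
    # detection
    det_seg_len: float = 1.0
    det_context: float = 3.0
    det_batch: int = 200
    det_lr: float = 0.01
    det_epochs: int = 100
    # synthetic corpus size (demonstration scale)
    n_scenes: int = 4
    scene_duration: float = 60.0
    n_participants: int = 60
    events_per_scene: int = 5
    consensus: float = 0.45
    rt_median: float = 0.9
    rt_spread: float = 0.15
    lapse_rate: float = 0.005
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
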