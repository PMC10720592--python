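"""Synthetic scenes, behavioral cohorts, and embedding streams with known truth.

Every downstream stage of the pipeline is exercised against data generated
here, where the planted structure (event onsets, response consensus, semantic
change points, generating linear filters) is known exactly and stored in a
:class:`GroundTruth` sidecar.  The generator emulates the study conditions of
a dichotic-listening salience experiment: 2-minute scenes with discrete
acoustic events over a noise background, cohorts of ~100 participants with
~0.45 consensus per event and ~0.9 s median reaction times, and deep-network
embedding streams that are stationary except at planted change points.

The cohort model is deliberately minimal: a participant responds to a planted
event with probability equal to the configured consensus; responders switch
toward the scene after an individual reaction time drawn from a shifted
log-normal (median/spread parameterization) and stay for a hold period;
spurious "lapse" switches arrive as a Poisson process.  No richer attention
dynamics are modeled — only what the analysis pipeline assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .behavioral import TrialResponse, SalienceMap, GRID_STEP
from .semantic import EmbeddingStream, PosteriorTable, ROOT_CLASSES

__all__ = [
    "PlantedEvent",
    "SceneSpec",
    "ResponseSpec",
    "GroundTruth",
    "make_scene",
    "normalize_scene",
    "make_response_set",
    "make_embedding_stream",
    "make_linear_ground_truth",
    "make_posterior_table",
    "SyntheticEmbeddingProvider",
]

EVENT_KINDS = ("tone", "am-tone", "noise-burst", "ripple")

#: Reference RMS level of the loudest 1% of frames after normalization.
TARGET_RMS = 0.1


@dataclass
class PlantedEvent:
    onset: float  # s
    duration: float  # s
    kind: str = "tone"
    level_step: float = 20.0  # dB above background RMS
    carrier: float = 1000.0  # Hz
    mod_rate: float = 8.0  # Hz (AM rate or ripple drift rate)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}")


@dataclass
class SceneSpec:
    scene_id: str
    duration: float = 120.0  # s
    sample_rate: int = 22050
    noise_level_db: float = -30.0  # background RMS in dBFS; -inf for silence
    spectral_tilt: float = -3.0  # dB/octave of the background spectrum
    planted_events: list[PlantedEvent] = field(default_factory=list)

    def validate(self) -> None:
        if self.duration <= 10:
            raise ValueError("scene duration must exceed 10 s")
        onsets = [e.onset for e in self.planted_events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("planted onsets must be strictly increasing")
        for e in self.planted_events:
            if e.onset < 0 or e.onset + e.duration > self.duration:
                raise ValueError(f"event at {e.onset}s falls outside [0, {self.duration}]s")
        by_kind: dict[str, list[PlantedEvent]] = {}
        for e in self.planted_events:
            by_kind.setdefault(e.kind, []).append(e)
        for kind, evs in by_kind.items():
            for a, b in zip(evs, evs[1:]):
                if b.onset < a.onset + a.duration:
                    raise ValueError(
                        f"overlapping {kind!r} events at {a.onset}s and {b.onset}s; "
                        "same-kind events must not overlap"
                    )


@dataclass
class ResponseSpec:
    """Cohort parameters for a synthetic dichotic-listening response set."""

    n_participants: int = 100
    consensus: float | list = 0.45  # fraction responding, scalar or per event
    rt_median: float = 0.9  # s
    rt_spread: float = 0.15  # s (std-like multiplicative spread)
    lapse_rate: float = 0.0  # spurious switches per second
    hold_duration: float = 3.0  # s a responder keeps attending after a switch
    seed: int = 0

    def consensus_for(self, n_events: int) -> np.ndarray:
        c = np.broadcast_to(np.asarray(self.consensus, dtype=float), (n_events,))
        if np.any((c < 0) | (c > 1)):
            raise ValueError("consensus must lie in [0, 1]")
        return c


@dataclass
class GroundTruth:
    """Planted structure stored alongside every synthetic output."""

    planted_onsets: list = field(default_factory=list)
    planted_offsets: list = field(default_factory=list)
    planted_kinds: list = field(default_factory=list)
    planted_filter: np.ndarray | None = None  # (n_features, n_lags)
    bias: float = 0.0
    noise_sigma: float = 0.0
    change_points: list = field(default_factory=list)
    rescale: tuple | None = None  # (offset, scale) applied to the linear target

    def to_json(self, path) -> None:
        d = asdict(self)
        if self.planted_filter is not None:
            d["planted_filter"] = np.asarray(self.planted_filter).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("planted_filter") is not None:
            d["planted_filter"] = np.asarray(d["planted_filter"], dtype=float)
        if d.get("rescale") is not None:
            d["rescale"] = tuple(d["rescale"])
        return cls(**d)


def _ramped(env_len: int, sr: int, ramp: float = 0.01) -> np.ndarray:
    """Unit envelope with raised-cosine on/off ramps."""
    n_ramp = min(int(ramp * sr), env_len // 2)
    env = np.ones(env_len)
    if n_ramp > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = r
        env[-n_ramp:] = r[::-1]
    return env


def _event_samples(e: PlantedEvent, sr: int, amp_rms: float, rng: np.random.Generator) -> np.ndarray:
    n = int(round(e.duration * sr))
    t = np.arange(n) / sr
    if e.kind == "tone":
        x = np.sin(2 * np.pi * e.carrier * t)
    elif e.kind == "am-tone":
        x = np.sin(2 * np.pi * e.carrier * t) * (1 + 0.9 * np.sin(2 * np.pi * e.mod_rate * t))
    elif e.kind == "noise-burst":
        x = rng.standard_normal(n)
    else:  # ripple: moving spectrotemporal grating over log-spaced components
        comps = np.geomspace(e.carrier / 4, min(e.carrier * 8, sr / 2.5), 48)
        phases = rng.uniform(0, 2 * np.pi, len(comps))
        x = np.zeros(n)
        for f, ph in zip(comps, phases):
            a = 1 + 0.9 * np.sin(2 * np.pi * (e.mod_rate * t + np.log2(f / e.carrier)))
            x += a * np.sin(2 * np.pi * f * t + ph)
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x *= amp_rms / rms
    return x * _ramped(n, sr)


def _tilted_noise(n: int, sr: int, tilt_db_per_oct: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a power-law spectral tilt (dB per octave re 1 kHz)."""
    white = rng.standard_normal(n)
    if tilt_db_per_oct == 0:
        gain = white
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, 1 / sr)
        w = np.ones_like(f)
        nz = f > 0
        w[nz] = 10 ** (tilt_db_per_oct * np.log2(f[nz] / 1000.0) / 20.0)
        w[0] = 0.0
        gain = np.fft.irfft(spec * w, n)
    cur = np.sqrt(np.mean(gain**2))
    return gain * (rms / cur) if cur > 0 else gain


def normalize_scene(
    waveform: np.ndarray,
    sample_rate: int,
    frame_len: float = 0.05,
    top_fraction: float = 0.01,
    target_rms: float = TARGET_RMS,
) -> np.ndarray:
    """Scale a scene so the RMS of its loudest 1% of frames hits ``target_rms``.

    Frame energies are measured over non-overlapping ``frame_len`` windows.
    The operation is idempotent and leaves silence untouched.
    """
    n = int(round(frame_len * sample_rate))
    n_frames = len(waveform) // n
    if n_frames == 0:
        raise ValueError("scene shorter than one normalization frame")
    frames = waveform[: n_frames * n].reshape(n_frames, n)
    energies = np.mean(frames**2, axis=1)
    k = max(1, int(np.ceil(top_fraction * n_frames)))
    top = np.sort(energies)[-k:]
    cur = np.sqrt(np.mean(top))
    if cur == 0:
        return waveform.copy()
    return waveform * (target_rms / cur)


def make_scene(spec: SceneSpec, seed: int = 0) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize a scene waveform with planted events and record the truth.

    The background is spectrally tilted Gaussian noise at the configured
    level; each planted event adds a tone, AM tone, noise burst, or moving
    ripple at ``level_step`` dB above the background RMS.  The final waveform
    is normalized so the RMS of its loudest 1% of 50 ms frames equals the
    reference level.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    sr = spec.sample_rate
    n = int(round(spec.duration * sr))
    if np.isneginf(spec.noise_level_db):
        w = np.zeros(n)
        bg_rms = 0.01  # reference level for events over silence
    else:
        bg_rms = 10 ** (spec.noise_level_db / 20)
        w = _tilted_noise(n, sr, spec.spectral_tilt, bg_rms, rng)
    for e in spec.planted_events:
        amp = bg_rms * 10 ** (e.level_step / 20)
        i0 = int(round(e.onset * sr))
        x = _event_samples(e, sr, amp, rng)
        w[i0 : i0 + len(x)] += x
    if np.any(w != 0):
        w = normalize_scene(w, sr)
    truth = GroundTruth(
        planted_onsets=[e.onset for e in spec.planted_events],
        planted_offsets=[e.onset + e.duration for e in spec.planted_events],
        planted_kinds=[e.kind for e in spec.planted_events],
    )
    return w, truth


def make_response_set(
    truth: GroundTruth,
    spec: ResponseSpec,
    trial_duration: float,
    scene_id: str = "scene",
    direction: str = "fwd",
    opposing_scene_id: str = "other",
    dt: float = 0.05,
) -> list[TrialResponse]:
    """Simulate a cohort of binary attention traces toward one scene.

    Each participant responds to planted event ``i`` with probability
    ``consensus[i]``; responders switch toward the scene at
    ``onset + rt`` with rt drawn from a shifted log-normal of median
    ``rt_median`` and multiplicative spread set by ``rt_spread``, then hold
    attention for ``hold_duration``.  Lapse switches arrive as a Poisson
    process with rate ``lapse_rate`` per second.  Traces are sampled at a
    cursor-like 20 Hz (``dt`` = 0.05 s).
    """
    if spec.n_participants <= 0:
        raise ValueError("n_participants must be positive")
    onsets = np.asarray(truth.planted_onsets, dtype=float)
    if np.any(onsets >= trial_duration):
        raise ValueError("planted onsets must fall within the trial duration")
    cons = spec.consensus_for(len(onsets))
    rng = np.random.default_rng(spec.seed)
    sigma = spec.rt_spread / spec.rt_median if spec.rt_median > 0 else 0.0
    n_samp = int(round(trial_duration / dt))
    trials = []
    for p in range(spec.n_participants):
        trace = np.zeros(n_samp, dtype=np.int8)
        for onset, c in zip(onsets, cons):
            if rng.random() >= c:
                continue
            rt = spec.rt_median * np.exp(sigma * rng.standard_normal()) if sigma > 0 else spec.rt_median
            t0 = onset + rt
            i0 = int(round(t0 / dt))
            i1 = int(round((t0 + spec.hold_duration) / dt))
            trace[max(i0, 0) : min(i1, n_samp)] = 1
        if spec.lapse_rate > 0:
            n_lapse = rng.poisson(spec.lapse_rate * trial_duration)
            for t0 in rng.uniform(0, trial_duration, n_lapse):
                dur = rng.exponential(0.5)
                i0 = int(round(t0 / dt))
                i1 = int(round((t0 + dur) / dt))
                trace[max(i0, 0) : min(i1, n_samp)] = 1
        trials.append(
            TrialResponse(f"p{p:04d}", scene_id, direction, opposing_scene_id, trace, dt)
        )
    return trials


def make_embedding_stream(
    T: int,
    layers: int,
    dims: int | list,
    change_points: list,
    step_norm: float,
    seed: int = 0,
    frame_step: float = GRID_STEP,
    noise_sigma: float = 1.0,
    scene_id: str = "scene",
) -> EmbeddingStream:
    """Stationary noise embeddings with planted mean shifts at change points.

    At each change point the per-layer mean shifts by a random direction of
    Euclidean norm ``step_norm`` (shifts accumulate).  With ``noise_sigma``
    = 0 the surprisal at a change point equals ``step_norm`` exactly.
    """
    dims_list = [dims] * layers if np.isscalar(dims) else list(dims)
    if len(dims_list) != layers:
        raise ValueError("dims list length must equal the layer count")
    if any(d <= 0 for d in dims_list):
        raise ValueError("layer dimensions must be positive")
    cps = sorted(float(c) for c in change_points)
    if any(c < 0 or c >= T * frame_step for c in cps):
        raise ValueError("change points must lie inside the stream")
    rng = np.random.default_rng(seed)
    out = []
    for K in dims_list:
        mean = np.zeros((T, K))
        for cp in cps:
            direction = rng.standard_normal(K)
            direction *= step_norm / np.linalg.norm(direction)
            mean[int(round(cp / frame_step)) :] += direction
        noise = noise_sigma * rng.standard_normal((T, K)) if noise_sigma > 0 else 0.0
        out.append(mean + noise)
    return EmbeddingStream(scene_id, out, frame_step)


def make_linear_ground_truth(
    features,
    filt: np.ndarray,
    noise_sigma: float,
    seed: int = 0,
    bias: float = 0.5,
    scene_id: str | None = None,
    grid_step: float | None = None,
) -> tuple[SalienceMap, GroundTruth]:
    """Salience target generated by a known causal linear filter on features.

    target_t = sum_f sum_tau filt[f, tau] * x[t - tau, f] + bias + noise,
    affinely rescaled into [0, 1] (rescale recorded in the truth, so the
    linear model stays exactly recoverable).  ``features`` may be a
    FeatureMatrix-like object (with .values/.scene_id/.frame_step) or a plain
    (T, F) array.
    """
    if hasattr(features, "values") and not isinstance(features, np.ndarray):
        X = np.asarray(features.values, dtype=float)
        scene_id = scene_id or getattr(features, "scene_id", "scene")
        grid_step = grid_step or getattr(features, "frame_step", GRID_STEP)
    else:
        X = np.asarray(features, dtype=float)
        scene_id = scene_id or "scene"
        grid_step = grid_step or GRID_STEP
    filt = np.atleast_2d(np.asarray(filt, dtype=float))
    T, F = X.shape
    if filt.shape[0] != F:
        raise ValueError(f"filter has {filt.shape[0]} feature rows, features have {F}")
    if filt.shape[1] > T:
        raise ValueError("filter lag span exceeds the feature duration")
    r = np.full(T, float(bias))
    for f in range(F):
        r += np.convolve(X[:, f], filt[f])[:T]
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        r = r + noise_sigma * rng.standard_normal(T)
    lo, hi = float(r.min()), float(r.max())
    if hi > lo:
        offset, scale = lo, hi - lo
        y = (r - offset) / scale
    else:
        offset, scale = 0.0, 1.0
        y = np.clip(r, 0.0, 1.0)
    truth = GroundTruth(
        planted_filter=filt,
        bias=float(bias),
        noise_sigma=float(noise_sigma),
        rescale=(offset, scale),
    )
    return SalienceMap(scene_id, "fwd", grid_step, y, 0), truth


def make_posterior_table(
    T: int,
    switch_times: list,
    seed: int = 0,
    frame_step: float = GRID_STEP,
    leaves_per_root: int = 4,
    active_level: float = 0.9,
    noise: float = 0.02,
    scene_id: str = "scene",
) -> PosteriorTable:
    """Synthetic leaf-class posteriors with planted class switches.

    One leaf is active (posterior ~``active_level``) at a time; at each switch
    time the active leaf jumps to a leaf of the next ontology root, so the
    class distribution changes sharply at the planted moments.
    """
    rng = np.random.default_rng(seed)
    leaves, root_map = [], {}
    for r in ROOT_CLASSES:
        for i in range(leaves_per_root):
            leaf = f"{r.lower()}_{i}"
            leaves.append(leaf)
            root_map[leaf] = r
    vals = np.clip(rng.uniform(0, noise, (T, len(leaves))), 0, 1)
    bounds = [0] + [int(round(s / frame_step)) for s in sorted(switch_times)] + [T]
    for seg, (i0, i1) in enumerate(zip(bounds, bounds[1:])):
        root_idx = seg % len(ROOT_CLASSES)
        leaf_idx = root_idx * leaves_per_root + (seg // len(ROOT_CLASSES)) % leaves_per_root
        vals[i0:i1, leaf_idx] = active_level
    return PosteriorTable(scene_id, leaves, np.clip(vals, 0, 1), frame_step, root_map)


class SyntheticEmbeddingProvider:
    """Embedding provider planting change points at configured times.

    Satisfies the :class:`~audisal.semantic.EmbeddingProvider` contract
    without any neural network: it ignores the waveform content and returns a
    seeded synthetic stream whose change points are supplied at construction
    (typically the planted event onsets of the matching synthetic scene).
    """

    def __init__(
        self,
        change_points: list,
        layers: int = 18,
        dims: int = 16,
        step_norm: float = 4.0,
        noise_sigma: float = 1.0,
        frame_step: float = GRID_STEP,
        seed: int = 0,
    ):
        self.change_points = list(change_points)
        self.layers, self.dims = layers, dims
        self.step_norm, self.noise_sigma = step_norm, noise_sigma
        self.frame_step, self.seed = frame_step, seed

    def embed(self, waveform: np.ndarray, sample_rate: float) -> EmbeddingStream:
        T = int(len(waveform) / sample_rate / self.frame_step)
        return make_embedding_stream(
            T,
            self.layers,
            self.dims,
            self.change_points,
            self.step_norm,
            seed=self.seed,
            frame_step=self.frame_step,
            noise_sigma=self.noise_sigma,
        )
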