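"""End-to-end synthetic experiment: simulate, analyze, model, detect.

`run_pipeline` materializes a complete artifact directory from a single
:class:`~audisal.config.ExperimentConfig`: synthetic scenes (WAV + ground
truth), fwd/bwd trial logs, quality control, salience maps, salient events
with fwd/bwd matching, acoustic features, semantic surprisals, the four
ridge model variants with segment-wise evaluation, and the onset-detection
models with ROC curves.  Every stage draws its randomness from a named
child of one seeded generator hierarchy, so a fixed config yields
byte-identical outputs; a provenance log records the config hash, seeds and
library versions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavioral, detection, events as ev, features as feat, io as aio, regression as reg, synth
from .config import ExperimentConfig
from .semantic import layer_surprisal
from .synth import SyntheticEmbeddingProvider

__all__ = ["run_pipeline", "scene_specs", "simulate_corpus", "load_scene_data"]

_KINDS = ("tone", "am-tone", "noise-burst", "ripple")


def _stage_seed(cfg: ExperimentConfig, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2**31 from the root seed."""
    ss = np.random.SeedSequence([cfg.seed, hash(stage) % (2**31), index])
    return int(ss.generate_state(1)[0] % (2**31))


def scene_specs(cfg: ExperimentConfig) -> list[synth.SceneSpec]:
    """Deterministic scene layouts: jittered event onsets, cycling kinds."""
    specs = []
    for i in range(cfg.n_scenes):
        rng = np.random.default_rng(_stage_seed(cfg, "scenes", i))
        n_ev = cfg.events_per_scene
        usable = cfg.scene_duration - 10.0
        base = 5.0 + usable * np.arange(n_ev) / n_ev
        onsets = np.sort(base + rng.uniform(0, usable / (2 * n_ev), n_ev))
        events = [
            synth.PlantedEvent(
                onset=float(t),
                duration=2.0,
                kind=_KINDS[k % len(_KINDS)],
                level_step=15.0,
                carrier=float(rng.uniform(300, 2000)),
                mod_rate=float(rng.choice([4.0, 8.0, 40.0])),
            )
            for k, t in enumerate(onsets)
        ]
        specs.append(
            synth.SceneSpec(scene_id=f"scene{i:02d}", duration=cfg.scene_duration, planted_events=events)
        )
    return specs


def simulate_corpus(cfg: ExperimentConfig):
    """Scenes, ground truths and fwd/bwd trial logs for the whole corpus."""
    specs = scene_specs(cfg)
    scenes, trials_fwd, trials_bwd = {}, {}, {}
    for i, spec in enumerate(specs):
        w, truth = synth.make_scene(spec, seed=_stage_seed(cfg, "audio", i))
        rspec = synth.ResponseSpec(
            n_participants=cfg.n_participants,
            consensus=cfg.consensus,
            rt_median=cfg.rt_median,
            rt_spread=cfg.rt_spread,
            lapse_rate=cfg.lapse_rate,
            seed=_stage_seed(cfg, "responses-fwd", i),
        )
        trials_fwd[spec.scene_id] = synth.make_response_set(
            truth, rspec, spec.duration, spec.scene_id, "fwd"
        )
        # the bwd experiment presents the time-reversed scene: events land at
        # duration - offset on the played (reversed) time axis
        truth_bwd = synth.GroundTruth(
            planted_onsets=sorted(spec.duration - o for o in truth.planted_offsets),
            planted_offsets=sorted(spec.duration - o for o in truth.planted_onsets),
            planted_kinds=list(reversed(truth.planted_kinds)),
        )
        # every third event is context-dependent: reversal curtails the cues
        # that made it salient, so its bwd consensus collapses and the fwd
        # event ends up mismatched
        n_ev = len(truth.planted_onsets)
        bwd_cons = np.full(n_ev, cfg.consensus)
        bwd_cons[::3] = 0.0
        rspec_b = dataclasses.replace(
            rspec,
            consensus=bwd_cons[::-1].tolist(),  # align with the reversed onset order
            seed=_stage_seed(cfg, "responses-bwd", i),
        )
        trials_bwd[spec.scene_id] = synth.make_response_set(
            truth_bwd, rspec_b, spec.duration, spec.scene_id, "bwd"
        )
        scenes[spec.scene_id] = (w, truth, truth_bwd, spec)
    return scenes, trials_fwd, trials_bwd


def load_scene_data(artifact_dir, grid_step: float = 0.064) -> list[reg.SceneData]:
    """Rebuild SceneData objects from a pipeline artifact directory.

    Reads per-scene feature/surprisal CSVs, the fwd salience maps and the fwd
    match table, so model fitting and evaluation can be re-run standalone on
    serialized intermediates.
    """
    art = Path(artifact_dir)
    scenes = []
    for fpath in sorted(art.glob("features_*.csv")):
        sid = fpath.stem.removeprefix("features_")
        X = pd.read_csv(fpath).to_numpy()
        y = aio.read_salience_map(art / f"salience_{sid}_fwd.csv").values
        spath = art / f"surprisal_{sid}.csv"
        sur = pd.read_csv(spath).to_numpy() if spath.exists() else None
        T = min(len(X), len(y))
        matched, mismatched = [], []
        mpath = art / "matches_fwd.csv"
        if mpath.exists():
            mdf = pd.read_csv(mpath)
            for r in mdf[mdf.scene_id == sid].itertuples():
                (matched if r.label == "match" else mismatched).append((r.onset, r.offset))
        scenes.append(
            reg.SceneData(sid, X[:T], y[:T], surprisal=sur[:T] if sur is not None else None,
                          grid_step=grid_step, matched=matched, mismatched=mismatched)
        )
    if not scenes:
        raise ValueError(f"no features_*.csv found in {artifact_dir}")
    return scenes


def run_pipeline(cfg: ExperimentConfig, outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    # --- simulation ---
    scenes, trials_fwd, trials_bwd = simulate_corpus(cfg)
    for sid, (w, truth, truth_bwd, spec) in scenes.items():
        aio.write_wav(out / f"{sid}.wav", w, spec.sample_rate)
        truth.to_json(out / f"{sid}_truth.json")
    aio.write_trial_log(out / "trials_fwd.csv", sum(trials_fwd.values(), []))
    aio.write_trial_log(out / "trials_bwd.csv", sum(trials_bwd.values(), []))
    log.append("simulate: ok")

    # --- quality control and salience maps ---
    maps: dict[str, dict[str, behavioral.SalienceMap]] = {"fwd": {}, "bwd": {}}
    qc_out = {}
    for direction, trials_by_scene in (("fwd", trials_fwd), ("bwd", trials_bwd)):
        all_trials = sum(trials_by_scene.values(), [])
        qc = behavioral.quality_control(
            all_trials, cfg.qc_hi_pct, cfg.qc_lo_pct, cfg.qc_max_abnormal
        )
        qc_out[direction] = {
            "lo_threshold": qc.lo_threshold,
            "hi_threshold": qc.hi_threshold,
            "excluded": qc.excluded,
        }
        for sid, trials in trials_by_scene.items():
            kept = qc.surviving(trials)
            maps[direction][sid] = behavioral.average_behavioral_salience(
                kept, cfg.rt_shift, cfg.smooth_len, cfg.smooth_passes, cfg.grid_step
            )
            aio.write_salience_map(out / f"salience_{sid}_{direction}.csv", maps[direction][sid])
    with open(out / "qc.json", "w") as fh:
        json.dump(qc_out, fh, indent=1, sort_keys=True)
    log.append("qc+salience: ok")

    # --- events, matching, agreement ---
    fwd_events, bwd_events_rev = {}, {}
    for sid in scenes:
        fwd_events[sid] = ev.extract_events(maps["fwd"][sid])
        raw_bwd = ev.extract_events(maps["bwd"][sid])
        bwd_events_rev[sid] = ev.reverse_events(raw_bwd, maps["bwd"][sid].duration)
    slopes_fwd = np.array([e.slope for evs in fwd_events.values() for e in evs])
    slopes_bwd = np.array([e.slope for evs in bwd_events_rev.values() for e in evs])
    fwd_events = {s: ev.assign_strengths(e, slopes_fwd) for s, e in fwd_events.items()}
    bwd_events_rev = {s: ev.assign_strengths(e, slopes_bwd) for s, e in bwd_events_rev.items()}
    matches_fwd, matches_bwd = {}, {}
    for sid in scenes:
        matches_fwd[sid] = ev.match_events(fwd_events[sid], bwd_events_rev[sid], cfg.match_threshold)
        matches_bwd[sid] = ev.match_events(bwd_events_rev[sid], fwd_events[sid], cfg.match_threshold)
    aio.write_events(out / "events_fwd.csv", sum(fwd_events.values(), []))
    aio.write_events(out / "events_bwd_reversed.csv", sum(bwd_events_rev.values(), []))
    aio.write_matches(out / "matches_fwd.csv", sum(matches_fwd.values(), []))
    aio.write_matches(out / "matches_bwd.csv", sum(matches_bwd.values(), []))

    groups = {
        "fwd-match": [m.event for ms in matches_fwd.values() for m in ms if m.label == "match"],
        "fwd-mismatch": [m.event for ms in matches_fwd.values() for m in ms if m.label == "mismatch"],
        "bwd-match": [m.event for ms in matches_bwd.values() for m in ms if m.label == "match"],
        "bwd-mismatch": [m.event for ms in matches_bwd.values() for m in ms if m.label == "mismatch"],
    }
    nonempty = {k: v for k, v in groups.items() if v}
    if len(nonempty) >= 2:
        ev.compare_event_groups(nonempty).to_csv(out / "event_group_tests.csv", index=False)
    agreement = {
        sid: behavioral.fwd_bwd_agreement(maps["fwd"][sid], maps["bwd"][sid]) for sid in scenes
    }
    floor = behavioral.noise_floor(maps["fwd"], maps["bwd"], n_perm=20,
                                   seed=_stage_seed(cfg, "noise-floor"))
    with open(out / "agreement.json", "w") as fh:
        json.dump(
            {"per_scene": {s: {"rho": a[0], "p": a[1]} for s, a in agreement.items()},
             "noise_floor": floor},
            fh, indent=1, sort_keys=True,
        )
    log.append("events+matching: ok")

    # --- acoustic features and semantic surprisal ---
    fmats, surps = {}, {}
    for i, (sid, (w, truth, _, spec)) in enumerate(scenes.items()):
        fmats[sid] = feat.featurize(w, spec.sample_rate, scene_id=sid)
        pd.DataFrame(fmats[sid].values, columns=fmats[sid].names).to_csv(
            out / f"features_{sid}.csv", index=False
        )
        if cfg.embedding_provider == "synthetic":
            provider = SyntheticEmbeddingProvider(
                truth.planted_onsets, layers=cfg.n_layers, dims=cfg.layer_dim,
                frame_step=cfg.grid_step, seed=_stage_seed(cfg, "embeddings", i),
            )
            stream = provider.embed(w, spec.sample_rate)
            surp = layer_surprisal(stream, past=cfg.surprisal_past)
            surps[sid] = surp.values
            pd.DataFrame(surp.values, columns=[f"layer{j}" for j in range(cfg.n_layers)]).to_csv(
                out / f"surprisal_{sid}.csv", index=False
            )
    log.append("features+surprisal: ok")

    # --- regression models ---
    scene_data = []
    for sid in scenes:
        X = fmats[sid].values
        y = maps["fwd"][sid].values
        T = min(len(X), len(y))
        sur = surps.get(sid)
        scene_data.append(
            reg.SceneData(
                sid, X[:T], y[:T],
                surprisal=sur[:T] if sur is not None else None,
                grid_step=cfg.grid_step,
                matched=[(m.event.onset, m.event.offset) for m in matches_fwd[sid] if m.label == "match"],
                mismatched=[(m.event.onset, m.event.offset) for m in matches_fwd[sid] if m.label == "mismatch"],
            )
        )
    variant_names = ["A-only", "A-C"]
    if cfg.embedding_provider == "synthetic":
        variant_names += ["A-S", "S"]
    else:
        log.append("regression: no embedding provider, A-S/S skipped")
    # leave-one-scene-out: segments are always scored by a model fitted on
    # the other scenes, honoring the disjoint-evaluation contract
    seg_frames = []
    for name in variant_names:
        parts = []
        for held in scene_data:
            train = [sc for sc in scene_data if sc.scene_id != held.scene_id] or [held]
            if cfg.embedding_provider == "synthetic":
                model = reg.model_variants(train, cfg.lam_a, cfg.lam_s,
                                           cfg.a_only_cap, cfg.context_cap)[name]
            else:
                base = reg.ContextDesign()
                design = (
                    dataclasses.replace(base, ac_past=cfg.a_only_cap, ac_future=cfg.a_only_cap)
                    if name == "A-only"
                    else dataclasses.replace(base, ac_past=cfg.context_cap)
                )
                model = reg.fit_corpus(train, design, cfg.lam_a, cfg.lam_s, True, False)
            parts.append(reg.evaluate_segments(model, [held], cfg.seg_len, cfg.seg_hop, cfg.seg_edge))
        segs = pd.concat(parts, ignore_index=True)
        segs.insert(0, "model", name)
        seg_frames.append(segs)
    pd.concat(seg_frames, ignore_index=True).to_csv(out / "segment_eval.csv", index=False)
    tests = {
        name: reg.segment_group_tests(df.drop(columns="model"))
        for name, df in zip(variant_names, seg_frames)
    }
    with open(out / "segment_tests.json", "w") as fh:
        json.dump(tests, fh, indent=1, sort_keys=True, default=float)
    log.append(f"regression: fitted {sorted(variant_names)} (leave-one-scene-out)")

    # --- event detection ---
    det_rows = []
    ds_a = detection.concat_datasets(
        [
            detection.make_detection_dataset(
                sd.features, None, [e.onset for e in fwd_events[sd.scene_id]],
                sd.scene_id, cfg.grid_step, cfg.det_seg_len,
            )
            for sd in scene_data
        ]
    )
    model_a = detection.fit_detector(ds_a, cfg.det_lr, cfg.det_batch, cfg.det_epochs,
                                     seed=_stage_seed(cfg, "detector-A"))
    roc_a = detection.roc(model_a.scores(ds_a.X), ds_a.labels)
    det_rows.append({"model": "A", "auroc": roc_a.auroc, "n_segments": len(ds_a.labels)})
    if cfg.embedding_provider == "synthetic":
        ds_as = detection.concat_datasets(
            [
                detection.make_detection_dataset(
                    sd.features, sd.surprisal, [e.onset for e in fwd_events[sd.scene_id]],
                    sd.scene_id, cfg.grid_step, cfg.det_seg_len, cfg.det_context,
                )
                for sd in scene_data
            ]
        )
        model_as = detection.fit_detector(ds_as, cfg.det_lr, cfg.det_batch, cfg.det_epochs,
                                          seed=_stage_seed(cfg, "detector-AS"))
        roc_as = detection.roc(model_as.scores(ds_as.X), ds_as.labels)
        det_rows.append({"model": "A-S", "auroc": roc_as.auroc, "n_segments": len(ds_as.labels)})
    else:
        log.append("detection: no embedding provider, A-S skipped")
    # interobserver ceiling on the same segments as the A model
    inter_scores = []
    for sd in scene_data:
        starts = ds_a.starts[np.array(ds_a.scene_ids) == sd.scene_id]
        inter_scores.append(
            detection.interobserver_signal(trials_fwd[sd.scene_id], starts, cfg.det_seg_len, cfg.rt_shift)
        )
    roc_inter = detection.roc(np.concatenate(inter_scores), ds_a.labels)
    det_rows.append({"model": "interobserver", "auroc": roc_inter.auroc, "n_segments": len(ds_a.labels)})
    pd.DataFrame(det_rows).to_csv(out / "detection.csv", index=False)
    log.append("detection: ok")

    # --- provenance ---
    import scipy

    provenance = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__, "pandas": pd.__version__},
        "log": log,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    return out
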