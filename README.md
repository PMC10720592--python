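# audisal — behavioral auditory-salience analysis for dichotic listening

`audisal` is a Python library for analyzing **auditory salience** measured with
the dichotic-listening paradigm: listeners hear a different natural scene in
each ear and continuously report which side holds their attention. Averaging
many listeners' binary attention traces yields a continuous, behaviorally
grounded salience signal per scene — and comparing forward against
time-reversed presentations of the same scene separates events that grab
attention through raw acoustics from those that depend on context and
semantics.

The library is aimed at auditory-psychophysics and computational-audition
researchers who want to run this analysis end to end on their own trial logs
and audio, or to study its statistical behavior on synthetic data with known
ground truth.

## What it computes

**Average behavioral salience.** Each trial trace (1 = attending the scene) is
shifted 1 s earlier to undo the average reaction-time delay, resampled to a
64 ms grid, averaged across participants and smoothed with three 1.5 s moving
averages, giving a map r_t ∈ [0, 1]. Trials are quality-controlled by
switching rate (outside the 10th–90th percentile band = abnormal; more than
five abnormal trials excludes the participant).

**Salient events.** Event onsets are local maxima of the first difference of
r_t; each onset's offset is the next local minimum of that derivative. Events
carry a slope (derivative at onset), absolute consensus (peak r_t inside the
event), duration, and a strength

    strength = slope + consensus × P75(all onset slopes).

Backward-presentation events are reversed onto the forward time axis, and each
event is **matched** when its best normalized interval overlap with a
counterpart event exceeds 50% (strictly), else **mismatched**.

**Acoustic and semantic features.** Sixteen acoustic features (bark-band
loudness, spectral energy/centroid/bandwidth/flatness/irregularity, harmonic
pitch and harmonicity, and rate–scale statistics from a 2-D spectrotemporal
modulation filterbank) are computed on 8 ms frames, pooled to 64 ms and
z-scored per scene. Semantic structure comes from a pluggable embedding
provider: per-layer hidden vectors y_{l,t} are compressed to a **surprisal**
s_{l,t} = ‖y_{l,t} − mean(y over the past 4 s)‖₂.

**Salience prediction.** A block-ridge linear model with temporal context

    r̂_t = W_aᵀ a_t + W_sᵀ s_t + b,   min Σ‖r_t − r̂_t‖² + λ_a‖W_a‖² + λ_s‖W_s‖²

where a_t and s_t stack smoothed features over past/future lags. Four
variants — A-only (≤0.5 s context), A-C (4 s context), A-S (acoustic +
surprisal), S (surprisal only) — are scored by Pearson correlation on 8 s
segments (4 s hop), with segments labeled match/mismatch/no-event.

**Onset detection.** A constrained sigmoid readout of first-differenced
features (one temporal weight vector shared across features) classifies 1 s
segments as containing an event onset, trained by SGD with cross-entropy
(batch 200, lr 0.01, 100 epochs), evaluated by ROC/AUROC against the
interobserver-agreement ceiling and an audio-tagging posterior-change
baseline.

**Synthetic ground truth.** `audisal.synth` generates scenes with planted
events (WAV out), response cohorts with configurable consensus/reaction
times/lapses, embedding streams with planted change points, and linear
salience targets with known generating filters — so every stage above can be
validated by parameter recovery.

## Worked example

`examples/` holds one short script per capability. For instance:

```bash
$ python examples/01_simulate_behavior.py
cohort: 100 participants, median switching rate 0.067/s
QC thresholds (0.033, 0.133)/s -> 0 excluded
  planted event at   8.0 s -> peak salience 0.51
  planted event at  22.0 s -> peak salience 0.41
  planted event at  36.0 s -> peak salience 0.44
  planted event at  50.0 s -> peak salience 0.51
```

The peak salience near each planted event recovers the planted 45% consensus
(within binomial noise): the map literally reads as the fraction of listeners
attending the scene at each moment.

```bash
$ python examples/05_salience_regression.py
held-out scene correlation per model variant:
  A-only  r = 0.011
  A-C     r = 0.985
  A-S     r = 0.979
  S       r = 0.221
```

Here the synthetic target depends on features ~2 s in the past, so the 0.5 s
context model fails while the 4 s context model explains the held-out scene
almost perfectly — the qualitative signature of temporal context in salience.

A full synthetic experiment (scenes → trial logs → QC → maps → events →
matching → features → surprisal → models → detection, with a provenance log)
runs from one config:

```bash
audisal run --seed 0 artifacts/        # or: python -m audisal.cli ...
audisal report artifacts/
```

## Layout

```
src/audisal/     behavioral, events, features, semantic, regression,
                 detection, synth, io, config, pipeline, cli
examples/        one narrative script per capability
tests/           unit, property and acceptance tests
docs/methods.md  modeling and numerical choices, in detail
```
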