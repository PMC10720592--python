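# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions behind `audisal`, in the order the pipeline runs.

## Behavioral salience maps

A trial trace is a binary, uniformly sampled indicator of attending the
analyzed scene. The pipeline assumes traces are already binarized (any
center/neutral cursor zone has been resolved upstream); the trial-log schema
documents this.

- **Reaction-time shift** (`rt_shift`, default 1.0 s): each trace is shifted
  earlier by the average reaction-time delay. The vacated tail is filled by
  edge replication; the alternative (zero fill) would fabricate a switch at
  the scene end.
- **Grid** (`grid_step`, 64 ms): one grid is shared by salience maps,
  acoustic features and surprisals. Raw traces (20 Hz in the simulator — a
  cursor-like rate; the true interface rate is a free parameter) are
  resampled by zero-order hold, which is exact for piecewise-constant binary
  signals.
- **Smoothing** (1.5 s window, 3 passes): centered moving averages with the
  window length rounded to an odd sample count (23 samples at 64 ms) and
  edge replication. Three box passes equal one convolution with a
  twice-convolved box (a quadratic B-spline-like kernel of ~4.4 s support);
  the test suite checks that identity against `np.convolve`.
- **Quality control**: percentile thresholds (linear-interpolation
  percentiles) are computed over all trials' switching rates; a trial is
  abnormal when strictly outside the open (P10, P90) interval, so a
  degenerate all-equal cohort excludes no one. Participants with more than
  five abnormal trials are dropped.
- **Individual reaction times** are reported relative to event onsets on the
  shifted timeline (the timeline events are extracted on). With the
  simulator's 0.9 s median and the 1 s shift, measured values center near
  −0.1 s; a switch exactly at an extracted onset reads 0.

## Salient events

The derivative is the first difference of the smoothed map only (it is not
re-smoothed). Extrema use a strict inequality with plateau handling — the
first sample of a plateau wins — after quantizing the derivative at 1e-9
relative to its peak, so float rounding on an exactly linear ramp cannot
shatter a plateau into spurious extrema.

Onset candidacy uses two floors: an absolute `min_slope` (1e-6 per frame,
numerical ripple) and a relative floor (5% of the map's peak derivative).
The relative floor is what separates collective attention switches from the
shallow ripples left on the averaged map by spurious individual switches: a
cohort lapsing at 0.005/s leaves derivative maxima around 1e-4 — far above
any absolute ripple floor, but well under 5% of a genuine event's slope.
Both floors are parameters.

Events whose onset has no following derivative minimum are closed at scene
end and flagged (`closed_at_end`). Offsets are treated as imprecise by
design; no offset-quality modeling is attempted.

Strength reads "slope plus consensus scaled by the 75th-percentile slope" as
`slope + consensus × P75`: the alternative parse `(slope + consensus) × P75`
is rejected because consensus (~0.5) would dominate slope (~1e-4..1e-2) and
break the observed order-of-magnitude relations between the three
quantities. Slope is recorded in salience units per 64 ms frame. The
matching threshold (50%, strict) is a parameter; scores exactly at the
threshold are mismatches.

## Acoustic features

The front end is this package's own implementation: a 128-channel
log-frequency (constant-Q-like) magnitude spectrogram from 512-sample Hann
windows placed at exact 8 ms centers (so pooling by 8 lands exactly on the
64 ms grid at any sample rate). Divergences from any particular cortical-
model codebase are expected; the contracts each feature satisfies are pinned
by tests instead.

- **LD**: mean energy over 24 triangular bands equally spaced on the bark
  scale (Zwicker's approximation).
- **SE/BR/BW/FL**: energy, magnitude-weighted centroid, spread, and
  geometric/arithmetic mean ratio of the linear-frequency spectrum.
- **IR**: sum of squared differences of adjacent log magnitudes, normalized
  by the summed squared log magnitudes (one of several "jaggedness"
  formulas; this one is scale-dependent before z-scoring, documented as
  such).
- **P/H**: harmonic sieve over 96 geometric candidates in 50–800 Hz,
  harmonics gathered up to 4 kHz; H is the candidate's mean harmonic-bin
  magnitude over the frame mean, minus 1 and clipped at 0 (≈0 for white
  noise); P is the argmax fundamental, 0 when H = 0.
- **Rate–scale features**: a 2-D modulation filterbank over the
  log-frequency spectrogram — log-Gaussian bands (0.6 octave width) at rates
  {2, 4, 8, 16, 32, 64} Hz × scales {0.25, 0.5, 1, 2, 4, 8} cyc/oct × two
  ripple directions, implemented by masking the 2-D FFT in one analytic
  half-plane. RSE/MS/CS/MR are totals, maxima and centroids of the
  resulting energies; HR/LR split at 20 Hz (32 and 64 Hz bands are "high");
  CR is the signed-rate centroid, CAR the centroid over |rate|
  (direction-blind). The 45 Hz–11 kHz channel span gives ≈16
  channels/octave, placing the 8 cyc/oct band at the spectral-modulation
  Nyquist edge — acceptable, and noted.

Pooling precedes z-scoring ("downsampled ... and z-score normalized" read in
that order). Z-scoring a constant column outputs zeros with a warning; the
constancy test is relative (std ≤ 1e-12·max(1, |mean|)) so float summation
fuzz cannot disguise a constant.

**Feature change** around an onset is mean(post) − mean(pre) over
[0.5, 1.0] s windows. Window means are computed by averaging the linearly
interpolated feature at 33 uniform points spanning the window: for a linear
trend this gives the window-center value exactly (Δ = 1.5·slope to machine
precision), independent of grid phase — a plain frame-index mean would bias
the window center by up to half a frame. Group statistics: one-sample
t-tests per (group, feature); a three-factor ANOVA (presentation × event
type × feature with all pairwise interactions, type-II) that refuses designs
with empty cells; and Tukey-HSD-corrected pairwise contrasts per feature.

## Semantic stream

Any object satisfying the `EmbeddingProvider` protocol (waveform →
equal-frame-count per-layer series) plugs in; the repository ships only the
synthetic provider. Surprisal uses a strictly-past window (t−W..t−1): the
current frame is excluded, otherwise a step of norm δ would read
δ·W/(W+1). Warm-up frames use the partial history available and are flagged
rather than dropped. Frame 0 has no history and reads 0.

Dominant-class labeling averages leaf posteriors over the half-open segment,
keeps the top 10 (ties broken by lexicographic class id), sums candidates
into their five ontology roots (Human, Things, Music, Animals, Background)
and returns the argmax root, again with lexicographic tie-break. The
leaf→root table is user-supplied; the synthetic taxonomy maps its generated
leaves explicitly. The posterior change baseline binarizes at 0.5,
median-filters with an odd window (~1 s), first-differences and sums |Δ|
across classes.

## Regression models

Design matrices stack per-block smoothed features over lags −past..+future
(lag-major flattening); frames lacking full context in either block are
dropped and indexed. The closed-form block ridge solves
(XᵀX + Λ)w = Xᵀy with Λ carrying λ_a on acoustic columns, λ_s on semantic
columns and 0 on the bias; a singular system at zero penalty falls back to
the pseudoinverse with a warning.

Repo-default hyperparameters (used when no corpus selects them): smoothing
0.5 s (acoustic) / 1 s (semantic), past 4 s, future 1 s; λ grids logarithmic
over 1e-4..1e4. Variant context caps: A-only ±0.5 s; A-C 4 s past / 1 s
future; A-S adds the surprisal block; S is surprisal-only. The second
penalty symbol in the model's hyperparameter list is read as λ_s.

Evaluation cuts scenes into 8 s segments with 4 s hop, excluding the first
and last second. Segment labels follow the higher-overlap rule (ties go to
match); zero-variance or context-less segments are excluded and counted.
The end-to-end pipeline scores segments by leave-one-scene-out models, so
evaluation data is always disjoint from fitting data. Cross-validation
splits by scene with a seeded permutation (deterministic folds). The layer
ablation adds surprisal layers cumulatively and contrasts each cutoff with a
randomized-surprisal baseline (≥10 seeds, standard error reported); cutoff 0
is the A-C model. TRFs are the acoustic weights reshaped to (lag × feature);
autocorrelations are normalized to 1 at lag 0 and averaged over scenes.

## Onset detection

Segments are half-open [start, start+1 s) on the 64 ms grid (16 frames ≈
1.024 s), non-overlapping; an onset exactly on a boundary belongs to the
segment it starts. Features are first-differenced before windowing; the A-S
variant appends a 3 s past context and the surprisal columns. The model is
bilinear-sigmoid — score = σ(w_timeᵀ X w_feat + b) — trained by plain SGD
(no momentum), cross-entropy, mini-batch 200, learning rate 0.01, 100
epochs, seeded shuffling, keeping the lowest-training-loss snapshot.

A practical consequence of fixing that recipe: convergence is governed by
the number of SGD updates, i.e. by corpus size. On corpora of a few hundred
segments the detector stays visibly undertrained (near-chance AUROC); at a
few thousand segments — the scale of a ~50-minute training corpus — it
converges well. The demonstration pipeline's small corpus therefore shows a
modest detector AUROC by design, while `examples/06` trains at the larger
scale. ROC sweeps all unique scores (plus +∞), giving a monotone curve from
(0,0) to (1,1) whose trapezoidal area equals the normalized Mann–Whitney U
statistic. Signal baselines (interobserver counts, posterior change) are
max-pooled per segment — onset pulses are sparse, so the max is the natural
pooled score.

## Synthetic generator

The generator's defaults encode the emulated study conditions: 2-minute
scenes at 22.05 kHz (16-bit PCM on disk), ~100 participants per experiment,
consensus 0.45 per event, reaction times with 0.9 s median and 0.15 s
spread, and a 64 ms analysis grid. Specifics:

- **Scenes**: spectrally tilted Gaussian noise background (default −30 dBFS,
  −3 dB/octave) plus tone / AM-tone / noise-burst / moving-ripple events at
  a level step (default 15–20 dB) over the background, with 10 ms raised-
  cosine ramps. Same-kind events must not overlap. Normalization scales the
  waveform so the RMS of the loudest 1% of 50 ms non-overlapping frames hits
  0.1; it is idempotent to machine precision.
- **Responses**: a participant responds to event i with probability
  consensus_i; responders switch toward the scene at onset + rt, rt drawn
  from a log-normal with the configured median and a coefficient-of-
  variation spread (any unimodal positive law would do; log-normal gives the
  right skew), then hold attention 3 s. Lapses are a Poisson process
  (spurious attend intervals, exponential ~0.5 s). Traces sample at 20 Hz.
- **Embeddings**: stationary unit-variance noise per layer with mean shifts
  of configurable norm at change points; **posteriors**: one active leaf
  (0.9) hopping across ontology roots at switch times.
- **Linear targets**: causal convolution of features with a stored filter,
  plus bias and Gaussian noise, then *affine rescale* into [0, 1] (not
  clipping), so the generating filter remains exactly recoverable up to the
  stored affine map.

What the simulator does **not** emulate: acoustic realism beyond what the
feature bank needs, cursor kinematics or a center zone, participant
heterogeneity beyond reaction-time spread, and any attention dynamics
(capture, adaptation, competition between ears). Passing recovery tests
therefore shows the *analysis* is correct and well-calibrated under its own
assumptions — not that those assumptions hold for human listeners.

## Problem sizes and determinism

Tests and the acceptance script size their simulations for single-CPU runs:
event recovery uses 10 cohorts of 200 participants; ridge recovery 20
scenes × 120 s at SNR 10; model comparisons 20 seeds of 3-scene corpora;
the end-to-end determinism check 2 scenes × 40 s × 25 participants, run
twice and compared by file checksums. All randomness flows through
`numpy.random.default_rng` seeded per stage from one root seed
(`SeedSequence` children, kept below 2³¹), which is what makes byte-identical
reruns possible.

## Known limitations

- The acoustic front end is a self-contained approximation of a cortical
  spectrogram/modulation model; absolute feature values are not comparable
  across implementations (z-scoring absorbs most of this, centroids less).
- The harmonic sieve searches 50–800 Hz fundamentals only.
- Surprisal compresses each layer to one dimension; richer reductions
  (e.g. kernel PCA) are out of scope.
- The detector's offset-detection extension (3-way labels) is left as a
  schema hook, unimplemented.
- No audio-tagging network ships with the package; real embedding streams
  require a user-supplied provider satisfying the documented protocol.
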