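"""Train the salient-event-onset detector and compare it to its ceiling.

1 s segments of first-differenced features are labeled positive when they
contain an event onset; a shared-temporal-weight sigmoid model is trained
by SGD and evaluated by ROC/AUROC.  The interobserver agreement — how many
simulated participants switch toward the scene in each segment — bounds
what any feature-driven detector can achieve.
"""

import numpy as np

from audisal import (
    GroundTruth,
    ResponseSpec,
    fit_detector,
    interobserver_signal,
    make_detection_dataset,
    make_response_set,
    roc,
)

STEP = 0.064
rng = np.random.default_rng(9)

# training corpus sized like the study's (~50 minutes of scenes, thousands
# of segments): the fixed SGD recipe needs that many updates to converge
duration = 3000.0
onsets = list(np.arange(8.0, duration - 5.0, 9.0))
T = int(duration / STEP)
X = 0.3 * rng.standard_normal((T, 8))
for o in onsets:
    X[int(o / STEP) : int(o / STEP) + 31] += 2.5  # 2 s acoustic trace per event

dataset = make_detection_dataset(X, None, onsets)
model = fit_detector(dataset, seed=0)
result = roc(model.scores(dataset.X), dataset.labels)
print(f"{len(dataset.labels)} segments, {dataset.labels.sum()} positive")
print(f"acoustic detector AUROC = {result.auroc:.3f} (best training loss "
      f"{model.best_loss:.3f})")

# interobserver ceiling on a 2-minute excerpt with a behavioral cohort
excerpt = 120.0
ex_onsets = [o for o in onsets if o < excerpt - 5]
truth = GroundTruth(planted_onsets=ex_onsets)
trials = make_response_set(
    truth, ResponseSpec(n_participants=100, consensus=0.45, rt_median=1.0,
                        rt_spread=0.0, lapse_rate=0.005, seed=1), excerpt
)
ex_mask = dataset.starts < excerpt - 1.0
counts = interobserver_signal(trials, dataset.starts[ex_mask], rt_shift=1.0)
ceiling = roc(counts, dataset.labels[ex_mask]).auroc
print(f"interobserver ceiling AUROC = {ceiling:.3f}")
print("the gap between detector and ceiling is the room left for better features.")
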