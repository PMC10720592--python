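"""Compute the 16 acoustic features of a scene and the changes at an onset.

The feature bank spans energy (LD, SE, RSE), spectral shape (BR, BW, FL,
IR), pitch (P, H) and spectrotemporal modulation statistics (MS, CS, MR,
HR, LR, CR, CAR), on the pipeline's 64 ms grid.  Feature change at an event
onset is the mean over [0.5, 1.0] s after minus the mean over the same
window before — the quantity used to ask which acoustic dimensions drive
attention switches.
"""

import numpy as np

from audisal import PlantedEvent, SceneSpec, feature_change, featurize, make_scene

spec = SceneSpec(
    "feat-demo",
    duration=30.0,
    planted_events=[
        PlantedEvent(onset=8.0, duration=2.0, kind="am-tone", carrier=800.0, mod_rate=8.0),
        PlantedEvent(onset=20.0, duration=2.0, kind="noise-burst", level_step=18.0),
    ],
)
waveform, truth = make_scene(spec, seed=4)

raw = featurize(waveform, spec.sample_rate, zscore=False)
print("pre-z-score medians (physical-ish units):")
for name in ("LD", "BR", "FL", "P", "H", "LR", "HR"):
    print(f"  {name:4s} {np.median(raw.column(name)):10.4g}")

features = featurize(waveform, spec.sample_rate)  # z-scored per scene
table, n_excluded = feature_change(features, truth.planted_onsets)
print(f"\nfeature changes at {len(truth.planted_onsets)} planted onsets "
      f"({n_excluded} excluded for window support), z-scored units:")
pivot = table.pivot(index="feature", columns="onset", values="delta")
print(pivot.round(2))
print("\npositive LD/SE/RSE deltas: events arrive with an energy increase,")
print("the signature the behavioral analysis associates with matched events.")
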