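"""Fit the four salience-prediction model variants on a known linear system.

The target is a known causal filter (peaking ~2 s back) applied to AR(1)
features plus noise, so longer temporal context must help: A-only (0.5 s
context) < A-C (4 s context).  A semantic block of pure noise should add
nothing (A-S ~ A-C), and the semantic-only model S should fail.
"""

import numpy as np

from audisal import SceneData, make_linear_ground_truth, model_variants, predict_scene

STEP = 0.064
rng = np.random.default_rng(8)


def ar1(T, F, rho=0.9):
    x = np.zeros((T, F))
    eps = rng.standard_normal((T, F)) * np.sqrt(1 - rho**2)
    for t in range(1, T):
        x[t] = rho * x[t - 1] + eps[t]
    return x


F, lag = 4, int(round(2.0 / STEP))
filt = np.zeros((F, lag + 4))
filt[:, lag:] = rng.standard_normal((F, 4)) / np.sqrt(F * 4)

scenes = []
for i in range(4):
    X = ar1(900, F)
    target, _ = make_linear_ground_truth(X, filt, 0.05, seed=100 + i)
    scenes.append(
        SceneData(f"s{i}", X, target.values,
                  surprisal=np.abs(rng.standard_normal((900, 3))), grid_step=STEP)
    )

models = model_variants(scenes[:3], lam_a=1.0, lam_s=1.0)
held = scenes[3]
print("held-out scene correlation per model variant:")
for name, model in models.items():
    pred, valid = predict_scene(model, held)
    r = np.corrcoef(pred, held.target[valid])[0, 1]
    print(f"  {name:7s} r = {r:.3f}")
print("A-C beats A-only because the generating filter acts ~2 s in the past;")
print("the noise surprisal block neither helps (A-S ~ A-C) nor suffices (S).")
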