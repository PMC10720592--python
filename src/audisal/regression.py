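"""Linear salience prediction with temporal-context ridge models.

Behavioral salience r_t is predicted frame-by-frame as a linear readout of
windowed acoustic features a_t and semantic surprisals s_t:

    r_hat_t = W_a' a_t + W_s' s_t + b

where a_t / s_t stack per-block smoothed features over past and future
context lags, flattened into vectors.  W_a, W_s and the unpenalized bias b
minimize squared error with separate L2 penalties lambda_a, lambda_s per
block (closed-form block ridge).  Model quality is the Pearson correlation
between predicted and observed salience over 8 s segments (4 s hop, first
and last second of each scene excluded), with segments labeled by their
overlap with matched/mismatched salient events.

Model variants follow the study design: A-only (acoustic, context capped at
0.5 s), A-C (acoustic, 4 s context), A-S (acoustic + semantic), and S
(semantic only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .behavioral import GRID_STEP

__all__ = [
    "ContextDesign",
    "RidgeModel",
    "SceneData",
    "build_design",
    "fit_ridge",
    "fit_corpus",
    "predict_scene",
    "evaluate_segments",
    "segment_group_tests",
    "cross_validate",
    "model_variants",
    "layer_ablation",
    "trf_and_autocorrelation",
    "classwise_performance",
]


@dataclass
class ContextDesign:
    """Temporal-context window configuration for both feature blocks.

    Past/future lengths and smoothing are in seconds on the 64 ms grid.
    Repository defaults (used when no training corpus selects them):
    0.5 s / 1 s smoothing and 4 s past, 1 s future context.
    """

    frame_step: float = GRID_STEP
    ac_smooth: float = 0.5
    ac_past: float = 4.0
    ac_future: float = 1.0
    sem_smooth: float = 1.0
    sem_past: float = 4.0
    sem_future: float = 1.0

    def lags(self, block: str) -> tuple[int, int]:
        past = self.ac_past if block == "acoustic" else self.sem_past
        future = self.ac_future if block == "acoustic" else self.sem_future
        if past < 0 or future < 0:
            raise ValueError("context lengths must be non-negative")
        return int(round(past / self.frame_step)), int(round(future / self.frame_step))


@dataclass
class SceneData:
    """One scene's aligned inputs for model fitting and evaluation."""

    scene_id: str
    features: np.ndarray  # (T, F) acoustic features on the 64 ms grid
    target: np.ndarray  # (T,) behavioral salience
    surprisal: np.ndarray | None = None  # (T, L)
    grid_step: float = GRID_STEP
    matched: list = field(default_factory=list)  # (onset, offset) of matched events
    mismatched: list = field(default_factory=list)
    direction: str = "fwd"


@dataclass
class RidgeModel:
    W_a: np.ndarray | None
    W_s: np.ndarray | None
    b: float
    lam_a: float
    lam_s: float
    design: ContextDesign
    n_acoustic: int = 0  # feature count per lag, acoustic block
    n_semantic: int = 0

    def predict(self, X_a: np.ndarray | None, X_s: np.ndarray | None) -> np.ndarray:
        parts = []
        if self.W_a is not None:
            parts.append(X_a @ self.W_a)
        if self.W_s is not None:
            parts.append(X_s @ self.W_s)
        return sum(parts) + self.b


def _smooth(X: np.ndarray, length: float, step: float) -> np.ndarray:
    win = int(round(length / step))
    if win <= 1:
        return X
    if win % 2 == 0:
        win += 1
    return uniform_filter1d(X, size=win, axis=0, mode="nearest")


def _lag_stack(X: np.ndarray, past: int, future: int, lo: int, hi: int) -> np.ndarray:
    """Rows t in [lo, hi): concatenation over lags -past..+future of X[t+off].

    Flattening is lag-major: row = [X[t-past], ..., X[t], ..., X[t+future]].
    """
    offs = np.arange(-past, future + 1)
    cols = [X[lo + off : hi + off] for off in offs]
    return np.concatenate(cols, axis=1)


def build_design(
    features: np.ndarray,
    surprisal: np.ndarray | None,
    design: ContextDesign,
) -> tuple[np.ndarray | None, np.ndarray | None, np.ndarray]:
    """Build lagged design blocks and the surviving frame indices.

    Returns (X_a, X_s, valid_idx): each block smoothed with its own moving
    average, lag-stacked over its context window, restricted to frames with
    full context in *both* blocks.  ``features`` may be None for
    semantic-only models.
    """
    T = len(features) if features is not None else len(surprisal)
    pa, fa = design.lags("acoustic")
    ps, fs = design.lags("semantic")
    past = max(pa if features is not None else 0, ps if surprisal is not None else 0)
    fut = max(fa if features is not None else 0, fs if surprisal is not None else 0)
    lo, hi = past, T - fut
    if hi <= lo:
        raise ValueError("context window longer than the scene")
    valid = np.arange(lo, hi)
    X_a = X_s = None
    if features is not None:
        Xs = _smooth(np.asarray(features, dtype=float), design.ac_smooth, design.frame_step)
        X_a = _lag_stack(Xs, pa, fa, lo, hi)
    if surprisal is not None:
        Ss = _smooth(np.asarray(surprisal, dtype=float), design.sem_smooth, design.frame_step)
        X_s = _lag_stack(Ss, ps, fs, lo, hi)
    return X_a, X_s, valid


def fit_ridge(
    X_a: np.ndarray | None,
    X_s: np.ndarray | None,
    y: np.ndarray,
    lam_a: float = 1.0,
    lam_s: float = 1.0,
    design: ContextDesign | None = None,
) -> RidgeModel:
    """Closed-form block-penalized ridge with an unpenalized bias.

    Solves (X'X + Lambda) w = X'y with Lambda diagonal: lam_a over acoustic
    columns, lam_s over semantic columns, 0 on the bias.  A singular system
    at zero penalty falls back to the pseudoinverse with a warning.
    """
    if lam_a < 0 or lam_s < 0:
        raise ValueError("penalties must be non-negative")
    blocks = [B for B in (X_a, X_s) if B is not None]
    if not blocks:
        raise ValueError("at least one feature block is required")
    X = np.concatenate(blocks + [np.ones((len(y), 1))], axis=1)
    pen = np.concatenate(
        [np.full(X_a.shape[1], lam_a) if X_a is not None else np.empty(0),
         np.full(X_s.shape[1], lam_s) if X_s is not None else np.empty(0),
         [0.0]]
    )
    A = X.T @ X + np.diag(pen)
    rhs = X.T @ np.asarray(y, dtype=float)
    try:
        w = np.linalg.solve(A, rhs)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular ridge system; falling back to pseudoinverse")
        w = np.linalg.pinv(A) @ rhs
    da = X_a.shape[1] if X_a is not None else 0
    ds = X_s.shape[1] if X_s is not None else 0
    return RidgeModel(
        W_a=w[:da] if da else None,
        W_s=w[da : da + ds] if ds else None,
        b=float(w[-1]),
        lam_a=lam_a,
        lam_s=lam_s,
        design=design or ContextDesign(),
        n_acoustic=0,
        n_semantic=0,
    )


def fit_corpus(
    scenes: list[SceneData],
    design: ContextDesign,
    lam_a: float = 1.0,
    lam_s: float = 1.0,
    use_acoustic: bool = True,
    use_semantic: bool = False,
) -> RidgeModel:
    """Fit one ridge model on the pooled valid frames of several scenes."""
    Xa_all, Xs_all, y_all = [], [], []
    for sc in scenes:
        if use_semantic and sc.surprisal is None:
            raise ValueError(f"scene {sc.scene_id} has no surprisal input for a semantic model")
        X_a, X_s, valid = build_design(
            sc.features if use_acoustic else None,
            sc.surprisal if use_semantic else None,
            design,
        )
        if X_a is not None:
            Xa_all.append(X_a)
        if X_s is not None:
            Xs_all.append(X_s)
        y_all.append(sc.target[valid])
    X_a = np.concatenate(Xa_all) if Xa_all else None
    X_s = np.concatenate(Xs_all) if Xs_all else None
    model = fit_ridge(X_a, X_s, np.concatenate(y_all), lam_a, lam_s, design)
    model.n_acoustic = scenes[0].features.shape[1] if use_acoustic else 0
    model.n_semantic = scenes[0].surprisal.shape[1] if use_semantic else 0
    return model


def predict_scene(model: RidgeModel, scene: SceneData) -> tuple[np.ndarray, np.ndarray]:
    """Predicted salience over a scene's valid frames; returns (pred, valid_idx)."""
    X_a, X_s, valid = build_design(
        scene.features if model.W_a is not None else None,
        scene.surprisal if model.W_s is not None else None,
        model.design,
    )
    return model.predict(X_a, X_s), valid


def _overlap(lo: float, hi: float, intervals: list) -> float:
    return sum(max(0.0, min(hi, b) - max(lo, a)) for a, b in intervals)


def evaluate_segments(
    model: RidgeModel,
    scenes: list[SceneData],
    seg_len: float = 8.0,
    hop: float = 4.0,
    edge: float = 1.0,
) -> pd.DataFrame:
    """Segment-wise Pearson correlation of predicted vs observed salience.

    Scenes are cut into ``seg_len``-second segments with ``hop``-second
    steps, ignoring the first and last ``edge`` seconds.  Each segment is
    labeled match / mismatch / no-event by its overlap with the scene's
    matched and mismatched events (the category with higher overlap wins;
    exact ties go to match).  Segments with zero target variance, or without
    full model context, are excluded and reported with label "excluded".
    """
    rows = []
    for sc in scenes:
        pred, valid = predict_scene(model, sc)
        step = sc.grid_step
        duration = len(sc.target) * step
        start = edge
        while start + seg_len <= duration - edge + 1e-9:
            i0, i1 = int(round(start / step)), int(round((start + seg_len) / step))
            row = {"scene_id": sc.scene_id, "start": start, "end": start + seg_len}
            seg_valid = (i0 >= valid[0]) and (i1 <= valid[-1] + 1)
            y = sc.target[i0:i1]
            if not seg_valid or np.ptp(y) == 0:
                row.update(r=np.nan, label="excluded")
            else:
                p = pred[i0 - valid[0] : i1 - valid[0]]
                if np.ptp(p) == 0:
                    row.update(r=np.nan, label="excluded")
                else:
                    r = float(np.corrcoef(p, y)[0, 1])
                    ov_m = _overlap(start, start + seg_len, sc.matched)
                    ov_x = _overlap(start, start + seg_len, sc.mismatched)
                    if ov_m == 0 and ov_x == 0:
                        label = "no-event"
                    else:
                        label = "match" if ov_m >= ov_x else "mismatch"
                    row.update(r=r, label=label)
            rows.append(row)
            start += hop
    return pd.DataFrame(rows)


def segment_group_tests(segments: pd.DataFrame, alternative: str = "two-sided") -> dict:
    """Wilcoxon rank-sum comparison of match vs mismatch segment correlations."""
    m = segments.loc[segments.label == "match", "r"].dropna()
    x = segments.loc[segments.label == "mismatch", "r"].dropna()
    out = {
        "match_mean": float(m.mean()) if len(m) else np.nan,
        "mismatch_mean": float(x.mean()) if len(x) else np.nan,
        "n_match": len(m),
        "n_mismatch": len(x),
        "n_excluded": int((segments.label == "excluded").sum()),
    }
    if len(m) >= 2 and len(x) >= 2:
        s, p = stats.ranksums(m, x, alternative=alternative)
        out.update(statistic=float(s), p=float(p))
    return out


def _scene_score(model: RidgeModel, scene: SceneData) -> float:
    pred, valid = predict_scene(model, scene)
    y = scene.target[valid]
    if np.ptp(y) == 0 or np.ptp(pred) == 0:
        return np.nan
    return float(np.corrcoef(pred, y)[0, 1])


def cross_validate(
    scenes: list[SceneData],
    grid: list[dict],
    n_folds: int = 10,
    use_acoustic: bool = True,
    use_semantic: bool = False,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame, RidgeModel]:
    """Scene-wise k-fold grid search; refit the winner on all scenes.

    ``grid`` entries carry any of the ContextDesign fields plus ``lam_a`` /
    ``lam_s``.  The selected point maximizes the mean held-out per-scene
    correlation.  Fold assignment is a seeded permutation of scenes, fully
    deterministic under a fixed seed.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    n_folds = min(n_folds, len(scenes))
    order = np.random.default_rng(seed).permutation(len(scenes))
    folds = np.array_split(order, n_folds)
    rows = []
    for gi, params in enumerate(grid):
        design = replace(
            ContextDesign(),
            **{k: v for k, v in params.items() if k not in ("lam_a", "lam_s")},
        )
        lam_a, lam_s = params.get("lam_a", 1.0), params.get("lam_s", 1.0)
        for fi, test_idx in enumerate(folds):
            train = [scenes[i] for i in order if i not in set(test_idx)]
            test = [scenes[i] for i in test_idx]
            if not train or not test:
                continue
            model = fit_corpus(train, design, lam_a, lam_s, use_acoustic, use_semantic)
            scores = [_scene_score(model, sc) for sc in test]
            rows.append({"grid_index": gi, "fold": fi, "score": float(np.nanmean(scores)), **params})
    scores_df = pd.DataFrame(rows)
    mean_by_grid = scores_df.groupby("grid_index")["score"].mean()
    best_gi = int(mean_by_grid.idxmax())
    best = grid[best_gi]
    final_design = replace(
        ContextDesign(), **{k: v for k, v in best.items() if k not in ("lam_a", "lam_s")}
    )
    final = fit_corpus(
        scenes, final_design, best.get("lam_a", 1.0), best.get("lam_s", 1.0),
        use_acoustic, use_semantic,
    )
    return best, scores_df, final


def model_variants(
    scenes: list[SceneData],
    lam_a: float = 1.0,
    lam_s: float = 1.0,
    a_only_cap: float = 0.5,
    context_cap: float = 4.0,
) -> dict[str, RidgeModel]:
    """Fit the four study models: A-only, A-C, A-S and S.

    A-only caps acoustic context at 0.5 s (past and future); A-C extends the
    past context to 4 s (future 1 s); A-S adds the semantic surprisal block
    with the same caps; S uses the surprisal block alone.  A-S and S require
    surprisal on every scene.
    """
    base = ContextDesign()
    designs = {
        "A-only": replace(base, ac_past=a_only_cap, ac_future=a_only_cap),
        "A-C": replace(base, ac_past=context_cap, ac_future=1.0),
        "A-S": replace(base, ac_past=context_cap, ac_future=1.0),
        "S": base,
    }
    out = {}
    out["A-only"] = fit_corpus(scenes, designs["A-only"], lam_a, lam_s, True, False)
    out["A-C"] = fit_corpus(scenes, designs["A-C"], lam_a, lam_s, True, False)
    if any(sc.surprisal is None for sc in scenes):
        raise ValueError("A-S and S variants need surprisal for every scene")
    out["A-S"] = fit_corpus(scenes, designs["A-S"], lam_a, lam_s, True, True)
    out["S"] = fit_corpus(scenes, designs["S"], lam_a, lam_s, False, True)
    return out


def layer_ablation(
    scenes: list[SceneData],
    lam_a: float = 1.0,
    lam_s: float = 1.0,
    n_folds: int = 5,
    n_random_seeds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out performance as surprisal layers are added cumulatively.

    Cutoff k fits an A-S model restricted to the first k surprisal layers
    (cutoff 0 is the A-C model).  A randomized baseline replaces the k
    layers with standard-normal noise, averaged over ``n_random_seeds``
    seeds with its standard error; genuinely informative layers separate
    from this flat baseline.
    """
    L = scenes[0].surprisal.shape[1]
    design = ContextDesign()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(scenes))
    folds = np.array_split(order, min(n_folds, len(scenes)))

    def heldout_score(make_scene_data) -> float:
        scores = []
        for test_idx in folds:
            train = [make_scene_data(i) for i in order if i not in set(test_idx)]
            test = [make_scene_data(i) for i in test_idx]
            use_sem = train[0].surprisal is not None
            model = fit_corpus(train, design, lam_a, lam_s, True, use_sem)
            scores.extend(_scene_score(model, sc) for sc in test)
        return float(np.nanmean(scores))

    rows = []
    for k in range(L + 1):
        def cut(i, k=k):
            sc = scenes[i]
            sur = sc.surprisal[:, :k] if k > 0 else None
            return replace(sc, surprisal=sur)

        score = heldout_score(cut)
        rand_scores = []
        if k > 0:
            for rs in range(n_random_seeds):
                rrng = np.random.default_rng(seed + 1000 + rs)
                noise = {i: rrng.standard_normal((len(scenes[i].target), k)) for i in range(len(scenes))}

                def randomized(i, noise=noise):
                    return replace(scenes[i], surprisal=noise[i])

                rand_scores.append(heldout_score(randomized))
        rows.append(
            {
                "cutoff": k,
                "score": score,
                "random_mean": float(np.mean(rand_scores)) if rand_scores else score,
                "random_se": float(np.std(rand_scores) / np.sqrt(len(rand_scores))) if rand_scores else 0.0,
            }
        )
    return pd.DataFrame(rows)


def trf_and_autocorrelation(
    model: RidgeModel, scenes: list[SceneData], max_lag: float = 4.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Temporal response functions and feature autocorrelations.

    The acoustic weight vector is reshaped to (lag, feature) and returned
    long-form; feature autocorrelations (normalized to 1 at lag 0, averaged
    over scenes) expose the temporal statistics the TRFs should track.
    """
    if model.W_a is None:
        raise ValueError("model has no acoustic block")
    pa, fa = model.design.lags("acoustic")
    n_lags = pa + fa + 1
    if n_lags < 2:
        raise ValueError("model has no temporal lags; TRF undefined")
    F = model.W_a.size // n_lags
    W = model.W_a.reshape(n_lags, F)
    lags_s = (np.arange(n_lags) - pa) * model.design.frame_step
    trf = pd.DataFrame(
        [
            {"lag": lags_s[i], "feature": f, "weight": W[i, f]}
            for i in range(n_lags)
            for f in range(F)
        ]
    )
    K = int(round(max_lag / model.design.frame_step))
    ac_rows = []
    for f in range(F):
        acs = []
        for sc in scenes:
            x = sc.features[:, f] - sc.features[:, f].mean()
            denom = np.dot(x, x)
            if denom == 0:
                continue
            acs.append([np.dot(x[: len(x) - k], x[k:]) / denom for k in range(K + 1)])
        if acs:
            mean_ac = np.mean(acs, axis=0)
            ac_rows.extend(
                {"lag": k * model.design.frame_step, "feature": f, "autocorr": float(mean_ac[k])}
                for k in range(K + 1)
            )
    return trf, pd.DataFrame(ac_rows)


def classwise_performance(segments: pd.DataFrame) -> pd.DataFrame:
    """Per-root-class comparison of A-only vs A-S segment correlations.

    ``segments`` must carry columns ``root`` (dominant class), ``r_a``
    (A-only) and ``r_as`` (A-S).  For each class with >= 2 segments a paired
    one-sided Wilcoxon signed-rank test asks whether A-S improves on A-only.
    """
    rows = []
    for root, sub in segments.groupby("root"):
        a = sub["r_a"].to_numpy()
        s = sub["r_as"].to_numpy()
        row = {
            "root": root,
            "n": len(sub),
            "mean_r_a": float(np.nanmean(a)),
            "mean_r_as": float(np.nanmean(s)),
        }
        diffs = s - a
        if len(sub) < 2 or np.all(diffs == 0):
            row.update(p=np.nan, tested=False)
        else:
            _, p = stats.wilcoxon(s, a, alternative="greater")
            row.update(p=float(p), tested=True)
        rows.append(row)
    return pd.DataFrame(rows)
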