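"""Low-level acoustic features for salience analysis.

Sixteen features spanning energy, spectral shape, pitch, and spectrotemporal
modulation statistics are computed on 8 ms frames, mean-pooled by 8 onto the
pipeline's 64 ms grid, and z-scored per scene:

====  =======================================================================
LD    loudness: average energy in a bark-band decomposition
SE    spectral energy: total energy in the spectrogram bands
RSE   rate-scale energy: total energy of the modulation decomposition
BR    brightness: spectral centroid
BW    bandwidth: spectral spread about the centroid
FL    flatness: geometric / arithmetic mean ratio of spectral magnitudes
IR    irregularity: jaggedness of the log spectrum
P     pitch: fundamental from harmonic template matching
H     harmonicity: strength of the best harmonic template match
MS    maximum energy across spectral-modulation scales
CS    centroid of scales (cyc/oct)
MR    maximum energy across temporal-modulation rates
HR    roughness: energy at rates > 20 Hz
LR    energy at rates <= 20 Hz
CR    centroid of signed rates (Hz; sign encodes ripple direction)
CAR   rate centroid over |rate| (direction ignored)
====  =======================================================================

The front end is a 128-channel log-frequency (constant-Q-like) magnitude
spectrogram; the modulation analysis is a 2-D filterbank over that
spectrogram with rates {2, 4, 8, 16, 32, 64} Hz in both ripple directions
and scales {0.25, 0.5, 1, 2, 4, 8} cyc/oct, following standard cortical-
model defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behavioral import GRID_STEP

__all__ = [
    "FEATURE_NAMES",
    "FeatureMatrix",
    "featurize",
    "feature_change",
    "feature_change_tests",
    "zscore_columns",
]

FEATURE_NAMES = [
    "LD", "SE", "RSE", "BR", "BW", "FL", "IR", "P",
    "H", "MS", "CS", "MR", "HR", "LR", "CR", "CAR",
]

FRAME_STEP_FAST = 0.008  # s, initial analysis frame step
POOL = 8  # frames pooled onto the 64 ms grid
N_FFT = 512
N_LOG_CHANNELS = 128
F_LO = 45.0  # Hz, lowest log-frequency channel
RATES = np.array([2.0, 4.0, 8.0, 16.0, 32.0, 64.0])  # Hz
SCALES = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])  # cyc/oct
_EPS = 1e-12


@dataclass
class FeatureMatrix:
    """Per-scene T x 16 acoustic feature matrix on the 64 ms grid."""

    scene_id: str
    frame_step: float
    names: list[str]
    values: np.ndarray  # (T, 16)
    zscored: bool = True

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.names):
            raise ValueError("feature column count must match names")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) * self.frame_step

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


def zscore_columns(X: np.ndarray) -> np.ndarray:
    """Z-score each column; constant columns map to zeros with a warning."""
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    # relative threshold: float summation fuzz must not disguise a constant
    flat = std <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} constant feature column(s) z-scored to zeros")
    out = (X - mean) / np.where(flat, 1.0, std)
    out[:, flat] = 0.0
    return out


def _magnitude_spectrogram(waveform: np.ndarray, sr: float) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude spectrogram at exact 8 ms frame centers (T, n_bins) + bin freqs.

    Frames start at sample round(k * 8ms * sr), so pooling by 8 lands exactly
    on the pipeline's 64 ms grid regardless of the sample rate.
    """
    T = int(np.floor(len(waveform) / sr / FRAME_STEP_FAST))
    w = np.concatenate([waveform, np.zeros(N_FFT)])
    starts = np.round(np.arange(T) * FRAME_STEP_FAST * sr).astype(int)
    frames = w[starts[:, None] + np.arange(N_FFT)[None, :]]
    window = np.hanning(N_FFT)
    spec = np.abs(np.fft.rfft(frames * window, axis=1))
    freqs = np.fft.rfftfreq(N_FFT, 1 / sr)
    return spec, freqs


def _triangular_bank(freqs: np.ndarray, centers: np.ndarray, to_log: bool) -> np.ndarray:
    """Triangular filters with neighbors' centers as edges, rows normalized."""
    axis = np.log2(np.maximum(freqs, 1e-3)) if to_log else freqs
    c = np.log2(centers) if to_log else centers
    edges = np.concatenate([[2 * c[0] - c[1]], c, [2 * c[-1] - c[-2]]])
    bank = np.zeros((len(centers), len(freqs)))
    for i in range(len(centers)):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (axis - lo) / (mid - lo)
        down = (hi - axis) / (hi - mid)
        bank[i] = np.clip(np.minimum(up, down), 0, None)
    norm = bank.sum(axis=1, keepdims=True)
    return bank / np.maximum(norm, _EPS)


def _bark_edges(sr: float, n_bands: int = 24) -> np.ndarray:
    """Band center frequencies equally spaced on the bark scale."""
    def bark(f):
        return 13 * np.arctan(0.00076 * f) + 3.5 * np.arctan((f / 7500.0) ** 2)

    grid = np.linspace(20, sr / 2, 4000)
    z = bark(grid)
    targets = np.linspace(z[0], z[-1], n_bands + 2)[1:-1]
    return np.interp(targets, z, grid)


def _harmonic_sieve(freqs: np.ndarray, n_cand: int = 96, f_min: float = 50.0, f_max: float = 800.0,
                    max_freq: float = 4000.0) -> tuple[np.ndarray, np.ndarray]:
    """0/1 sieve matrix (candidate f0 x bins) selecting harmonic bins."""
    cands = np.geomspace(f_min, f_max, n_cand)
    df = freqs[1] - freqs[0]
    sieve = np.zeros((n_cand, len(freqs)))
    for i, f0 in enumerate(cands):
        harmonics = np.arange(f0, max_freq, f0)
        bins = np.round(harmonics / df).astype(int)
        bins = bins[bins < len(freqs)]
        sieve[i, bins] = 1.0
    counts = sieve.sum(axis=1)
    return cands, sieve / np.maximum(counts[:, None], 1)


def _log_gaussian(x: np.ndarray, center: float, width_oct: float = 0.6) -> np.ndarray:
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = np.exp(-0.5 * ((np.log2(x[nz] / center)) / width_oct) ** 2)
    return out


def _modulation_energies(logspec: np.ndarray, oct_per_channel: float) -> dict:
    """Per-frame energy of each (direction, rate, scale) modulation filter.

    The (T, channels) log-frequency spectrogram is 2-D Fourier transformed;
    each filter selects a Gaussian band around its rate (temporal modulation,
    Hz) and scale (spectral modulation, cyc/oct) in one analytic half-plane,
    with the spectral-modulation sign selecting up- vs down-moving ripples.
    Energy is |inverse transform|^2 averaged over channels.
    """
    T, C = logspec.shape
    X = logspec - logspec.mean()
    F = np.fft.fft2(X)
    omega = np.fft.fftfreq(T, FRAME_STEP_FAST)  # temporal modulation, Hz
    Omega = np.fft.fftfreq(C, oct_per_channel)  # spectral modulation, cyc/oct
    pos_t = (omega > 0).astype(float)[:, None]
    energies = {}
    for r in RATES:
        g_r = _log_gaussian(np.abs(omega), r)[:, None] * pos_t
        for s in SCALES:
            g_s = _log_gaussian(np.abs(Omega), s)[None, :]
            for direction, sign in (("down", 1.0), ("up", -1.0)):
                mask = g_r * g_s * (np.sign(Omega)[None, :] == sign)
                z = np.fft.ifft2(F * mask)
                energies[(direction, r, s)] = np.mean(np.abs(z) ** 2, axis=1)
    return energies


def _pool(x: np.ndarray, k: int = POOL) -> np.ndarray:
    n = (len(x) // k) * k
    return x[:n].reshape(-1, k).mean(axis=1)


def featurize(
    waveform: np.ndarray,
    sample_rate: float,
    scene_id: str = "scene",
    zscore: bool = True,
) -> FeatureMatrix:
    """Compute the 16 acoustic features of a mono scene on the 64 ms grid.

    All features are computed on 8 ms frames, mean-pooled over 8 consecutive
    frames, and (by default) z-scored per scene.  Pass ``zscore=False`` for
    physical-unit values (energies, Hz, cyc/oct).
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1:
        raise ValueError("stereo input: mix down or split channels before featurizing")
    if len(waveform) < sample_rate:
        raise ValueError("scene must be at least 1 s long")

    spec, freqs = _magnitude_spectrogram(waveform, sample_rate)
    power = spec**2
    T = spec.shape[0]

    # --- energy ---
    bark_bank = _triangular_bank(freqs, _bark_edges(sample_rate), to_log=False)
    LD = (power @ bark_bank.T).mean(axis=1)
    SE = power.mean(axis=1)

    # --- spectral shape (magnitude-weighted; silent frames -> 0) ---
    mag_sum = spec.sum(axis=1)
    safe = np.maximum(mag_sum, _EPS)
    BR = (spec @ freqs) / safe
    BW = np.sqrt(np.maximum((spec * (freqs[None, :] - BR[:, None]) ** 2).sum(axis=1) / safe, 0))
    gmean = np.exp(np.mean(np.log(spec + _EPS), axis=1))
    FL = gmean / (spec.mean(axis=1) + _EPS)
    logmag = np.log(spec + _EPS)
    IR = np.sum(np.diff(logmag, axis=1) ** 2, axis=1) / np.maximum(np.sum(logmag**2, axis=1), _EPS)

    # --- pitch / harmonicity via harmonic sieve ---
    cands, sieve = _harmonic_sieve(freqs)
    scores = sieve @ spec.T  # (n_cand, T): mean magnitude at harmonic bins
    overall = spec.mean(axis=1) + _EPS
    ratio = scores / overall[None, :]
    best = np.argmax(ratio, axis=0)
    H = np.maximum(ratio[best, np.arange(T)] - 1.0, 0.0)
    P = cands[best]
    P[H <= 0] = 0.0  # no harmonic structure -> no pitch

    # --- rate-scale modulation features ---
    centers = np.geomspace(F_LO, sample_rate / 2, N_LOG_CHANNELS)
    log_bank = _triangular_bank(freqs, centers, to_log=True)
    logspec = spec @ log_bank.T  # (T, 128)
    oct_per_channel = np.log2(centers[-1] / centers[0]) / (N_LOG_CHANNELS - 1)
    E = _modulation_energies(logspec, oct_per_channel)

    RSE = np.sum(list(E.values()), axis=0)
    total = np.maximum(RSE, _EPS)
    e_scale = {s: sum(E[(d, r, s)] for d in ("down", "up") for r in RATES) for s in SCALES}
    MS = np.max(np.stack([e_scale[s] for s in SCALES]), axis=0)
    CS = sum(s * e_scale[s] for s in SCALES) / total
    e_rate = {r: sum(E[(d, r, s)] for d in ("down", "up") for s in SCALES) for r in RATES}
    MR = np.max(np.stack([e_rate[r] for r in RATES]), axis=0)
    HR = sum(e_rate[r] for r in RATES if r > 20)
    LR = sum(e_rate[r] for r in RATES if r <= 20)
    e_signed = {
        sign * r: sum(E[(d, r, s)] for s in SCALES)
        for r in RATES
        for sign, d in ((1.0, "down"), (-1.0, "up"))
    }
    CR = sum(sr_ * e for sr_, e in e_signed.items()) / total
    CAR = sum(abs(sr_) * e for sr_, e in e_signed.items()) / total

    columns = [LD, SE, RSE, BR, BW, FL, IR, P, H, MS, CS, MR, HR, LR, CR, CAR]
    pooled = np.stack([_pool(c) for c in columns], axis=1)
    if zscore:
        pooled = zscore_columns(pooled)
    return FeatureMatrix(scene_id, FRAME_STEP_FAST * POOL, list(FEATURE_NAMES), pooled, zscored=zscore)


def _window_mean(times: np.ndarray, col: np.ndarray, lo: float, hi: float, k: int = 33) -> float:
    """Mean of a feature over [lo, hi] by uniform linear-interpolation sampling.

    Sampling the window at symmetric uniform offsets makes the mean of a
    linear trend exact (center of the window), independent of grid phase.
    """
    return float(np.mean(np.interp(np.linspace(lo, hi, k), times, col)))


def feature_change(
    features: FeatureMatrix,
    onsets: list[float],
    pre_win: tuple[float, float] = (-1.0, -0.5),
    post_win: tuple[float, float] = (0.5, 1.0),
) -> tuple[pd.DataFrame, int]:
    """Per-event, per-feature change around salient-event onsets.

    Delta = mean(feature over onset+post_win) - mean(feature over
    onset+pre_win).  Onsets without full window support inside the scene are
    excluded; the count of exclusions is returned alongside the long-form
    table (columns: onset, feature, delta).
    """
    times = features.times
    t_max = times[-1] if len(times) else 0.0
    rows, n_excluded = [], 0
    for onset in onsets:
        if onset + pre_win[0] < 0 or onset + post_win[1] > t_max:
            n_excluded += 1
            continue
        for j, name in enumerate(features.names):
            col = features.values[:, j]
            pre = _window_mean(times, col, onset + pre_win[0], onset + pre_win[1])
            post = _window_mean(times, col, onset + post_win[0], onset + post_win[1])
            rows.append({"onset": onset, "feature": name, "delta": post - pre})
    return pd.DataFrame(rows, columns=["onset", "feature", "delta"]), n_excluded


def feature_change_tests(table: pd.DataFrame) -> dict:
    """Group-level statistics on a feature-change table.

    ``table`` must carry columns ``delta`` and ``feature`` and, for the
    factorial analysis, ``presentation`` (fwd/bwd) and ``event_type``
    (match/mismatch).  Returns per-(group, feature) one-sample t-tests
    against zero, a factorial ANOVA over presentation x event type x feature
    (with the pairwise interactions), and Tukey-HSD-corrected pairwise group
    contrasts per feature.  The ANOVA refuses unbalanced designs with empty
    cells.
    """
    out: dict = {}
    group_cols = [c for c in ("presentation", "event_type") if c in table.columns]
    t_rows = []
    keys = table.groupby(group_cols + ["feature"], sort=True) if group_cols else table.groupby(["feature"])
    for key, sub in keys:
        key = key if isinstance(key, tuple) else (key,)
        d = sub["delta"].to_numpy()
        if len(d) < 2:
            continue
        if np.all(d == d[0]):  # degenerate: zero variance
            t, p = (0.0, 1.0) if d[0] == 0 else (np.inf, 0.0)
        else:
            t, p = stats.ttest_1samp(d, 0.0)
        row = dict(zip(group_cols + ["feature"], key))
        row.update(n=len(d), mean=float(d.mean()), t=float(t), p=float(p))
        t_rows.append(row)
    out["per_group_t"] = pd.DataFrame(t_rows)

    factorial = len(group_cols) == 2 and all(table[c].nunique() >= 2 for c in group_cols)
    if factorial:
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        cells = table.groupby(["presentation", "event_type", "feature"]).size()
        expected = (
            table["presentation"].nunique() * table["event_type"].nunique() * table["feature"].nunique()
        )
        if len(cells) < expected:
            raise ValueError(
                "ANOVA refused: empty presentation x event_type x feature cells; "
                f"found {len(cells)} of {expected} cells"
            )
        model = ols(
            "delta ~ C(presentation) + C(event_type) + C(feature)"
            " + C(presentation):C(event_type) + C(presentation):C(feature)"
            " + C(event_type):C(feature)",
            data=table,
        ).fit()
        out["anova"] = anova_lm(model, typ=2)

        pair_rows = []
        labels = table["presentation"] + "-" + table["event_type"]
        for feat, sub in table.assign(group=labels).groupby("feature"):
            if sub["group"].nunique() < 2:
                continue
            res = pairwise_tukeyhsd(sub["delta"], sub["group"])
            df = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
            df.insert(0, "feature", feat)
            pair_rows.append(df)
        out["pairwise"] = pd.concat(pair_rows, ignore_index=True) if pair_rows else pd.DataFrame()
    return out
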