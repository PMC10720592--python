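"""Behavioral pipeline: switching rates, QC, salience maps, agreement."""

import numpy as np
import pytest

from audisal import (
    SalienceMap,
    TrialResponse,
    average_behavioral_salience,
    fwd_bwd_agreement,
    individual_reaction_times,
    noise_floor,
    quality_control,
    switching_rate,
)
from audisal.behavioral import smooth_map
from audisal.events import SalientEvent


def _trial(trace, pid="p0", scene="s", dt=0.05, direction="fwd"):
    return TrialResponse(pid, scene, direction, "o", np.asarray(trace, dtype=np.int8), dt)


class TestSwitchingRate:
    def test_constant_trace_has_zero_rate(self):
        assert switching_rate(_trial(np.ones(2400))) == 0.0

    def test_transition_count_over_duration(self):
        trace = np.zeros(2400, dtype=int)
        for i in range(10):  # 10 transitions
            trace[200 * (i + 1) :] = 1 - trace[200 * (i + 1)]
        t = _trial(trace)
        assert switching_rate(t) == pytest.approx(10 / 120.0)

    def test_alternating_20hz_trace_is_about_20_per_second(self):
        trace = np.arange(2400) % 2
        assert switching_rate(_trial(trace)) == pytest.approx(2399 / 120.0)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            switching_rate(_trial(np.empty(0)))


class TestQualityControl:
    def test_identical_rates_exclude_no_one(self):
        trials = [
            _trial(np.concatenate([np.zeros(100), np.ones(100)]), pid=f"p{i}", scene=f"s{j}")
            for i in range(5)
            for j in range(10)
        ]
        assert quality_control(trials).excluded == []

    def test_planted_spammers_are_exactly_the_excluded_set(self):
        trials = []
        normal = np.zeros(2400, dtype=int)
        normal[1200:] = 1  # one switch in 120 s: 0.0083/s, well inside
        for i in range(45):
            for j in range(10):
                tr = np.roll(normal, i + j)  # slight variety, same rate
                tr[: i + j] = 0
                trials.append(_trial(tr, pid=f"good{i:02d}", scene=f"s{j}"))
        for i in range(5):
            for j in range(10):
                trials.append(_trial(np.arange(2400) % 2, pid=f"spam{i}", scene=f"s{j}"))
        report = quality_control(trials)
        assert report.excluded == [f"spam{i}" for i in range(5)]

    def test_exactly_five_abnormal_trials_is_retained(self):
        trials = []
        for i in range(20):
            for j in range(10):
                step = np.zeros(2400, dtype=int)
                step[1000 + 10 * j :] = 1
                trials.append(_trial(step, pid=f"p{i:02d}", scene=f"s{j}"))
        # one participant alternates in exactly 5 of 10 trials
        for j in range(5):
            trials = [
                t for t in trials if not (t.participant_id == "p00" and t.scene_id == f"s{j}")
            ]
            trials.append(_trial(np.arange(2400) % 2, pid="p00", scene=f"s{j}"))
        report = quality_control(trials)
        assert report.abnormal_trials.get("p00", 0) == 5
        assert "p00" not in report.excluded


class TestAverageBehavioralSalience:
    def test_single_step_trace_ramps_to_plateau_one_shifted_earlier(self):
        trace = np.zeros(2400, dtype=int)
        trace[int(60 / 0.05) :] = 1  # step at 60 s
        m = average_behavioral_salience([_trial(trace)])
        assert m.values.max() == pytest.approx(1.0)
        assert m.values[: int(55 / 0.064)].max() == 0.0
        # half-rise near 59 s: step shifted earlier by 1 s, symmetric smoothing
        half = np.argmin(np.abs(m.values - 0.5)) * 0.064
        assert abs(half - 59.0) < 0.2

    def test_complementary_traces_average_to_half(self):
        a = np.zeros(2400, dtype=int)
        a[::2] = 1
        m = average_behavioral_salience(
            [_trial(a, pid="p0"), _trial(1 - a, pid="p1")]
        )
        interior = m.values[50:-50]
        assert np.allclose(interior, 0.5)

    def test_impulse_response_is_the_triple_box_kernel(self):
        # one-sample spike on the analysis grid; dt == grid step isolates smoothing
        trace = np.zeros(1875, dtype=int)
        trace[900] = 1
        m = average_behavioral_salience([_trial(trace, dt=0.064)], rt_shift=0.0)
        win = 23  # round(1.5 / 0.064) forced odd
        kernel = np.ones(win) / win
        triple = np.convolve(np.convolve(kernel, kernel), kernel)
        expected = np.zeros(1875)
        expected[900 - (len(triple) // 2) : 900 + len(triple) // 2 + 1] = triple
        assert np.max(np.abs(m.values - expected)) < 1e-12
        assert len(triple) * 0.064 == pytest.approx(4.416, abs=0.2)  # ~3 x 1.5 s support

    def test_smoothing_conserves_interior_mean(self, rng):
        x = rng.uniform(0, 1, 2000)
        sm = smooth_map(x, 0.064, 1.5, 3)
        assert abs(sm[200:-200].mean() - x[200:-200].mean()) < 1e-3

    def test_participant_order_invariance(self, clean_cohort):
        fwd = average_behavioral_salience(clean_cohort)
        rev = average_behavioral_salience(list(reversed(clean_cohort)))
        assert np.array_equal(fwd.values, rev.values)

    def test_mixed_scene_ids_rejected(self):
        with pytest.raises(ValueError):
            average_behavioral_salience([_trial(np.zeros(100)), _trial(np.zeros(100), scene="t")])

    def test_consensus_round_trip_plateau(self, tone_scene, clean_cohort):
        # isolated planted events: bump height ~ consensus (0.6) within 3 SE
        m = average_behavioral_salience(clean_cohort)
        se = np.sqrt(0.6 * 0.4 / len(clean_cohort))
        for onset in tone_scene[2].planted_onsets:
            peak = m.values[int((onset - 0.5) / 0.064) : int((onset + 2.5) / 0.064)].max()
            assert abs(peak - 0.6) <= 3 * se


class TestReactionTimes:
    def test_no_switches_means_non_responsive(self):
        res = individual_reaction_times(
            {"p0": [_trial(np.zeros(600))]},
            {"s": [SalientEvent("s", "fwd", 10.0, 12.0, 0.01, 0.5)]},
        )
        assert not res["p0"]["responsive"]
        assert np.isnan(res["p0"]["mean_rt"])

    def test_switch_at_onset_has_zero_reaction_time(self):
        trace = np.zeros(600, dtype=int)
        trace[int(11.0 / 0.05) :] = 1  # raw switch at 11 s -> shifted to 10 s
        res = individual_reaction_times(
            {"p0": [_trial(trace)]},
            {"s": [SalientEvent("s", "fwd", 10.0, 12.0, 0.01, 0.5)]},
            rt_shift=1.0,
        )
        assert res["p0"]["mean_rt"] == pytest.approx(0.0, abs=0.051)

    def test_simulator_round_trip_rt_near_zero_after_adjustment(self, tone_scene, clean_cohort):
        # with rt_median 0.9 and the 1 s shift, switches land ~0.1 s before
        # the planted onsets on the shifted timeline
        _, _, truth = tone_scene
        events = {
            "tones": [
                SalientEvent("tones", "fwd", o, o + 2.0, 0.01, 0.6) for o in truth.planted_onsets
            ]
        }
        by_p = {t.participant_id: [t] for t in clean_cohort}
        res = individual_reaction_times(by_p, events, rt_shift=1.0)
        rts = [r["mean_rt"] for r in res.values() if r["responsive"]]
        assert abs(np.mean(rts) - (-0.1)) < 0.15


class TestAgreement:
    def test_map_against_its_double_reversal_is_perfectly_correlated(self, rng):
        v = smooth_map(rng.uniform(0, 1, 500), 0.064, 1.5, 3)
        fwd = SalienceMap("s", "fwd", 0.064, v, 10)
        bwd = SalienceMap("s", "bwd", 0.064, v[::-1], 10)
        rho, _ = fwd_bwd_agreement(fwd, bwd)
        assert rho == pytest.approx(1.0)

    def test_monotone_decreasing_transform_gives_minus_one(self, rng):
        v = smooth_map(rng.uniform(0, 1, 400), 0.064, 1.5, 3)
        fwd = SalienceMap("s", "fwd", 0.064, v, 10)
        bwd = SalienceMap("s", "bwd", 0.064, (1 - v**2)[::-1], 10)
        rho, _ = fwd_bwd_agreement(fwd, bwd)
        assert rho == pytest.approx(-1.0)

    def test_length_mismatch_beyond_one_step_rejected(self):
        fwd = SalienceMap("s", "fwd", 0.064, np.linspace(0, 1, 100), 10)
        bwd = SalienceMap("s", "bwd", 0.064, np.linspace(0, 1, 104), 10)
        with pytest.raises(ValueError):
            fwd_bwd_agreement(fwd, bwd)

    def test_independent_maps_have_near_zero_mean_correlation(self, rng):
        # permutation noise floor over 100 random pairings
        rhos = []
        for _ in range(100):
            a = smooth_map(rng.uniform(0, 1, 400), 0.064, 1.5, 3)
            b = smooth_map(rng.uniform(0, 1, 400), 0.064, 1.5, 3)
            rho, _ = fwd_bwd_agreement(
                SalienceMap("s", "fwd", 0.064, a, 1), SalienceMap("s", "bwd", 0.064, b, 1)
            )
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.1


class TestNoiseFloor:
    def _maps(self, rng, n=5):
        fwd, bwd = {}, {}
        for i in range(n):
            fwd[f"s{i}"] = SalienceMap(
                f"s{i}", "fwd", 0.064, smooth_map(rng.uniform(0, 1, 300), 0.064, 1.5, 3), 1
            )
            bwd[f"s{i}"] = SalienceMap(
                f"s{i}", "bwd", 0.064, smooth_map(rng.uniform(0, 1, 300), 0.064, 1.5, 3), 1
            )
        return fwd, bwd

    def test_independent_maps_floor_near_zero(self, rng):
        fwd, bwd = self._maps(rng)
        res = noise_floor(fwd, bwd, n_perm=50, seed=0)
        assert abs(res["mean"]) < 0.1

    def test_single_permutation_reproducible(self, rng):
        fwd, bwd = self._maps(rng)
        a = noise_floor(fwd, bwd, n_perm=1, seed=3)
        b = noise_floor(fwd, bwd, n_perm=1, seed=3)
        assert a == b

    def test_constant_maps_excluded_not_nan(self, rng):
        fwd, bwd = self._maps(rng, n=3)
        fwd["s0"] = SalienceMap("s0", "fwd", 0.064, np.full(300, 0.5), 1)
        res = noise_floor(fwd, bwd, n_perm=10, seed=1)
        assert res["n_excluded"] > 0
        assert np.isfinite(res["mean"])

    def test_single_scene_rejected(self, rng):
        fwd, bwd = self._maps(rng, n=1)
        with pytest.raises(ValueError):
            noise_floor(fwd, bwd)
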