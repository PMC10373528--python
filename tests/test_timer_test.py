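"""Shuffle null constructions, one-sided KS testing and verdict logic."""
from itertools import permutations

import numpy as np
import pytest
from scipy.stats import ks_2samp

from stripetime.boundary import classify_boundary
from stripetime.config import SimConfig
from stripetime.datatypes import ActivationEvent, BoundaryAssignment
from stripetime.synthetic import simulate_dataset
from stripetime.timer_test import (
    extract_first_burst_events,
    ks_one_sided,
    run_timer_threshold_analysis,
    shuffle_levels_to_available_times,
    shuffle_times_to_available_levels,
)
from stripetime.traces import preprocess_embryo
from tests.conftest import make_embryo


def _toy_events(offsets=(0.0, 30.0, 60.0), obs_t=(2.0, 5.0, 8.0), slope=1.0):
    """Monotone toy traces trace_i(t) = offset_i + t on t = 0..9 min."""
    t = np.arange(10.0)
    traces = np.array([o + slope * t for o in offsets])
    events = []
    for i, ti in enumerate(obs_t):
        k = int(ti)
        events.append(ActivationEvent(i, None, float(t[k]), float(traces[i, k])))
    return events, traces, t


class TestExtractEvents:
    def test_first_burst_wins(self):
        t = -20 + np.arange(91) / 3.0
        spot = np.zeros(91)
        spot[t >= -18] = 1.0
        spot[(t > -16) & (t < -10)] = 0.0  # second burst from -10
        protein = {0: 1.0 + 0.01 * np.arange(91)}
        embryo = make_embryo(protein=protein, spot={0: spot}, t=t)
        embryo.computed_gastrulation = 0.0
        a = BoundaryAssignment(classes={0: "PB"})
        events = extract_first_burst_events(embryo, a)
        assert len(events) == 1
        assert events[0].t_first == pytest.approx(-18.0, abs=1 / 3)
        k = embryo.frame_of(-18.0)
        assert events[0].level == pytest.approx(protein[0][k])

    def test_silent_pb_contributes_nothing(self):
        embryo = make_embryo(protein={0: np.ones(91)})
        embryo.computed_gastrulation = 0.0
        a = BoundaryAssignment(classes={0: "PB"})
        assert extract_first_burst_events(embryo, a) == []

    def test_post_gastrulation_events_excluded_unless_engrailed(self):
        t = -20 + np.arange(91) / 3.0
        spot = np.zeros(91)
        spot[t >= 5.0] = 1.0
        embryo = make_embryo(protein={0: np.ones(91)}, spot={0: spot}, t=t)
        embryo.computed_gastrulation = 0.0
        a = BoundaryAssignment(classes={0: "PB"})
        assert extract_first_burst_events(embryo, a, pre_gastrulation_only=True) == []
        assert len(extract_first_burst_events(embryo, a, pre_gastrulation_only=False)) == 1

    def test_timer_mean_recovered_from_generator(self):
        cfg = SimConfig(construct="autoregulatory", rng_seed=2)
        times = []
        for embryo, _ in simulate_dataset(cfg, 3, base_seed=31):
            processed = preprocess_embryo(embryo, background=cfg.background)
            assignment = classify_boundary(processed)
            times += [e.t_first for e in extract_first_burst_events(processed, assignment)]
        times = np.array(times)
        assert len(times) > 100
        se = times.std() / np.sqrt(len(times))
        assert abs(times.mean() - cfg.timer_mean) <= 2 * se + 1 / 3


class TestShuffleLevelsToTimes:
    def test_exhaustive_oracle_multiset_equality(self):
        events, traces, t = _toy_events()
        got, rounds = shuffle_levels_to_available_times(
            events, traces, t, tolerance=0.01, max_perm=10_000,
            rng=np.random.default_rng(0),
        )
        assert rounds == 6
        oracle = []
        levels = [e.level for e in events]
        for perm in permutations(range(3)):
            for i, j in enumerate(perm):
                for k in range(len(t)):
                    if abs(traces[i, k] - levels[j]) <= 0.01 * levels[j]:
                        oracle.append(t[k])
        np.testing.assert_allclose(np.sort(got), np.sort(oracle))

    def test_monotone_trace_yields_one_match_per_round(self):
        events, traces, t = _toy_events(offsets=(5.0, 5.0), obs_t=(2.0, 8.0))
        got, rounds = shuffle_levels_to_available_times(
            events, traces, t, tolerance=0.01, rng=np.random.default_rng(0)
        )
        assert rounds == 2
        assert len(got) == 2 * len(events)

    def test_unreachable_level_registers_nothing(self):
        events, traces, t = _toy_events(offsets=(0.0, 30.0), obs_t=(2.0, 5.0))
        events[1] = ActivationEvent(1, None, 5.0, 1000.0)  # far above both traces
        got, rounds = shuffle_levels_to_available_times(
            events, traces, t, tolerance=0.01, rng=np.random.default_rng(0)
        )
        # the huge level matches nowhere; the small level only matches its
        # own (low-offset) trace, so of 2 exhaustive rounds only one frame
        # is ever registered
        assert rounds == 2
        assert len(got) == 1

    def test_infinite_tolerance_is_unconstrained_resampling(self):
        events, traces, t = _toy_events()
        got, rounds = shuffle_levels_to_available_times(
            events, traces, t, tolerance=1e9, rng=np.random.default_rng(0)
        )
        assert len(got) == rounds * len(events)
        assert t[0] in got and t[-1] in got  # every frame is reachable

    def test_fewer_than_two_events_rejected(self):
        events, traces, t = _toy_events(offsets=(0.0,), obs_t=(2.0,))
        with pytest.raises(ValueError):
            shuffle_levels_to_available_times(events, traces, t)


class TestShuffleTimesToLevels:
    def test_exhaustive_oracle_multiset_equality(self):
        events, traces, t = _toy_events()
        got, rounds = shuffle_times_to_available_levels(
            events, traces, t, target_count=18, rng=np.random.default_rng(0)
        )
        oracle = []
        for perm in permutations(range(3)):
            for i, j in enumerate(perm):
                k = int(events[j].t_first)
                oracle.append(traces[i, k])
        np.testing.assert_allclose(np.sort(got), np.sort(oracle))

    def test_identical_traces_are_permutation_invariant(self):
        events, traces, t = _toy_events(offsets=(4.0, 4.0, 4.0))
        got, _ = shuffle_times_to_available_levels(
            events, traces, t, target_count=18, rng=np.random.default_rng(1)
        )
        expected = {traces[0, int(e.t_first)] for e in events}
        assert set(np.round(got, 9)) == set(np.round(list(expected), 9))

    def test_zero_target_flagged_empty(self, caplog):
        events, traces, t = _toy_events()
        got, rounds = shuffle_times_to_available_levels(
            events, traces, t, target_count=0, rng=np.random.default_rng(0)
        )
        assert len(got) == 0 and rounds == 0
        assert "target_count" in caplog.text

    def test_counts_stay_comparable_to_target(self):
        events, traces, t = _toy_events()
        for target in (6, 12, 18):
            got, _ = shuffle_times_to_available_levels(
                events, traces, t, target_count=target,
                rng=np.random.default_rng(2),
            )
            assert abs(len(got) - target) <= 0.05 * target + len(events)
        # a target beyond the permutation budget exhausts all n! rounds
        got, rounds = shuffle_times_to_available_levels(
            events, traces, t, target_count=60, rng=np.random.default_rng(2)
        )
        assert rounds == 6 and len(got) == 18


class TestKSOneSided:
    def test_identical_samples_do_not_reject(self):
        x = np.linspace(0, 1, 50)
        res = ks_one_sided(x, x.copy())
        assert res.d == 0.0 and res.p == 1.0 and not res.reject

    def test_stochastically_smaller_null_rejects(self):
        rng = np.random.default_rng(0)
        obs = rng.uniform(10, 11, 50)
        avail = rng.uniform(0, 1, 50)
        res = ks_one_sided(obs, avail)
        assert res.d == 1.0 and res.reject

    def test_matches_ecdf_sweep_oracle_and_scipy(self):
        rng = np.random.default_rng(3)
        obs = rng.normal(0.2, 1.0, 37)
        avail = rng.normal(0.0, 1.3, 53)
        res = ks_one_sided(obs, avail)
        pooled = np.concatenate([obs, avail])
        d_oracle = max(
            np.mean(avail <= x) - np.mean(obs <= x) for x in pooled
        )
        assert res.d == pytest.approx(d_oracle)
        ref = ks_2samp(avail, obs, alternative="greater", method="asymp")
        assert res.d == pytest.approx(ref.statistic)
        # scipy applies a continuity correction on top of the plain
        # one-sided asymptotic formula used here
        assert res.p == pytest.approx(ref.pvalue, abs=0.02)

    def test_asymptotic_formula(self):
        rng = np.random.default_rng(4)
        obs, avail = rng.normal(size=40), rng.normal(size=60)
        res = ks_one_sided(obs, avail)
        m, n = 40, 60
        assert res.p == pytest.approx(
            min(1.0, np.exp(-2 * res.d**2 * m * n / (m + n)))
        )

    def test_exact_permutation_p_close_to_asymptotic(self):
        rng = np.random.default_rng(5)
        obs = rng.normal(0.3, 1, 30)
        avail = rng.normal(0, 1, 200)
        asym = ks_one_sided(obs, avail)
        exact = ks_one_sided(obs, avail, method="exact", n_exact=2000,
                             rng=np.random.default_rng(6))
        assert exact.p == pytest.approx(asym.p, abs=0.08)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            ks_one_sided(np.array([1.0]), np.array([1.0, 2.0]))


class TestVerdicts:
    @pytest.mark.parametrize("model", ["timer", "threshold"])
    def test_generating_model_recovered(self, model):
        cfg = SimConfig(construct="autoregulatory", activation_model=model,
                        rng_seed=0)
        pairs = []
        for embryo, _ in simulate_dataset(cfg, 6, base_seed=51):
            processed = preprocess_embryo(embryo, background=cfg.background)
            pairs.append((processed, classify_boundary(processed)))
        report = run_timer_threshold_analysis(pairs, stripe=2, seed=5)
        assert report.verdict == f"{model}-consistent"
        assert report.null.tolerance == 0.05
        # the two null lists stay comparable in size
        assert (
            abs(len(report.null.available_levels) - len(report.null.available_times))
            <= 0.05 * len(report.null.available_times)
            + len(report.null.observed_times)
        )

    def test_matching_nulls_are_inconclusive(self):
        # observed lists equal to their nulls: neither test rejects
        rng = np.random.default_rng(7)
        x = rng.normal(size=100)
        ks_t = ks_one_sided(x, x.copy())
        ks_l = ks_one_sided(x, x.copy())
        assert not ks_t.reject and not ks_l.reject
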