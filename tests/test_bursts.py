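"""Burst calling, derived quantity traces, aligned ensembles, dot-intensity
modes and heat-shock analysis."""
import numpy as np
import pytest

from stripetime.bursts import (
    call_bursts,
    classify_mode,
    derive_quantity_trace,
    dot_intensity_modes,
    heat_shock_group,
    heat_shock_phenotype,
    kde_mode,
    realign_and_average,
)
from stripetime.config import HeatShockParams, SimConfig
from stripetime.datatypes import BoundaryAssignment, Burst
from stripetime.synthetic import simulate_embryo
from tests.conftest import make_embryo


class TestCallBursts:
    def test_run_lengths_and_means(self):
        bursts = call_bursts(np.array([0, 2, 2, 0, 0, 0, 3, 0], float), 20.0)
        assert len(bursts) == 2
        assert bursts[0].duration == pytest.approx(2 / 3)  # 40 s
        assert bursts[1].duration == pytest.approx(1 / 3)  # 20 s
        assert bursts[0].mean_intensity == 2.0
        assert bursts[1].mean_intensity == 3.0

    def test_silent_trace(self):
        assert call_bursts(np.zeros(20), 20.0) == []

    def test_always_on_trace_is_one_burst(self):
        bursts = call_bursts(np.full(30, 1.5), 20.0)
        assert len(bursts) == 1
        assert (bursts[0].start, bursts[0].end) == (0, 29)
        assert bursts[0].duration == pytest.approx(10.0)


class TestDerivedQuantities:
    def test_burst_duration_trace(self):
        spot = np.zeros(40)
        spot[5:20] = 1.0  # 15 frames = 5 min at 20 s
        out = derive_quantity_trace(spot, "burst_duration", 20.0)
        assert np.all(out[5:20] == pytest.approx(5.0))
        assert np.all(np.isnan(out[:5])) and np.all(np.isnan(out[20:]))

    def test_activation_marks_only_first_frames(self):
        spot = np.array([0, 1, 1, 0, 0, 0, 2, 2, 2, 0], float)
        out = derive_quantity_trace(spot, "activation_probability", 20.0)
        assert out.sum() == len(call_bursts(spot, 20.0))
        np.testing.assert_array_equal(np.flatnonzero(out), [1, 6])

    def test_cov_zero_for_constant_burst(self):
        spot = np.full(30, 2.0)
        out = derive_quantity_trace(spot, "cov_paper", 20.0)
        assert out[15] == pytest.approx(0.0)

    def test_cov_is_window_variance_over_mean(self):
        rng = np.random.default_rng(0)
        spot = rng.uniform(1, 2, 30)
        out = derive_quantity_trace(spot, "cov_paper", 20.0)
        seg = spot[10:15]  # centered 5-frame window at index 12
        assert out[12] == pytest.approx(seg.var() / seg.mean())

    def test_unknown_quantity_rejected(self):
        with pytest.raises(ValueError):
            derive_quantity_trace(np.zeros(5), "banana", 20.0)

    def test_active_fraction_brute_force_recount(self, endogenous_pairs):
        embryo, assignment, _ = endogenous_pairs[0]
        ens = realign_and_average([(embryo, assignment)], "active_fraction",
                                  cls="PB", min_nuclei=1)
        # recount at t = -10 min by hand
        j = int(np.argmin(np.abs(ens.t_rel + 10.0)))
        dt = embryo.dt_min
        active = total = 0
        for p in assignment.pb:
            g = embryo.local_movement_times[p]
            k = int(round((-10.0 + round(g / dt) * dt - embryo.t[0]) / dt))
            if 0 <= k < len(embryo.t):
                total += 1
                active += embryo.traces[p].spot[k] > 0
        assert 0.0 <= ens.mean[j] <= 1.0
        assert ens.mean[j] == pytest.approx(active / total)


class TestRealign:
    def _assignment(self, ids):
        return BoundaryAssignment(classes={i: "PB" for i in ids})

    def test_identical_traces_average_to_themselves(self):
        t = -10 + np.arange(61) / 3.0
        protein = {i: np.sin(t / 3.0) + 2 for i in range(30)}
        embryo = make_embryo(protein=protein, t=t)
        embryo.computed_gastrulation = 0.0
        embryo.local_movement_times = {i: 0.0 for i in range(30)}
        ens = realign_and_average([(embryo, self._assignment(range(30)))],
                                  "protein", cls="PB", smooth=False)
        j0 = int(np.argmin(np.abs(ens.t_rel - t[0])))
        np.testing.assert_allclose(ens.mean[j0 : j0 + 61], protein[0], atol=1e-9)
        np.testing.assert_allclose(ens.sd[j0 : j0 + 61], 0.0, atol=1e-12)

    @pytest.mark.parametrize("n_nuclei,masked", [(24, True), (25, False)])
    def test_minimum_participation_masking(self, n_nuclei, masked):
        t = -10 + np.arange(61) / 3.0
        embryo = make_embryo(protein={i: np.ones(61) for i in range(n_nuclei)}, t=t)
        embryo.local_movement_times = {i: 0.0 for i in range(n_nuclei)}
        ens = realign_and_average([(embryo, self._assignment(range(n_nuclei)))],
                                  "protein", cls="PB", smooth=False)
        assert np.isnan(ens.at(0.0)) == masked

    def test_dot_quantities_masked_below_three_dots(self):
        t = -10 + np.arange(61) / 3.0
        spot = {i: np.zeros(61) for i in range(30)}
        for i in range(2):  # only two active dots at frame 30
            spot[i][30] = 1.0
        for i in range(5):
            spot[i][40] = 1.0  # five active dots at frame 40
        embryo = make_embryo(spot=spot, t=t)
        embryo.local_movement_times = {i: 0.0 for i in range(30)}
        ens = realign_and_average([(embryo, self._assignment(range(30)))],
                                  "dot_intensity", cls="PB")
        assert np.isnan(ens.at(t[30]))
        assert ens.at(t[40]) == pytest.approx(1.0)

    def test_shifted_ramps_align_to_common_ramp(self):
        t = np.arange(91) / 3.0
        ramp = t.copy()
        # nucleus 1 is delayed by 2 min and gastrulates 2 min later; after
        # alignment both contribute the same ramp in relative time
        protein = {0: ramp, 1: ramp - 2.0}
        embryo = make_embryo(protein=protein, t=t, manual_gastrulation=10.0)
        embryo.local_movement_times = {0: 10.0, 1: 12.0}
        ens = realign_and_average([(embryo, self._assignment([0, 1]))],
                                  "protein", cls="PB", min_nuclei=2, smooth=False)
        both = ens.n >= 2
        np.testing.assert_allclose(ens.sd[both], 0.0, atol=1e-9)
        np.testing.assert_allclose(ens.mean[both] - (ens.t_rel[both] + 10.0), 0.0,
                                   atol=1e-9)

    def test_ab_traces_shifted_by_partner_pb(self):
        t = np.arange(31) / 3.0
        protein = {0: np.ones(31), 1: 2 * np.ones(31)}
        embryo = make_embryo(protein=protein, t=t, manual_gastrulation=5.0)
        embryo.local_movement_times = {1: 5.0}
        a = BoundaryAssignment(classes={0: "AB", 1: "PB"}, ab_partner={0: 1})
        ens = realign_and_average([(embryo, a)], "protein", cls="AB",
                                  min_nuclei=1, smooth=False)
        assert ens.at(0.0) == pytest.approx(1.0)


class TestDotIntensityModes:
    def test_two_separated_gaussians(self):
        rng = np.random.default_rng(0)
        res = dot_intensity_modes(
            {"AB": rng.normal(0.4, 0.08, 400), "PB": rng.normal(1.1, 0.12, 300)}
        )
        assert 0.4 < res.threshold < 1.1
        assert not res.flagged
        assert res.mode["AB"] == pytest.approx(0.4, abs=0.05)
        assert res.mode["PB"] == pytest.approx(1.1, abs=0.07)

    def test_identical_distributions_fall_back_flagged(self):
        rng = np.random.default_rng(1)
        s = rng.normal(0.7, 0.1, 200)
        res = dot_intensity_modes({"AB": s, "PB": s.copy()})
        assert res.flagged

    def test_kernel_width_comes_from_smaller_class(self):
        rng = np.random.default_rng(2)
        small = rng.normal(0.4, 0.08, 50)
        big = rng.normal(1.1, 0.12, 5000)
        res = dot_intensity_modes({"AB": small, "PB": big})
        from stripetime.bursts import freedman_diaconis_width

        assert res.kernel_width == pytest.approx(freedman_diaconis_width(small))

    def test_generator_modes_recovered_within_tolerance(self, endogenous_pairs):
        cfg = SimConfig()
        early, late = [], []
        for embryo, assignment, truth in endogenous_pairs:
            act = truth.nuclei.set_index("nucleus_id")["activation_time"]
            for nid in assignment.pb + assignment.ab:
                for b in call_bursts(embryo.traces[nid].spot, embryo.frame_interval,
                                     nid, embryo.t):
                    if b.t_start < cfg.divergence_time:
                        early.append(b.mean_intensity)
                    a = act.get(nid, np.nan)
                    if assignment.classes[nid] == "PB" and np.isfinite(a) and b.t_start >= a:
                        late.append(b.mean_intensity)
        assert kde_mode(np.array(early)) == pytest.approx(
            cfg.low_mode.mean_intensity, abs=0.1)
        assert kde_mode(np.array(late)) == pytest.approx(
            cfg.high_mode.mean_intensity, abs=0.1)

    def test_mode_classification_accuracy_on_ground_truth(self, endogenous_pairs):
        # the intersection threshold comes from the late time window, where
        # the PB distribution is dominated by the high mode
        cfg = SimConfig()
        correct = total = 0
        for embryo, assignment, truth in endogenous_pairs:
            samples = {"AB": [], "PB": []}
            by_nucleus = {}
            for nid in assignment.pb + assignment.ab:
                bs = call_bursts(embryo.traces[nid].spot, embryo.frame_interval,
                                 nid, embryo.t)
                by_nucleus[nid] = bs
                for b in bs:
                    cls = assignment.classes[nid]
                    if cls == "AB" or (cls == "PB" and b.t_start >= cfg.timer_mean):
                        samples[cls].append(b.mean_intensity)
            thr = dot_intensity_modes(
                {k: np.array(v) for k, v in samples.items()}).threshold
            truth_bursts = truth.bursts
            for nid, bs in by_nucleus.items():
                tb = truth_bursts[truth_bursts["nucleus_id"] == nid]
                for b in bs:
                    hit = tb[(tb["start"] <= b.start) & (tb["end"] >= b.start)]
                    if len(hit) != 1:
                        continue
                    total += 1
                    correct += classify_mode(b, thr) == hit["mode"].iloc[0]
        assert total > 2000
        assert correct / total >= 0.95


class TestClassifyMode:
    def test_threshold_rule(self):
        b = Burst(0, 0, 2, 0.0, 0.7, 1.0, mean_intensity=0.4)
        assert classify_mode(b, 0.7) == "low"
        b.mean_intensity = 1.1
        assert classify_mode(b, 0.7) == "high"
        b.mean_intensity = 0.7  # exactly at threshold: strict inequality
        assert classify_mode(b, 0.7) == "low"


class TestHeatShock:
    def test_group_bins(self):
        assert heat_shock_group(-52.0) == "early"
        assert heat_shock_group(-20.0) == "mid"
        assert heat_shock_group(-9.0) == "late"
        assert heat_shock_group(-30.0) == "mid"
        assert heat_shock_group(0.0) == "late"

    def test_out_of_range_start_rejected(self):
        with pytest.raises(ValueError):
            heat_shock_group(-75.0)
        with pytest.raises(ValueError):
            heat_shock_group(5.0)

    @pytest.mark.parametrize("start,expect_flag", [(-52.0, False), (-9.0, True)])
    def test_phenotype_surrogate_on_generator(self, start, expect_flag):
        from stripetime.boundary import classify_boundary
        from stripetime.traces import preprocess_embryo

        cfg = SimConfig(construct="heatshock",
                        heat_shock=HeatShockParams(start=start), rng_seed=4)
        embryo, truth = simulate_embryo(cfg)
        processed = preprocess_embryo(embryo, background=cfg.background)
        stripe_truth = set(truth.ids_of("PB")) | set(truth.ids_of("interior"))
        assignment = classify_boundary(
            processed, acceptor=lambda nid, diag: nid in stripe_truth
        )
        group, flag, label = heat_shock_phenotype(processed, assignment, start)
        assert label == "surrogate"
        assert group == ("early" if start < -30 else "late")
        assert flag == expect_flag
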