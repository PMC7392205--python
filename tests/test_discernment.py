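"""Tests of schedule generation, optimal response, and tracking scores."""

import numpy as np
import pytest

from thquorum import (
    ScheduleConfig,
    apc_constants,
    optimal_response,
    random_apc_timecourse,
    tracking_performance,
)
from thquorum.deterministic import TH1, TH2
from thquorum.discernment import DEFAULT_SCHEDULE_CONFIG
from thquorum.schedule import APCSchedule


class TestRandomTimecourse:
    def test_same_seed_identical(self, params):
        a = random_apc_timecourse(7, params)
        b = random_apc_timecourse(7, params)
        assert np.array_equal(a.t_start, b.t_start)
        assert np.array_equal(a.apc1, b.apc1)

    def test_covers_horizon_contiguously(self, params):
        for seed in range(20):
            s = random_apc_timecourse(seed, params)
            assert s.t_start[0] == 0.0
            assert s.horizon == DEFAULT_SCHEDULE_CONFIG.horizon

    def test_single_segment_config_gives_constant_schedule(self, params):
        cfg = ScheduleConfig(n_segments_range=(1, 1), initial_bias_choices=(1.0,))
        s = random_apc_timecourse(0, params, cfg)
        assert len(s.t_start) == 1
        assert s.bias(100.0) == 1.0

    def test_zero_horizon_rejected(self, params):
        with pytest.raises(ValueError, match="horizon"):
            random_apc_timecourse(0, params, ScheduleConfig(horizon=0.0))

    def test_collection_contains_transient_and_sustained_switches(self, params):
        """200 draws include both ignore-worthy and obey-worthy changes."""
        tau = 48.0
        n_obeyed = n_complete_runs = 0
        for seed in range(200):
            s = random_apc_timecourse(seed, params)
            opt = optimal_response(s, tau)
            n_obeyed += len(opt.switches) > 0
            bias = s.apc1 / np.maximum(s.apc1 + s.apc2, 1e-30)
            n_complete_runs += np.sum(np.isin(bias, (0.0, 1.0))) > 1
        assert n_obeyed >= 10            # sustained complete switches occur
        assert n_complete_runs - n_obeyed >= 10  # and transient/unobeyed ones


class TestOptimalResponse:
    def _sched(self, params, segments):
        """segments: list of (duration, bias)."""
        durs = [d for d, _ in segments]
        breaks = np.concatenate([[0.0], np.cumsum(durs)])
        return APCSchedule.from_biases(
            breaks, np.array([b for _, b in segments]), 30.0, params
        )

    def test_constant_instruction_constant_target(self, params):
        s = self._sched(params, [(500.0, 1.0)])
        opt = optimal_response(s, 48.0)
        assert opt.initial_label == TH1 and opt.switches == ()

    def test_sustained_complete_switch_obeyed_at_tau(self, params):
        s = self._sched(params, [(100.0, 1.0), (400.0, 0.0)])
        opt = optimal_response(s, 48.0)
        assert opt.switches == ((148.0, TH2),)

    def test_short_excursion_ignored(self, params):
        s = self._sched(params, [(100.0, 1.0), (24.0, 0.0), (376.0, 1.0)])
        assert optimal_response(s, 48.0).switches == ()

    def test_incomplete_change_ignored_regardless_of_duration(self, params):
        s = self._sched(params, [(100.0, 1.0), (400.0, 0.25)])
        assert optimal_response(s, 48.0).switches == ()

    def test_double_switch(self, params):
        s = self._sched(params, [(100.0, 0.0), (150.0, 1.0), (250.0, 0.0)])
        opt = optimal_response(s, 50.0)
        assert opt.initial_label == TH2
        assert opt.switches == ((150.0, TH1), (300.0, TH2))

    def test_zero_instruction_everywhere_rejected(self, params):
        s = APCSchedule([0.0], [500.0], [0.0], [0.0])
        with pytest.raises(ValueError, match="zero APC"):
            optimal_response(s, 48.0)

    def test_labels_at_respects_switch_times(self, params):
        s = self._sched(params, [(100.0, 1.0), (400.0, 0.0)])
        opt = optimal_response(s, 48.0)
        lab = opt.labels_at(np.array([0.0, 147.9, 148.0, 400.0]))
        assert list(lab) == [TH1, TH1, TH2, TH2]


class TestTrackingPerformance:
    def _const_opt(self, label):
        from thquorum.discernment import OptimalResponse

        return OptimalResponse(label, (), 48.0)

    def test_pinned_committed_path_scores_one_or_zero(self):
        times = np.linspace(0, 500, 50)
        theta = np.full((1, 50), 0.95)
        assert tracking_performance(theta, times, self._const_opt(TH1))["pooled"] == 1.0
        assert tracking_performance(theta, times, self._const_opt(TH2))["pooled"] == 0.0

    def test_mixed_balance_disagrees_with_any_target(self):
        times = np.linspace(0, 500, 20)
        theta = np.full((1, 20), 0.5)
        for lab in (TH1, TH2):
            assert tracking_performance(theta, times, self._const_opt(lab))["pooled"] == 0.0

    def test_relabel_symmetry(self, params):
        """Swapping Th1<->Th2 in both paths and target leaves scores unchanged."""
        rng = np.random.default_rng(0)
        times = np.linspace(0, 500, 100)
        theta = rng.uniform(0, 1, (10, 100))
        s = APCSchedule.from_biases(
            np.array([0.0, 200.0, 500.0]), np.array([1.0, 0.0]), 30.0, params
        )
        s_sw = APCSchedule.from_biases(
            np.array([0.0, 200.0, 500.0]), np.array([0.0, 1.0]), 30.0, params
        )
        a = tracking_performance(theta, times, optimal_response(s, 48.0))["pooled"]
        b = tracking_performance(1 - theta, times, optimal_response(s_sw, 48.0))["pooled"]
        assert a == pytest.approx(b)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tracking_performance(
                np.empty((0, 10)), np.linspace(0, 1, 10), self._const_opt(TH1)
            )


class TestZeroNoiseCannotObey:
    def test_ode_quorum_ignores_sustained_complete_switch(self, params):
        """Without noise the quorum cannot track even an obey-worthy switch."""
        from thquorum import integrate_ode
        from thquorum.deterministic import balance_index

        apc1 = apc_constants(30, 0, params)
        apc2 = apc_constants(0, 30, params)
        sched = APCSchedule.switch(apc1, apc2, 200.0, 500.0)
        traj = integrate_ode(
            np.array([0.1, 0.1, 0.0, 0.0]), params, 1e9, sched, t_span=(0, 500)
        )
        assert balance_index(traj.final) > 0.8  # still Th1: switch not obeyed
        opt = optimal_response(sched, 48.0)
        theta = balance_index(traj.y)[None, :]
        score = tracking_performance(theta, traj.t, opt)["pooled"]
        assert score < 1.0


class TestNoiseEnablesObedience:
    def _switch_schedules(self, params, n_needed=20, tau=48.0):
        """Random schedules that contain at least one obey-worthy switch."""
        out = []
        seed = 0
        while len(out) < n_needed and seed < 500:
            s = random_apc_timecourse(seed, params)
            if optimal_response(s, tau).switches:
                out.append(s)
            seed += 1
        return out

    def test_calibrated_noise_beats_zero_noise_on_switch_schedules(self, params):
        """On schedules with sustained complete switches, the calibrated
        noise setting (low TF, high CY volatility) outperforms the
        deterministic quorum, path-for-path."""
        import numpy as np

        from thquorum.discernment import _score_cell

        schedules = self._switch_schedules(params)
        assert len(schedules) >= 20
        seeds = np.random.SeedSequence((0, 1))
        kw = dict(
            schedules=schedules, params=params, taus=(48.0,), n_paths=20,
            seed_seq=seeds, dt=0.02, record_every=2.0, rho=1e9,
        )
        zero = _score_cell(0.0, 0.0, **kw)[48.0]
        calibrated = _score_cell(0.02, 1.0, **kw)[48.0]
        assert calibrated > zero

    def test_high_noise_reduces_dwell_consistency(self, params):
        """Beyond the useful range, volatility erodes how long a committed
        quorum dwells on its side."""
        import numpy as np

        from thquorum import apc_constants, run_ensemble
        from thquorum.deterministic import balance_index

        apc = apc_constants(30, 0, params)
        dwell = {}
        for n in (0.3, 1.0):
            ens = run_ensemble(
                30, np.array([0.1, 0.1, 0.0, 0.0]), params.with_noise(n),
                1e9, apc, t_span=(0.0, 300.0), dt=0.02, master_seed=17,
            )
            theta = balance_index(ens.paths[:, ens.t > 100, :])
            dwell[n] = np.mean(theta > 0.8)
        assert dwell[1.0] < dwell[0.3]
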