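"""Tests of ODE integration, equilibrium location and bifurcation scans."""

import numpy as np
import pytest

from thquorum import (
    IN_VITRO_DENSITY,
    IN_VIVO_DENSITY,
    ZERO_APC,
    apc_constants,
    apply_density,
    balance_index,
    drift,
    find_equilibria,
    integrate_ode,
    mixed_equilibrium,
    quorum_density,
    reversal_window,
    scale_decomposition,
    secretion_bifurcation_scan,
)
from thquorum.deterministic import _leading_eig
from thquorum.schedule import APCSchedule

NAIVE = np.array([0.1, 0.1, 0.0, 0.0])


class TestIntegrateODE:
    def test_stable_equilibrium_is_fixed(self, params):
        x = mixed_equilibrium(params, IN_VITRO_DENSITY)
        traj = integrate_ode(x, params, IN_VITRO_DENSITY, t_span=(0, 200))
        np.testing.assert_allclose(traj.final, x, rtol=1e-6)

    def test_symmetric_initial_state_stays_on_symmetric_manifold(self, params):
        traj = integrate_ode(NAIVE, params, IN_VITRO_DENSITY, t_span=(0, 300))
        np.testing.assert_allclose(traj.y[:, 0], traj.y[:, 1], rtol=1e-8)
        np.testing.assert_allclose(traj.y[:, 2], traj.y[:, 3], rtol=1e-7, atol=1e-12)

    def test_invitro_long_run_reaches_mixed_equilibrium(self, params):
        x = mixed_equilibrium(params, IN_VITRO_DENSITY)
        traj = integrate_ode(NAIVE, params, IN_VITRO_DENSITY, t_span=(0, 2000))
        np.testing.assert_allclose(traj.final, x, rtol=1e-5)

    def test_nonnegative_throughout(self, params):
        traj = integrate_ode(
            NAIVE, params, IN_VIVO_DENSITY,
            apc_constants(6, 4, params), t_span=(0, 300),
        )
        assert np.all(traj.y >= 0)

    def test_schedule_must_cover_span(self, params):
        sched = APCSchedule.constant(ZERO_APC, 10.0)
        with pytest.raises(ValueError, match="cover"):
            integrate_ode(NAIVE, params, 2e6, sched, t_span=(0, 50))

    def test_trajectory_csv_roundtrip(self, params, tmp_path):
        traj = integrate_ode(NAIVE, params, 2e6, t_span=(0, 20))
        traj.write(tmp_path / "traj.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "traj.csv")
        np.testing.assert_allclose(
            df[["TF1", "TF2", "CY1", "CY2"]].to_numpy(), traj.y
        )
        assert (tmp_path / "traj.meta.json").exists()


def brute_force_attractors(params, rho, scale, grid_pts=5, t_end=3000.0):
    """Oracle: cluster endpoints of integrations from a dense IC grid."""
    tf = np.geomspace(0.05, 50, grid_pts)
    # offset the TF2 grid so no start sits exactly on the symmetric invariant
    # manifold (from there the ODE would ride into the mixed saddle)
    tf2_vals = tf * 1.13
    cy = np.geomspace(1e-3, 5, grid_pts)
    ends = []
    for T1 in tf:
        for T2 in tf2_vals:
            for C1 in cy[:: max(grid_pts // 2, 1)]:
                for C2 in cy[:: max(grid_pts // 2, 1)]:
                    traj = integrate_ode(
                        np.array([T1, T2, C1, C2]), params, rho,
                        secretion_scale=scale, t_span=(0, t_end),
                        reporting_step=t_end / 4,
                    )
                    ends.append(traj.final)
    ends = np.array(ends)
    clusters: list[np.ndarray] = []
    for e in ends:
        for c in clusters:
            if np.max(np.abs(e - c)) < 1e-3 * (1 + np.max(np.abs(c))):
                break
        else:
            clusters.append(e)
    return np.array(clusters)


class TestFindEquilibria:
    def test_toggle_without_secretion_is_bistable(self, params):
        eq = find_equilibria(params, IN_VITRO_DENSITY, secretion_scale=0.0)
        assert len(eq) == 3
        assert eq.n_stable == 2
        theta = balance_index(eq.states)
        stable_theta = np.sort(theta[eq.stable])
        assert stable_theta[0] < 0.2 and stable_theta[1] > 0.8
        unstable = eq.states[~eq.stable][0]
        assert unstable[0] == pytest.approx(unstable[1], rel=1e-6)

    def test_equilibrium_set_closed_under_index_swap(self, params):
        eq = find_equilibria(params, IN_VIVO_DENSITY)
        swapped = eq.states[:, [1, 0, 3, 2]]
        for s in swapped:
            dist = np.min(np.max(np.abs(eq.states - s), axis=1) / (1 + np.abs(s).max()))
            assert dist < 1e-5

    def test_invivo_mixed_unstable_two_polarized_stable(self, params):
        eq = find_equilibria(params, IN_VIVO_DENSITY)
        assert eq.n_stable == 2
        theta = balance_index(eq.states)
        assert np.all((theta[eq.stable] < 0.2) | (theta[eq.stable] > 0.8))
        mixed = eq.states[np.abs(theta - 0.5) < 1e-6]
        assert len(mixed) == 1
        assert not eq.stable[np.abs(theta - 0.5) < 1e-6][0]

    def test_invitro_single_stable_mixed(self, params):
        eq = find_equilibria(params, IN_VITRO_DENSITY)
        assert eq.n_stable == 1
        th = balance_index(eq.stable_states[0])
        assert 0.4 < th < 0.6

    def test_roots_satisfy_drift_tolerance(self, params):
        eq = find_equilibria(params, IN_VIVO_DENSITY)
        ctx = apply_density(params, IN_VIVO_DENSITY)
        for x in eq.states:
            d = drift(x, ctx, params)
            assert np.max(np.abs(d)) < 1e-8 * (1 + np.max(np.abs(x)))

    @pytest.mark.parametrize("scale,rho", [(0.0, IN_VITRO_DENSITY), (1.0, IN_VIVO_DENSITY)])
    def test_stable_set_matches_brute_force_oracle(self, params, scale, rho):
        """Endpoint clustering from a 5^4 IC grid finds the same attractors."""
        eq = find_equilibria(params, rho, secretion_scale=scale)
        oracle = brute_force_attractors(params, rho, scale)
        stable = eq.stable_states
        assert len(oracle) == len(stable)
        for o in oracle:
            dist = np.min(
                np.max(np.abs(stable - o), axis=1) / (1 + np.max(np.abs(o)))
            )
            assert dist < 1e-3


class TestSecretionBifurcation:
    @pytest.fixture(scope="class")
    def scan(self, params):
        return secretion_bifurcation_scan(
            params, IN_VITRO_DENSITY, scales=np.linspace(1.0, 0.0, 11)
        )

    def test_mixed_stable_at_full_secretion(self, scan):
        t = scan["table"]
        assert bool(t.loc[t.secretion_scale == 1.0, "mixed_stable"].iloc[0])

    def test_bistable_polarized_without_secretion(self, scan):
        t = scan["table"]
        row = t.loc[t.secretion_scale == 0.0].iloc[0]
        assert not row["mixed_stable"]
        assert row["n_stable"] == 2

    def test_critical_scale_bracketed_by_opposite_verdicts(self, params, scan):
        sc = scan["critical_scale"]
        assert sc is not None and 0.0 < sc < 1.0
        for s, sign in ((sc * 1.15, -1), (sc * 0.85, +1)):
            x = mixed_equilibrium(params, IN_VITRO_DENSITY, s)
            assert np.sign(_leading_eig(params, IN_VITRO_DENSITY, x, scale=s)) == sign

    def test_no_reentrant_stability(self, scan):
        flags = (
            scan["table"].sort_values("secretion_scale")["mixed_stable"].to_numpy()
        )
        assert np.all(np.diff(flags.astype(int)) >= 0)


class TestQuorumDensity:
    @pytest.fixture(scope="class")
    def q(self, params):
        return quorum_density(params)

    def test_quorum_strictly_between_invitro_and_invivo(self, q):
        assert 2e6 < q["critical_density"] < 1e9

    def test_opposite_verdicts_at_ten_percent_offsets(self, params, q):
        rho_c = q["critical_density"]
        for rho, sign in ((rho_c * 0.9, -1), (rho_c * 1.1, +1)):
            x = mixed_equilibrium(params, rho)
            assert np.sign(_leading_eig(params, rho, x)) == sign

    def test_production_removal_ratio_consistent_with_density_law(self, params, q):
        ctx = apply_density(params, q["critical_density"])
        assert q["production_removal_ratio"] == pytest.approx(
            ctx.a1 / ctx.dCY1, rel=1e-9
        )

    def test_invalid_bracket_reports_widening(self, params):
        with pytest.raises(ValueError, match="widen"):
            quorum_density(params, (1e6, 2e6))


class TestScaleDecomposition:
    def test_verdict_agrees_with_eigenvalues_at_both_operating_points(self, params):
        for rho, expect in ((IN_VITRO_DENSITY, "mixed-stable"), (IN_VIVO_DENSITY, "polarizing")):
            x = mixed_equilibrium(params, rho)
            dec = scale_decomposition(params, rho, x)
            assert dec.verdict == expect
            assert dec.mixed_stable == (_leading_eig(params, rho, x) < 0)

    def test_cross_blocks_vanish_without_tf_cy_coupling(self, params):
        # no secretion and no cytokine-driven induction: scales decouple
        p = params.replace(s1=1e-12, s2=1e-12)
        x = mixed_equilibrium(p, IN_VITRO_DENSITY, secretion_scale=0.0)
        x = np.array([x[0], x[1], 0.0, 0.0])
        dec = scale_decomposition(p, IN_VITRO_DENSITY, x, secretion_scale=0.0)
        assert dec.cross_effect == pytest.approx(0.0, abs=1e-10)

    def test_non_equilibrium_input_rejected(self, params):
        with pytest.raises(ValueError, match="not an equilibrium"):
            scale_decomposition(params, IN_VITRO_DENSITY, np.array([5.0, 5, 1, 1]))


class TestReversalWindow:
    @pytest.fixture(scope="class")
    def apcs(self, params):
        return apc_constants(6, 4, params), apc_constants(0, 1000, params)

    def test_unswitched_small_th1_bias_commits_th1(self, params, apcs):
        apc64, _ = apcs
        traj = integrate_ode(
            NAIVE, params, IN_VIVO_DENSITY, apc64, t_span=(0, 500)
        )
        assert balance_index(traj.final) > 0.8

    def test_immediate_mass_switch_reverses(self, params, apcs):
        _, apc1k = apcs
        traj = integrate_ode(
            NAIVE, params, IN_VIVO_DENSITY, apc1k, t_span=(0, 500)
        )
        assert balance_index(traj.final) < 0.2

    def test_window_positive_and_finite(self, params, apcs):
        res = reversal_window(params, IN_VIVO_DENSITY, *apcs)
        assert 0 < res["window"] < 200

    def test_window_shrinks_with_initial_bias(self, params, apcs):
        _, apc1k = apcs
        windows = [
            reversal_window(
                params, IN_VIVO_DENSITY,
                apc_constants(10 * b, 10 * (1 - b), params), apc1k,
            )["window"]
            for b in (0.6, 0.75, 0.9)
        ]
        assert windows[0] >= windows[1] >= windows[2]

    def test_same_side_instruction_rejected(self, params):
        with pytest.raises(ValueError, match="opposite"):
            reversal_window(
                params, IN_VIVO_DENSITY,
                apc_constants(6, 4, params), apc_constants(1000, 0, params),
            )
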