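"""Core locus dynamics: signals, mean field, SSA, master equation, observe."""

import numpy as np
import pandas as pd
import pytest

from heatmem import (LabProtocol, ModelParams, ObservationParams, Trajectory,
                     build_lab_profile, compute_signals, mean_field_rhs,
                     observe, simulate_mean_field, simulate_ssa,
                     solve_master_equation)


def pulse_profile(temp=43.5, start=24.0, duration=1.0, total=120.0):
    return build_lab_profile(LabProtocol(
        acc_enabled=True, acc_time=start, acc_temp=temp,
        acc_duration=duration, hs_enabled=False, total_duration=total))


class TestSignals:
    def test_constant_22_all_quiet(self, params, constant_profile):
        sig = compute_signals(constant_profile, params)
        assert np.all(sig.J == 0) and np.all(sig.S == 0) and np.all(sig.D == 1)

    def test_exponential_decay_after_pulse(self, params):
        prof = pulse_profile(temp=37.0, start=24.0, duration=1.0)
        sig = compute_signals(prof, params, dt=0.05)
        t0 = 25.0
        j0 = np.interp(t0, sig.grid, sig.J)
        later = sig.grid > t0
        expected = j0 * np.exp(-params.lambda_J * (sig.grid[later] - t0))
        np.testing.assert_allclose(sig.J[later], expected, rtol=1e-9)

    def test_damage_closed_form(self, params):
        p = params.replace(kappa_D=2.0, D_min=0.1)
        prof = pulse_profile(temp=43.5, start=24.0, duration=1.0)
        sig = compute_signals(prof, p, dt=0.05)
        d_end = np.interp(25.0, sig.grid, sig.D)
        assert d_end == pytest.approx(0.1 + 0.9 * np.exp(-2.0), abs=1e-9)

    def test_dt_must_resolve_heat_windows(self, params, lab_acc_hs):
        with pytest.raises(ValueError, match="shortest"):
            compute_signals(lab_acc_hs, params, dt=0.5)

    def test_halved_step_agreement(self, params, lab_acc_hs):
        coarse = compute_signals(lab_acc_hs, params, dt=0.2)
        fine = compute_signals(lab_acc_hs, params, dt=0.1)
        j_fine = np.interp(coarse.grid, fine.grid, fine.J)
        scale = max(j_fine.max(), 1.0)
        assert np.max(np.abs(coarse.J - j_fine)) / scale < 1e-6


class TestMeanFieldRhs:
    def test_absorbing_all_r_corner(self):
        p = ModelParams(k_noise=0.0, v0=0.0)
        dr, da = mean_field_rhs(1.0, 0.0, 0.0, 0.0, 1.0, p)
        assert dr == 0.0 and da == 0.0

    def test_pure_v0_derepression(self):
        p = ModelParams(k_noise=0.0, v0=0.05)
        dr, _ = mean_field_rhs(1.0, 0.0, 0.0, 0.0, 1.0, p)
        assert dr == pytest.approx(-0.05)

    def test_symmetric_params_mirror_symmetry(self):
        """Swapping the roles of R and A (k_act = k_rep, no signals, v0 = 0)
        maps (r, a) -> (a, r) and hence (dr, da) -> (da, dr); at a point
        with r = a the two derivatives coincide."""
        p = ModelParams(k_act=0.7, k_rep=0.7, v0=0.0)
        dr, da = mean_field_rhs(0.3, 0.3, 0.0, 0.0, 1.0, p)
        assert dr == pytest.approx(da)
        dr2, da2 = mean_field_rhs(0.5, 0.2, 0.0, 0.0, 1.0, p)
        dr3, da3 = mean_field_rhs(0.2, 0.5, 0.0, 0.0, 1.0, p)
        assert dr2 == pytest.approx(da3) and da2 == pytest.approx(dr3)

    def test_simplex_violation_rejected(self, params):
        with pytest.raises(ValueError):
            mean_field_rhs(0.8, 0.4, 0.0, 0.0, 1.0, params)


class TestMeanField:
    def test_reaches_fixed_point_without_signals(self, params,
                                                 constant_profile):
        traj = simulate_mean_field(params, constant_profile, "WT")
        r1, a1 = traj.r[-2], traj.a[-2]
        dr, da = mean_field_rhs(traj.r[-1], traj.a[-1], 0.0, 0.0, 1.0, params)
        # late-time drift is tiny: the state has settled
        assert abs(traj.r[-1] - r1) < 1e-6 and abs(traj.a[-1] - a1) < 1e-6

    def test_fractions_stay_in_simplex(self, params, lab_acc_hs):
        for g in ("WT", "jmjq"):
            traj = simulate_mean_field(params, lab_acc_hs, g)
            assert np.all(traj.r >= 0) and np.all(traj.a >= 0)
            assert np.all(traj.r + traj.a <= 1 + 1e-9)
            assert np.all(traj.m >= 0)

    def test_mutant_keeps_more_repression(self, params, lab_acc_hs):
        """After ACC the WT repressive fraction sits at or below the mutant's."""
        wt = simulate_mean_field(params, lab_acc_hs, "WT")
        jm = simulate_mean_field(params, lab_acc_hs, "jmjq")
        after = wt.grid >= 96.5
        assert np.all(wt.r[after] <= jm.r[after] + 1e-9)

    def test_acclimation_raises_hs_response(self, params, lab_acc_hs,
                                            lab_hs_only):
        t = 173.0  # HS + 4 h
        m_acc = simulate_mean_field(params, lab_acc_hs, "WT").at(t)["m"]
        m_hs = simulate_mean_field(params, lab_hs_only, "WT").at(t)["m"]
        assert m_acc > m_hs

    def test_monotone_in_phi(self, params, lab_acc_hs):
        """Repression at ACC+72 h rises, and expression at HS+4 h falls, as
        demethylase activity phi decreases."""
        r_vals, m_vals = [], []
        for phi in (0.0, 0.25, 0.5, 1.0):
            traj = simulate_mean_field(params.replace(phi_jmj=phi),
                                       lab_acc_hs, "jmjq")
            r_vals.append(traj.at(168.0)["r"])
            m_vals.append(traj.at(173.0)["m"])
        assert all(a >= b - 1e-9 for a, b in zip(r_vals, r_vals[1:]))
        assert all(a <= b + 1e-9 for a, b in zip(m_vals, m_vals[1:]))


class TestSSA:
    def test_single_nucleosome_flip_is_exponential(self, constant_profile):
        """With only v0 active the R->U flip time is Exp(v0)."""
        v0 = 0.1
        p = ModelParams(N=1, k_act=0.0, k_rep=0.0, k_noise=0.0, v0=v0,
                        vJ=0.0, vUA_S=0.0, r_init=1.0)
        sig = compute_signals(constant_profile, p, dt=0.1)
        n_runs = 2000
        flips = np.empty(n_runs)
        for i in range(n_runs):
            tr = simulate_ssa(p, constant_profile, "WT", n_runs=1, seed=i,
                              signals=sig)
            below = tr.r < 0.5
            flips[i] = tr.grid[np.argmax(below)] if below.any() \
                else tr.grid[-1]
        sem = flips.std(ddof=1) / np.sqrt(n_runs)
        assert abs(flips.mean() - 1.0 / v0) <= 3 * sem

    def test_zero_propensity_state_is_frozen(self, constant_profile):
        p = ModelParams(N=6, k_act=0.0, k_rep=0.0, k_noise=0.0, v0=0.0,
                        vJ=0.0, vUA_S=0.0, r_init=0.0)  # all-U start
        tr = simulate_ssa(p, constant_profile, "WT", n_runs=50, seed=3)
        assert np.all(tr.r == 0.0) and np.all(tr.a == 0.0)
        assert np.all(tr.sem_r == 0.0)

    def test_matches_master_equation(self, params):
        """Ensemble mean within 3 SEM of the exact distribution (N=4)."""
        p = params.replace(N=4)
        prof = pulse_profile(temp=37.0, start=24.0, duration=1.0 / 3.0,
                             total=96.0)
        me = solve_master_equation(p, prof, "WT", dt=0.1)
        ssa = simulate_ssa(p, prof, "WT", n_runs=2000, seed=11, dt_signal=0.1)
        checks = np.linspace(5.0, 95.0, 10)
        for t in checks:
            mu = np.interp(t, me.grid, me.r)
            est = np.interp(t, ssa.grid, ssa.r)
            sem = max(np.interp(t, ssa.grid, ssa.sem_r), 1e-9)
            assert abs(est - mu) <= 3 * sem

    def test_reproducible_given_seed(self, params, lab_acc_hs):
        a = simulate_ssa(params, lab_acc_hs, "WT", n_runs=20, seed=5)
        b = simulate_ssa(params, lab_acc_hs, "WT", n_runs=20, seed=5)
        np.testing.assert_array_equal(a.r, b.r)
        np.testing.assert_array_equal(a.m, b.m)

    def test_cost_guard(self, params, constant_profile):
        with pytest.raises(ValueError, match="force"):
            simulate_ssa(params.replace(N=600), constant_profile, "WT",
                         n_runs=20_000, seed=0)

    def test_mean_field_limit_in_N(self, lab_acc_hs):
        """SSA ensemble mean approaches the mean-field path as N grows
        (max-norm error over the default acclimation + heat-shock run)."""
        errs = []
        for N in (5, 20, 80):
            p = ModelParams(N=N, r_init=1.0)  # nR(0) = N exactly for every N
            mf = simulate_mean_field(p, lab_acc_hs, "WT", dt=0.1)
            ssa = simulate_ssa(p, lab_acc_hs, "WT", n_runs=800, seed=7,
                               dt_signal=0.1)
            errs.append(np.max(np.abs(ssa.r - mf.r)))
        assert errs[0] > errs[1] > errs[2]


class TestBistability:
    def _median_flip_time(self, k, k_noise, seed0, n_runs=40):
        p = ModelParams(N=10, k_act=k, k_rep=k, k_noise=k_noise, v0=0.0,
                        vJ=0.0, vUA_S=0.0, r_init=1.0)
        prof = build_lab_profile(LabProtocol(acc_enabled=False,
                                             hs_enabled=False,
                                             total_duration=3000.0))
        sig = compute_signals(prof, p, dt=1.0)
        flips = []
        for i in range(n_runs):
            tr = simulate_ssa(p, prof, "WT", n_runs=1, seed=seed0 + i,
                              signals=sig)
            below = tr.r <= 0.5
            flips.append(tr.grid[np.argmax(below)] if below.any()
                         else tr.grid[-1])
        return float(np.median(flips))

    def test_recruitment_stabilises_repressed_state(self):
        strong = self._median_flip_time(k=0.5, k_noise=0.005, seed0=100)
        weak = self._median_flip_time(k=0.005, k_noise=0.005, seed0=500)
        assert strong >= 10 * weak


class TestMasterEquation:
    def test_initial_point_mass(self, params, constant_profile):
        p = params.replace(N=4)
        tr = solve_master_equation(p, constant_profile, "WT", dt=0.5)
        n_r0 = round(p.r_init * p.N)
        assert tr.r[0] == pytest.approx(n_r0 / p.N)
        assert tr.a[0] == 0.0

    def test_n1_matches_analytic_three_state(self, constant_profile):
        """N=1 with constant rates is a 3-state chain solved by expm."""
        from scipy.linalg import expm
        p = ModelParams(N=1, k_act=0.0, k_rep=0.0, k_noise=0.03, v0=0.01,
                        vJ=0.0, vUA_S=0.0, r_init=1.0)
        tr = solve_master_equation(p, constant_profile, "WT", dt=0.5)
        # states (R, U, A); only noise and v0 move probability
        Q = np.array([
            [-(p.k_noise + p.v0), p.k_noise, 0.0],
            [p.k_noise + p.v0, -2 * p.k_noise, p.k_noise],
            [0.0, p.k_noise, -p.k_noise],
        ])
        for t in (10.0, 50.0, 150.0):
            pt = expm(Q * t) @ np.array([1.0, 0.0, 0.0])
            assert np.interp(t, tr.grid, tr.r) == pytest.approx(pt[0],
                                                                abs=1e-6)
            assert np.interp(t, tr.grid, tr.a) == pytest.approx(pt[2],
                                                                abs=1e-6)

    def test_refuses_large_n(self, params, constant_profile):
        with pytest.raises(ValueError):
            solve_master_equation(params.replace(N=9), constant_profile, "WT")


class TestObserve:
    def _traj(self, r, a, m):
        grid = np.array([0.0, 1.0])
        return Trajectory(grid=grid, r=np.full(2, r), a=np.full(2, a),
                          m=np.full(2, m), genotype="WT")

    def test_zero_r_gives_intercept(self):
        obs = ObservationParams(c27=10.0, b27=1.0)
        out = observe(self._traj(0.0, 0.2, 1.0), obs)
        k27 = out[out["assay"] == "K27"]["value"]
        assert np.all(k27 == 1.0)

    def test_cm_scales_only_expression(self):
        tr = self._traj(0.3, 0.2, 2.0)
        o1 = observe(tr, ObservationParams(cm=1.0))
        o2 = observe(tr, ObservationParams(cm=2.0))
        assert np.all(o2[o2["assay"] == "expr"]["value"].to_numpy()
                      == 2 * o1[o1["assay"] == "expr"]["value"].to_numpy())
        for assay in ("K27", "K4"):
            np.testing.assert_array_equal(
                o1[o1["assay"] == assay]["value"].to_numpy(),
                o2[o2["assay"] == assay]["value"].to_numpy())

    def test_affine_map_arithmetic(self):
        obs = ObservationParams(c27=10.0, b27=1.0)
        out = observe(self._traj(0.35, 0.0, 0.0), obs)
        assert np.all(out[out["assay"] == "K27"]["value"] == 4.5)
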