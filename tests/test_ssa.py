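"""Exact stochastic simulation: distributional oracles, conservation,
reproducibility and agreement with the analytic noise levels."""

import numpy as np
import pytest
from scipy import stats

import ssekit as sk
from ssekit.ssa import SSAConfig, mass_action_constants


class TestTrajectories:
    def test_pure_input_interevent_times_are_exponential(self):
        """For a zeroth-order input the waiting times are i.i.d. Exp(rate)."""
        b = sk.NetworkBuilder("input_only", 1e-15)
        b.add_species("X", 0.0)
        rate_conc = 2e-6  # M/s -> rate = 2e-6 * Omega_eff events/s
        b.add_mass_action("in", {}, {"X": 1}, rate_conc)
        net = b.build()
        rate = rate_conc * net.system_size
        cfg = SSAConfig(t_final=11000.0 / rate, seed=5)
        traj = sk.ssa_direct(net, cfg)
        waits = np.diff(traj.times)
        assert len(waits) >= 10_000
        ks = stats.kstest(waits[:10_000], "expon", args=(0, 1.0 / rate))
        assert ks.pvalue > 0.01

    def test_absorbing_state_freezes_trajectory(self):
        b = sk.NetworkBuilder("decay", 1e-15)
        b.add_species("X", 5.0, kind="amount")
        b.add_mass_action("out", {"X": 1}, {}, 1.0)
        net = b.build()
        cfg = SSAConfig(t_final=1e3, seed=1, n_grid=11)
        traj = sk.ssa_direct(net, cfg)
        assert traj.states[-1, 0] == 0
        assert traj.n_events == 5  # exactly five decays, then frozen
        grid = sk.sample_on_grid(traj, np.linspace(0, 1e3, 7))
        assert (grid[-3:] == 0).all()

    def test_conservation_exact_along_path(self, mm_small):
        cfg = SSAConfig(t_final=2.0, seed=3)
        traj = sk.ssa_direct(mm_small, cfg)
        iE = mm_small.species_index("E")
        iES = mm_small.species_index("ES")
        totals = traj.states[:, iE] + traj.states[:, iES]
        assert (totals == 24).all()
        assert (traj.states >= 0).all()

    def test_every_jump_is_a_stoichiometry_column(self, mm_small):
        traj = sk.ssa_direct(mm_small, SSAConfig(t_final=0.5, seed=9))
        cols = {tuple(c) for c in mm_small.stoich_matrix.T.tolist()}
        jumps = np.diff(traj.states, axis=0)
        assert {tuple(j) for j in jumps.tolist()} <= cols

    def test_negative_propensity_raises_named_error(self):
        import sympy as sp
        from ssekit.network import count_symbol

        b = sk.NetworkBuilder("bad", 1e-15)
        b.add_species("X", 10.0, kind="amount")
        b.add_custom("broken", {"X": 1}, {}, -1.0 * count_symbol("X"))
        b.add_mass_action("in", {}, {"X": 1}, 1e-6)
        with pytest.raises(RuntimeError, match="broken"):
            sk.ssa_direct(b.build(), SSAConfig(t_final=1.0, seed=0))


class TestGridSampling:
    def test_right_continuity_conventions(self):
        traj = sk.Trajectory(
            times=np.array([0.0, 1.0, 2.0]),
            states=np.array([[0], [1], [2]]),
            species_ids=["X"],
            t_final=3.0,
        )
        out = sk.sample_on_grid(traj, np.array([0.0, 0.5, 1.0, 1.5, 2.5]))
        assert out[:, 0].tolist() == [0, 0, 1, 1, 2]

    def test_grid_refinement_consistency(self, mm_small):
        traj = sk.ssa_direct(mm_small, SSAConfig(t_final=1.0, seed=4))
        coarse = np.linspace(0, 1, 5)
        fine = np.linspace(0, 1, 17)
        a = sk.sample_on_grid(traj, coarse)
        b = sk.sample_on_grid(traj, fine)
        assert (b[::4] == a).all()


class TestEnsembles:
    def test_mass_action_detection(self, mm_small):
        c = mass_action_constants(mm_small)
        assert c is not None and (c > 0).all()

    def test_birth_death_fano_factor_is_one(self):
        """Stationary law is Poisson, so variance/mean of copy numbers = 1."""
        net = sk.make_birth_death(k_in=1e-6, k_out=1.0, volume_liters=1e-16)
        nbar = 1e-6 * net.system_size / 1.0  # ~60 molecules
        cfg = SSAConfig(t_final=12.0, n_grid=25, n_realizations=4000, seed=11)
        ens = sk.run_ensemble(net, cfg)
        m = ens.t >= 8.0
        mean_n = (ens.mean[m, 0] * net.system_size).mean()
        var_n = (ens.var[m, 0] * net.system_size**2).mean()
        fano = var_n / mean_n
        se = np.sqrt(2.0 / (cfg.n_realizations - 1))
        assert abs(mean_n - nbar) < 3 * np.sqrt(nbar / cfg.n_realizations) * 3
        assert abs(fano - 1.0) < 3 * se

    def test_linear_network_mean_matches_rate_equations(self):
        net = sk.make_birth_death(k_in=1e-6, k_out=1.0, volume_liters=1e-16)
        cfg = SSAConfig(t_final=3.0, n_grid=13, n_realizations=3000, seed=2)
        ens = sk.run_ensemble(net, cfg)
        tc = sk.integrate_re(
            sk.compile_system(net),
            sk.SolverConfig(t_final=3.0, n_points=13),
        )
        nbar = tc.phi[:, 0] * net.system_size
        se = np.sqrt(np.clip(ens.var[:, 0], 0, None) / cfg.n_realizations)
        se_n = se * net.system_size
        diff = np.abs(ens.mean[:, 0] * net.system_size - nbar)
        assert (diff[1:] <= 3 * se_n[1:] + 1e-9).all()

    def test_seeded_runs_are_bit_identical_across_threads(self, mm_small):
        cfg1 = SSAConfig(t_final=2.0, n_grid=21, n_realizations=64, seed=17,
                         threads=1)
        cfg4 = SSAConfig(t_final=2.0, n_grid=21, n_realizations=64, seed=17,
                         threads=4)
        a = sk.run_ensemble(mm_small, cfg1)
        b = sk.run_ensemble(mm_small, cfg4)
        c = sk.run_ensemble(mm_small, cfg1)
        assert (a.mean == b.mean).all() and (a.cov == b.cov).all()
        assert (a.mean == c.mean).all()

    def test_direct_and_odm_same_distribution(self, mm_small):
        """Two-sample KS on endpoint substrate copy numbers, alpha = 0.01."""
        iS = mm_small.species_index("S")
        end = {}
        for method, seed in (("direct", 23), ("odm", 24)):
            cfg = SSAConfig(t_final=10.0, n_grid=2, n_realizations=2000,
                            seed=seed, method=method)
            ens = sk.run_ensemble(mm_small, cfg, return_paths=True)
            end[method] = ens.paths[:, -1, iS]
        ks = stats.ks_2samp(end["direct"], end["odm"])
        assert ks.pvalue > 0.01

    def test_cellular_scale_cv_matches_lna(self, mm_small_system, mm_small):
        """Quasi-stationary SSA CVs bracket the LNA prediction for the
        product (a linear species) in the small compartment."""
        res = sk.lna_steady(mm_small_system)
        iP = mm_small.species_index("P")
        cfg = SSAConfig(t_final=20.0, n_grid=81, n_realizations=1500, seed=29)
        ens = sk.run_ensemble(mm_small, cfg)
        m = ens.t >= 10.0
        cv_ssa = np.sqrt(ens.var[m, iP].mean()) / ens.mean[m, iP].mean()
        assert abs(cv_ssa - res.cv[iP]) / res.cv[iP] < 0.1


class TestDependencyGraph:
    def test_mm_binding_invalidates_only_readers_of_changed_species(
        self, mm_cellular
    ):
        graph = sk.dependency_graph(mm_cellular)
        ids = [r.id for r in mm_cellular.reactions]
        j = ids.index("bind")  # changes S, E, ES
        affected = {ids[k] for k in graph[j]}
        assert affected == {"bind", "unbind", "cat"}
        j_in = ids.index("input")  # changes S only
        assert {ids[k] for k in graph[j_in]} == {"bind"}

    def test_single_reaction_model_odm_equals_direct(self):
        b = sk.NetworkBuilder("one", 1e-15)
        b.add_species("X", 0.0)
        b.add_mass_action("in", {}, {"X": 1}, 1e-6)
        net = b.build()
        cfg_d = SSAConfig(t_final=1.0, n_grid=6, n_realizations=50, seed=3,
                          method="direct")
        cfg_o = SSAConfig(t_final=1.0, n_grid=6, n_realizations=50, seed=3,
                          method="odm")
        a = sk.run_ensemble(net, cfg_d)
        b_ = sk.run_ensemble(net, cfg_o)
        assert (a.mean == b_.mean).all()


class TestGenericFallback:
    def test_non_mass_action_model_runs_and_matches_re(self):
        """Saturating degradation (non-elementary propensity) exercises the
        symbolic fallback path of the simulator."""
        import sympy as sp
        from ssekit.constants import SYSTEM_SIZE
        from ssekit.network import count_symbol

        b = sk.NetworkBuilder("mm_eff", 2e-16)
        b.add_species("S", 0.0)
        n, vmax, K = count_symbol("S"), 2e-6, 1e-6
        b.add_custom("deg", {"S": 1}, {},
                     vmax * SYSTEM_SIZE * n / (K * SYSTEM_SIZE + n))
        b.add_mass_action("in", {}, {"S": 1}, 1e-6)
        net = b.build()
        assert mass_action_constants(net) is None
        cfg = SSAConfig(t_final=6.0, n_grid=13, n_realizations=200, seed=8)
        ens = sk.run_ensemble(net, cfg)
        phi_ss = sk.steady_state_re(sk.compile_system(net))
        n_ss = phi_ss[0] * net.system_size
        se = np.sqrt(ens.var[-1, 0] / cfg.n_realizations) * net.system_size
        assert abs(ens.mean[-1, 0] * net.system_size - n_ss) < 4 * se + 1
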