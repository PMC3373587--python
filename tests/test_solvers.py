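"""RE/LNA/EMRE solvers against closed-form and independent numeric oracles."""

import numpy as np
import pytest

import ssekit as sk
from ssekit.solvers import SolverConfig, state_dimension


K_IN, K_OUT = 1e-6, 1.0  # birth-death rates used by the session fixtures


def mm_flux_balance_oracle(k_in, k_out, k1, k_minus1, k2, E_T):
    """Independent steady-state algebra for the substrate-input enzyme:
    catalysis balances input, product balances output, binding balances
    unbinding + catalysis."""
    KM = (k_minus1 + k2) / k1
    es = k_in / k2
    p = k_in / k_out
    e = E_T - es
    s = KM * es / e
    return {"S": s, "E": e, "ES": es, "P": p}


class TestRateEquations:
    def test_birth_death_closed_form(self, bd_system):
        cfg = SolverConfig(t_final=1.0 / K_OUT, n_points=11)
        tc = sk.integrate_re(bd_system, cfg)
        expected = (K_IN / K_OUT) * (1 - np.exp(-K_OUT * tc.t))
        assert np.allclose(tc.phi[:, 0], expected, rtol=1e-5)

    def test_mm_relaxes_within_about_five_seconds(self, mm_cellular_system):
        cfg = SolverConfig(t_final=5.0, n_points=6)
        tc = sk.integrate_re(mm_cellular_system, cfg)
        u_end = mm_cellular_system.reduce(tc.phi[-1])
        # residual flux below 1e-6 M/s after ~5 s of model time
        assert np.linalg.norm(mm_cellular_system.rate(u_end)) < 1e-6

    def test_tolerance_refinement_consistency(self, bd_system):
        ends = []
        for scale in (1.0, 0.5):
            cfg = SolverConfig(t_final=3.0, n_points=4, rel_tol=1e-6 * scale,
                               abs_tol=1e-15 * scale)
            ends.append(sk.integrate_re(bd_system, cfg).phi[-1, 0])
        assert abs(ends[0] - ends[1]) <= 10 * 1e-6 * abs(ends[1])

    def test_stiff_and_explicit_methods_agree(self, bd_system):
        res = {}
        for stiff in (True, False, "auto"):
            cfg = SolverConfig(t_final=2.0, n_points=5, stiff=stiff)
            res[stiff] = sk.integrate_re(bd_system, cfg).phi[-1, 0]
        assert np.allclose(list(res.values()), res[True], rtol=1e-5)


class TestSteadyState:
    def test_birth_death_fixed_point_from_any_guess(self, bd_system):
        for guess in ([0.0], [5e-5], [3e-9]):
            phi = sk.steady_state_re(bd_system, initial=np.array(guess))
            assert np.isclose(phi[0], K_IN / K_OUT, rtol=1e-8)

    def test_mm_matches_flux_balance_algebra(self, mm_cellular_system):
        phi = sk.steady_state_re(mm_cellular_system)
        oracle = mm_flux_balance_oracle(1.8e-5, 7.0, 5e7, 5.0, 5.0, 4e-6)
        net = mm_cellular_system.net
        for s, v in oracle.items():
            assert np.isclose(phi[net.species_index(s)], v, rtol=1e-8), s

    def test_newton_residual_bound(self, coop_cellular_system):
        cfg = SolverConfig(newton_tol=1e-9)
        phi = sk.steady_state_re(coop_cellular_system, cfg)
        r = coop_cellular_system.rate(coop_cellular_system.reduce(phi))
        assert np.linalg.norm(r) < 1e-9

    def test_line_search_extends_convergence_basin(self, coop_cellular_system):
        """Damped Newton converges from far-out guesses on the fixtures, and
        on a saturating-kinetics model where the undamped iteration
        overshoots into negative concentrations and fails."""
        far = 1e-2 * np.ones(coop_cellular_system.net.n_species)
        phi = sk.steady_state_re(coop_cellular_system, initial=far)
        assert np.all(phi >= 0)

        from ssekit.constants import SYSTEM_SIZE
        from ssekit.network import count_symbol

        b = sk.NetworkBuilder("mm_sat", 1e-15)
        b.add_species("S", 0.0)
        n, vmax, K = count_symbol("S"), 1e-6, 1e-7
        b.add_custom("deg", {"S": 1}, {},
                     vmax * SYSTEM_SIZE * n / (K * SYSTEM_SIZE + n))
        b.add_mass_action("in", {}, {"S": 1}, 0.5e-6)
        sat = sk.compile_system(b.build())
        start = np.array([1e-4])  # deep in the saturated (flat) branch
        with pytest.raises(RuntimeError):
            sk.steady_state_re(sat, initial=start, line_search=False,
                               _retry=False)
        phi = sk.steady_state_re(sat, initial=start, _retry=False)
        assert np.isclose(phi[0], 1e-7, rtol=1e-6)  # s = K k_in/(vmax-k_in)


class TestLNA:
    def test_birth_death_stationary_poisson(self, bd_system):
        """Exact CME solution of the linear birth-death process is Poisson:
        number variance = number mean, so C_XX = phi/Omega_eff."""
        res = sk.lna_steady(bd_system)
        omega = bd_system.net.system_size
        assert np.isclose(res.cov_ss[0, 0], res.phi_ss[0] / omega, rtol=1e-10)

    def test_lyapunov_residual_and_psd(self, mm_cellular_system):
        res = sk.lna_steady(mm_cellular_system)
        sys = mm_cellular_system
        u = sys.reduce(res.phi_ss)
        A, D = sys.jac(u), sys.diff(u)
        sig = res._sig_red
        resid = A @ sig + sig @ A.T + D
        assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(D)
        assert np.linalg.eigvalsh(res.cov_ss).min() >= -1e-10 * res.cov_ss.max()

    def test_timecourse_limit_matches_algebraic_steady_state(self, mm_small_system):
        cfg = SolverConfig(t_final=60.0, n_points=61)
        tc = sk.lna_timecourse(mm_small_system, cfg)
        ss = sk.lna_steady(mm_small_system)
        assert np.allclose(tc.phi[-1], ss.phi_ss, rtol=1e-6, atol=1e-12)
        assert np.allclose(tc.cov[-1], ss.cov_ss, rtol=1e-5,
                           atol=1e-6 * np.abs(ss.cov_ss).max())

    def test_covariance_psd_along_time(self, mm_small_system):
        tc = sk.lna_timecourse(mm_small_system, SolverConfig(t_final=5, n_points=21))
        for C in tc.cov:
            assert np.linalg.eigvalsh(C).min() >= -1e-10 * max(C.max(), 1e-300)

    def test_cooperative_enzyme_substrate_anticorrelation(self, coop_cellular_system):
        """Free enzyme and substrate fluctuations become anti-correlated as
        the steady state is approached, with damped oscillatory transients."""
        cfg = SolverConfig(t_final=10.0, n_points=1001)
        tc = sk.lna_timecourse(coop_cellular_system, cfg)
        net = coop_cellular_system.net
        iS, iE = net.species_index("S"), net.species_index("E")
        corr_se = tc.corr[:, iS, iE]
        assert corr_se[-1] < 0
        sign_changes = np.sum(np.abs(np.diff(np.sign(corr_se[1:]))) > 0)
        assert sign_changes >= 2  # damped oscillation in the correlation

    def test_unstable_fixed_point_rejected(self):
        # X -> 2X autocatalysis has a repelling fixed point at the origin
        b = sk.NetworkBuilder("unstable", 1e-15)
        b.add_species("X", 0.0)
        b.add_mass_action("auto", {"X": 1}, {"X": 2}, 1.0)
        b.add_mass_action("in", {}, {"X": 1}, 1e-9)
        sys = sk.compile_system(b.build())
        with pytest.raises(RuntimeError, match="Hurwitz"):
            sk.lna_steady(sys, phi_ss=np.array([0.0]))


class TestEMRE:
    def test_equals_re_for_unimolecular_networks(self):
        sys = sk.compile_system(sk.make_linear_chain())
        res = sk.emre_steady(sys)
        assert np.allclose(res.emre_ss, res.phi_ss, rtol=1e-12)
        tc = sk.emre_timecourse(sys, SolverConfig(t_final=3, n_points=16))
        assert np.allclose(tc.emre_mean, tc.phi, rtol=1e-7,
                           atol=1e-9 * tc.phi.max())

    def test_birth_death_correction_is_zero(self, bd_system):
        res = sk.emre_steady(bd_system)
        assert np.allclose(res.emre_ss, res.phi_ss, rtol=1e-12)

    def test_mm_small_volume_only_substrate_corrected(self, mm_small_system):
        res = sk.emre_steady(mm_small_system)
        net = mm_small_system.net
        delta = res.emre_ss - res.phi_ss
        iS = net.species_index("S")
        assert delta[iS] > 0
        for s in ("E", "ES", "P"):
            assert abs(delta[net.species_index(s)]) < 1e-9 * delta[iS]

    def test_correction_scales_inversely_with_volume(self):
        """log-log slope of |EMRE - RE| against volume is -1 within 0.05."""
        vols = np.array([2e-17, 5e-17, 1e-16, 3e-16])
        norms = []
        for v in vols:
            net = sk.make_michaelis_menten(v)
            res = sk.emre_steady(sk.compile_system(net))
            norms.append(np.linalg.norm(res.emre_ss - res.phi_ss))
        slope = np.polyfit(np.log(vols), np.log(norms), 1)[0]
        assert abs(slope + 1.0) < 0.05

    def test_steady_matches_timecourse_limit(self, mm_small_system):
        ss = sk.emre_steady(mm_small_system)
        tc = sk.emre_timecourse(mm_small_system, SolverConfig(t_final=80, n_points=41))
        assert np.allclose(tc.emre_mean[-1], ss.emre_ss, rtol=1e-5)


class TestSummariesAndDimensions:
    def test_correlation_diagonal_and_zero_variance_flag(self, mm_cellular_system):
        res = sk.lna_steady(mm_cellular_system)
        cv, corr = sk.noise_summaries(res)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.abs(corr).max() <= 1 + 1e-12
        # a synthetic zero-variance row maps to zero correlation
        res.cov_ss[0, :] = 0.0
        res.cov_ss[:, 0] = 0.0
        _, corr2 = sk.noise_summaries(res)
        assert corr2[0, 1] == 0.0 and corr2[0, 0] == 0.0

    @pytest.mark.parametrize(
        "name,n_red", [("F1", 3), ("F3", 6), ("birth_death", 1)]
    )
    def test_equation_counts_after_reduction(self, name, n_red):
        sys = sk.compile_system(sk.make_paper_model(name))
        assert sys.n_red == n_red
        assert state_dimension(sys, "re") == n_red
        assert state_dimension(sys, "lna") == n_red + n_red * (n_red + 1) // 2
        assert state_dimension(sys, "emre") == 2 * n_red + n_red * (n_red + 1) // 2


class TestCriticalVolume:
    def test_agrees_with_emre_bisection(self):
        """Closed-form crossing volume vs an independent bisection on the
        sign of [S]_EMRE - [P]_EMRE over a volume scan, to 1%."""
        args = (1.8e-5, 7.0, 5e7, 5.0, 5.0, 4e-6)
        oc, sat = sk.critical_volume_mm(*args)
        assert 0 < sat < 1

        def gap(vol):
            net = sk.make_michaelis_menten(vol)
            r = sk.emre_steady(sk.compile_system(net))
            return (r.emre_ss[net.species_index("S")]
                    - r.emre_ss[net.species_index("P")])

        lo, hi = oc / 10, oc * 10
        assert gap(lo) > 0 > gap(hi)  # inversion below, normal order above
        for _ in range(40):
            mid = np.sqrt(lo * hi)
            if gap(mid) > 0:
                lo = mid
            else:
                hi = mid
        assert abs(np.sqrt(lo * hi) - oc) / oc < 0.01

    def test_saturated_regime_rejected(self):
        with pytest.raises(ValueError, match="saturates"):
            sk.critical_volume_mm(1.8e-5, 7.0, 5e7, 5.0, 5.0, 3e-6)


class TestFullVersusReduced:
    def test_unreduced_formulation_matches_reduced_timecourse(self, mm_small):
        """Integrating the full (conservation-singular) system and the
        reduced one gives the same RE/LNA/EMRE trajectories."""
        import sympy as sp
        from ssekit.conservation import _assemble
        from ssekit.sse import sse_coefficients

        tensors = sse_coefficients(mm_small)
        reduced = sk.compile_system(tensors)
        trivial = _assemble(
            sp.zeros(0, mm_small.n_species),
            mm_small.initial_concentrations(),
            list(range(mm_small.n_species)),
            [],
        )
        full = sk.compile_system(tensors, basis=trivial)
        cfg = SolverConfig(t_final=5.0, n_points=11, rel_tol=1e-9,
                           abs_tol=1e-12)
        a = sk.emre_timecourse(reduced, cfg)
        b = sk.emre_timecourse(full, cfg)
        scale = np.abs(a.phi).max()
        assert np.allclose(a.phi, b.phi, atol=1e-8 * scale)
        assert np.allclose(a.emre_mean, b.emre_mean, atol=1e-8 * scale)
        assert np.allclose(a.cov, b.cov, atol=1e-8 * np.abs(a.cov).max())
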