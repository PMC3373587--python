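"""Deterministic and fluctuation solvers built on the system-size expansion.

Three nested levels of description are solved, in time-course or steady-state
mode, always on the conservation-reduced state space:

* rate equations (REs): ``dphi/dt = S F(phi)``;
* linear noise approximation (LNA): the fluctuation covariance obeys the
  Lyapunov flow ``dSigma/dt = A Sigma + Sigma A^T + D``; the concentration
  covariance is ``C = Sigma / Omega_eff``;
* mesoscopic mean correction (EMRE): the first finite-volume correction to
  the means, ``d delta/dt = A delta + Delta(phi, Sigma) / Omega_eff``, with
  corrected means ``phi + delta``.

``Omega_eff`` is the number of molecules per unit concentration.  Reduction
by conservation laws makes the Jacobian non-singular at asymptotically stable
fixed points, so the steady-state problems become a Newton solve, a linear
Lyapunov equation and one more linear solve, respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.integrate import solve_ivp

from .conservation import ConservationBasis, find_conservation_laws
from .network import ReactionNetwork
from .sse import SSETensors, sse_coefficients

__all__ = [
    "SolverConfig",
    "TimeCourseResult",
    "SteadyStateResult",
    "CompiledSystem",
    "compile_system",
    "state_dimension",
    "integrate_re",
    "steady_state_re",
    "lna_timecourse",
    "lna_steady",
    "emre_timecourse",
    "emre_steady",
    "noise_summaries",
    "critical_volume_mm",
]


@dataclass
class SolverConfig:
    t_final: float = 10.0
    n_points: int = 200
    abs_tol: float = 1e-9
    rel_tol: float = 1e-6
    max_newton_iter: int = 100
    newton_tol: float = 1e-9
    stiff: object = "auto"  # True | False | "auto"

    def __post_init__(self):
        if self.t_final <= 0 or self.n_points < 2:
            raise ValueError("need t_final > 0 and n_points >= 2")
        if min(self.abs_tol, self.rel_tol, self.newton_tol) <= 0:
            raise ValueError("tolerances must be positive")

    @property
    def ivp_method(self) -> str:
        return {True: "BDF", False: "RK45", "auto": "LSODA"}[self.stiff]


@dataclass
class TimeCourseResult:
    """Time-indexed means and noise of a network, concentration units."""

    net: ReactionNetwork
    t: np.ndarray  # (P,)
    phi: np.ndarray  # (P, N) RE concentrations
    cov: np.ndarray | None = None  # (P, N, N) concentration covariance
    emre_mean: np.ndarray | None = None  # (P, N)
    warnings: list = field(default_factory=list)

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diagonal(self.cov, axis1=1, axis2=2), 0, None))

    @property
    def corr(self) -> np.ndarray:
        return np.stack([_corr_from_cov(c) for c in self.cov])


@dataclass
class SteadyStateResult:
    net: ReactionNetwork
    phi_ss: np.ndarray  # (N,)
    cov_ss: np.ndarray | None = None  # (N, N) concentration covariance
    emre_ss: np.ndarray | None = None  # (N,)
    warnings: list = field(default_factory=list)

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_ss), 0, None))

    @property
    def cv(self) -> np.ndarray:
        """Coefficient of variation sigma_X / <X>, RE-consistent means."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(self.phi_ss > 0, self.sd / self.phi_ss, 0.0)
        return out

    @property
    def inversion_flag(self) -> np.ndarray:
        """Boolean (N, N): EMRE reverses the RE ordering of the pair."""
        if self.emre_ss is None:
            return np.zeros((len(self.phi_ss),) * 2, dtype=bool)
        re_ord = self.phi_ss[:, None] > self.phi_ss[None, :]
        em_ord = self.emre_ss[:, None] > self.emre_ss[None, :]
        return re_ord != em_ord


def _corr_from_cov(C: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.clip(np.diag(C), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = C / np.outer(sd, sd)
    R[~np.isfinite(R)] = 0.0
    np.fill_diagonal(R, np.where(sd > 0, 1.0, 0.0))
    return R


class CompiledSystem:
    """Numeric closures over the symbolic SSE tensors, conservation-reduced.

    All callables take the *independent* concentration vector ``u``; full
    states are reconstructed through the conservation basis.
    """

    def __init__(self, tensors: SSETensors, basis: ConservationBasis | None = None):
        import sympy as sp

        net = tensors.net
        self.net = net
        self.tensors = tensors
        if basis is None:
            basis = find_conservation_laws(net, frame="concentration")
        self.basis = basis
        phi = net.conc_symbols()
        mods = "numpy"
        self._F = sp.lambdify(phi, tensors.F, modules=mods)
        self._A = sp.lambdify(phi, tensors.A, modules=mods)
        self._D = sp.lambdify(phi, tensors.D, modules=mods)
        self._H = [sp.lambdify(phi, H, modules=mods) for H in tensors.hessians]
        self._f1 = sp.lambdify(phi, tensors.f1, modules=mods)
        self.S = net.stoich_matrix.astype(float)
        self.ind = basis.independent_idx
        self.T = basis.T
        self.system_size = net.system_size
        self.n_red = len(self.ind)

    # -- frames -------------------------------------------------------------

    def full(self, u: np.ndarray) -> np.ndarray:
        return self.basis.reconstruct(u)

    def reduce(self, x: np.ndarray) -> np.ndarray:
        return self.basis.project(x)

    def cov_full(self, sig_red: np.ndarray) -> np.ndarray:
        return self.T @ sig_red @ self.T.T

    # -- reduced-frame evaluations -------------------------------------------

    def rate(self, u: np.ndarray) -> np.ndarray:
        """Reduced RE right-hand side (S F)(phi(u)) on independent species."""
        x = self.full(u)
        F = np.asarray(self._F(*x), dtype=float).ravel()
        return (self.S @ F)[self.ind]

    def jac(self, u: np.ndarray) -> np.ndarray:
        x = self.full(u)
        A = np.asarray(self._A(*x), dtype=float)
        return A[self.ind, :] @ self.T

    def diff(self, u: np.ndarray) -> np.ndarray:
        x = self.full(u)
        D = np.asarray(self._D(*x), dtype=float)
        return D[np.ix_(self.ind, self.ind)]

    def delta(self, u: np.ndarray, sig_red: np.ndarray) -> np.ndarray:
        """Reduced mean-correction vector Delta(phi, Sigma)."""
        x = self.full(u)
        sig_full = self.cov_full(sig_red)
        f1 = np.asarray(self._f1(*x), dtype=float).ravel()
        per_rxn = np.empty(self.net.n_reactions)
        for j in range(self.net.n_reactions):
            H = np.asarray(self._H[j](*x), dtype=float)
            per_rxn[j] = 0.5 * np.tensordot(H, sig_full) + f1[j]
        return (self.S @ per_rxn)[self.ind]


def compile_system(
    tensors_or_net, basis: ConservationBasis | None = None
) -> CompiledSystem:
    if isinstance(tensors_or_net, ReactionNetwork):
        tensors_or_net = sse_coefficients(tensors_or_net)
    return CompiledSystem(tensors_or_net, basis)


def _as_system(obj) -> CompiledSystem:
    return obj if isinstance(obj, CompiledSystem) else compile_system(obj)


def _anchor(sys: CompiledSystem, initial: np.ndarray | None) -> np.ndarray:
    """Anchor conserved totals to the initial condition; return reduced state."""
    if initial is None:
        initial = sys.net.initial_concentrations()
    initial = np.asarray(initial, dtype=float)
    if np.any(initial < 0):
        raise ValueError("initial concentrations must be non-negative")
    sys.basis = sys.basis.with_totals(initial)
    sys.T = sys.basis.T
    return sys.basis.project(initial)


# -- symmetric packing -------------------------------------------------------


def _tri_ix(n: int):
    return np.triu_indices(n)


def _pack(M: np.ndarray) -> np.ndarray:
    return M[_tri_ix(M.shape[0])]


def _unpack(v: np.ndarray, n: int) -> np.ndarray:
    M = np.zeros((n, n))
    iu = _tri_ix(n)
    M[iu] = v
    M.T[iu] = v
    return M


def _solve_ivp(fun, t_span, y0, config: SolverConfig, t_eval):
    sol = solve_ivp(
        fun,
        t_span,
        y0,
        method=config.ivp_method,
        t_eval=t_eval,
        rtol=config.rel_tol,
        atol=config.abs_tol,
    )
    if not sol.success:
        if config.ivp_method != "BDF":  # stiff fallback
            sol = solve_ivp(
                fun, t_span, y0, method="BDF", t_eval=t_eval,
                rtol=config.rel_tol, atol=config.abs_tol,
            )
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t = {sol.t[-1] if len(sol.t) else t_span[0]:g}: "
                f"{sol.message}"
            )
    return sol


# -- rate equations ----------------------------------------------------------


def integrate_re(
    tensors, config: SolverConfig | None = None, initial=None
) -> TimeCourseResult:
    """Integrate the macroscopic rate equations on the reduced state space."""
    sys = _as_system(tensors)
    config = config or SolverConfig()
    u0 = _anchor(sys, initial)
    t_eval = np.linspace(0.0, config.t_final, config.n_points)
    sol = _solve_ivp(lambda t, u: sys.rate(u), (0, config.t_final), u0, config, t_eval)
    phi = sys.basis.reconstruct(sol.y.T)
    return TimeCourseResult(net=sys.net, t=sol.t, phi=phi)


def state_dimension(sys: CompiledSystem, level: str) -> int:
    """Number of simultaneous ODEs solved at a given description level
    (after conservation reduction): N for the rate equations, plus the
    N(N+1)/2 distinct covariances for the LNA, plus N corrections for the
    mesoscopic means."""
    n = sys.n_red
    return {"re": n, "lna": n + n * (n + 1) // 2,
            "emre": 2 * n + n * (n + 1) // 2}[level]


def steady_state_re(
    tensors, config: SolverConfig | None = None, initial=None, _retry: bool = True,
    line_search: bool = True,
) -> np.ndarray:
    """RE fixed point by damped Newton iteration with backtracking line search.

    The merit function is ``0.5 ||S F||^2`` on the reduced state; on failure
    the system is pre-integrated for ten characteristic times and the solve
    retried from the relaxed state.
    """
    sys = _as_system(tensors)
    config = config or SolverConfig()
    u = _anchor(sys, initial).astype(float)

    def merit(u):
        g = sys.rate(u)
        return 0.5 * g @ g, g

    h, g = merit(u)
    for _ in range(config.max_newton_iter):
        if np.linalg.norm(g) < config.newton_tol:
            break
        J = sys.jac(u)
        try:
            p = np.linalg.solve(J, -g)
        except np.linalg.LinAlgError:
            p = -np.linalg.lstsq(J, g, rcond=None)[0]
        if not line_search:
            u = u + p
            h, g = merit(u)
            if not np.isfinite(h):
                break
            continue
        lam, ok = 1.0, False
        grad_h = J.T @ g  # gradient of the merit function
        slope = grad_h @ p
        for _ls in range(40):
            h_new, g_new = merit(u + lam * p)
            if h_new <= h + 1e-4 * lam * slope or h_new < h:
                ok = True
                break
            lam *= 0.5
        if not ok:
            break
        u = u + lam * p
        h, g = h_new, g_new
    if np.linalg.norm(g) >= config.newton_tol:
        if _retry:
            # pre-integrate to approach the basin, then retry once
            tau = 10.0 / max(_slowest_rate(sys, u), 1e-12)
            relax_cfg = SolverConfig(
                t_final=tau, n_points=2, abs_tol=config.abs_tol,
                rel_tol=config.rel_tol, stiff=config.stiff,
            )
            tc = integrate_re(sys, relax_cfg, initial=sys.full(u))
            return steady_state_re(sys, config, initial=tc.phi[-1], _retry=False)
        raise RuntimeError(
            f"Newton iteration did not converge (residual {np.linalg.norm(g):.3g}); "
            "consider pre-integrating the rate equations"
        )
    phi = sys.full(u)
    if np.any(phi < -1e-9 * max(1.0, np.max(np.abs(phi)))):
        raise RuntimeError("Newton converged to a negative steady state")
    return np.clip(phi, 0.0, None)


def _slowest_rate(sys: CompiledSystem, u: np.ndarray) -> float:
    ev = np.linalg.eigvals(sys.jac(u))
    re = np.abs(ev.real)
    re = re[re > 0]
    return float(re.min()) if len(re) else 1.0


# -- LNA ----------------------------------------------------------------------


def lna_timecourse(
    tensors, config: SolverConfig | None = None, initial=None, sigma0=None,
    with_emre: bool = False,
) -> TimeCourseResult:
    """Jointly integrate the REs and the fluctuation covariance.

    Deterministic initial conditions (``Sigma(0) = 0``) are assumed unless a
    reduced-frame initial covariance is supplied.  With ``with_emre`` the
    mean-correction ODE is appended and corrected means are returned too.
    """
    sys = _as_system(tensors)
    config = config or SolverConfig()
    u0 = _anchor(sys, initial)
    n = sys.n_red
    n_sig = n * (n + 1) // 2
    sig0 = np.zeros(n_sig) if sigma0 is None else _pack(np.asarray(sigma0))
    y0 = np.concatenate([u0, sig0] + ([np.zeros(n)] if with_emre else []))
    omega = sys.system_size

    def rhs(t, y):
        u = y[:n]
        sig = _unpack(y[n : n + n_sig], n)
        A = sys.jac(u)
        dsig = A @ sig + sig @ A.T + sys.diff(u)
        parts = [sys.rate(u), _pack(0.5 * (dsig + dsig.T))]
        if with_emre:
            d = y[n + n_sig :]
            parts.append(A @ d + sys.delta(u, sig) / omega)
        return np.concatenate(parts)

    t_eval = np.linspace(0.0, config.t_final, config.n_points)
    sol = _solve_ivp(rhs, (0, config.t_final), y0, config, t_eval)
    P = len(sol.t)
    phi = sys.basis.reconstruct(sol.y[:n].T)
    cov = np.empty((P, sys.net.n_species, sys.net.n_species))
    for p in range(P):
        cov[p] = sys.cov_full(_unpack(sol.y[n : n + n_sig, p], n)) / omega
    res = TimeCourseResult(net=sys.net, t=sol.t, phi=phi, cov=cov)
    if with_emre:
        delta = sol.y[n + n_sig :].T @ sys.T.T
        res.emre_mean = phi + delta
        if np.any(res.emre_mean < 0):
            res.warnings.append(
                "EMRE means became negative: volume below the breakdown volume"
            )
    return res


def lna_steady(tensors, phi_ss: np.ndarray | None = None,
               config: SolverConfig | None = None) -> SteadyStateResult:
    """Steady-state covariance from the algebraic Lyapunov equation."""
    sys = _as_system(tensors)
    config = config or SolverConfig()
    if phi_ss is None:
        phi_ss = steady_state_re(sys, config)
    else:
        _anchor(sys, phi_ss)
    u = sys.reduce(phi_ss)
    A = sys.jac(u)
    ev = np.linalg.eigvals(A)
    if np.any(ev.real >= 0):
        raise RuntimeError(
            "reduced Jacobian is not Hurwitz at the fixed point; the LNA "
            f"steady state is not admissible (eigenvalues {ev})"
        )
    D = sys.diff(u)
    sig = scipy.linalg.solve_continuous_lyapunov(A, -D)
    sig = 0.5 * (sig + sig.T)
    cov = sys.cov_full(sig) / sys.system_size
    res = SteadyStateResult(net=sys.net, phi_ss=np.asarray(phi_ss), cov_ss=cov)
    res._sig_red = sig  # reduced-frame fluctuation covariance, number scaling
    return res


# -- EMRE ---------------------------------------------------------------------


def emre_timecourse(
    tensors, config: SolverConfig | None = None, initial=None
) -> TimeCourseResult:
    """Time course of REs, LNA covariance and mesoscopic mean correction."""
    return lna_timecourse(tensors, config, initial, with_emre=True)


def emre_steady(
    tensors, phi_ss: np.ndarray | None = None, config: SolverConfig | None = None
) -> SteadyStateResult:
    """Steady-state corrected means: solve ``A delta = -Delta / Omega_eff``."""
    sys = _as_system(tensors)
    config = config or SolverConfig()
    if phi_ss is None:
        phi_ss = steady_state_re(sys, config)
    res = lna_steady(sys, phi_ss, config)
    u = sys.reduce(phi_ss)
    A = sys.jac(u)
    sig_red = res._sig_red
    d_red = np.linalg.solve(A, -sys.delta(u, sig_red) / sys.system_size)
    emre = res.phi_ss + sys.T @ d_red
    res.emre_ss = emre
    if np.any(emre < 0):
        res.warnings.append(
            "EMRE means negative at steady state: volume below breakdown volume"
        )
    return res


# -- summaries ----------------------------------------------------------------


def noise_summaries(result):
    """Per-species CV and pairwise correlation from a solved result.

    Returns ``(cv, corr)``; time-indexed for a :class:`TimeCourseResult`.
    CVs use the RE mean (the LNA-consistent choice); zero-variance species
    get a correlation of zero.
    """
    if isinstance(result, SteadyStateResult):
        return result.cv, _corr_from_cov(result.cov_ss)
    sd = result.sd
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(result.phi > 0, sd / result.phi, 0.0)
    return cv, result.corr


# -- Michaelis-Menten critical volume ----------------------------------------


def critical_volume_mm(
    k_in: float, k_out: float, k1: float, k_minus1: float, k2: float, E_T: float
):
    """Volume at which corrected substrate and product concentrations cross.

    For the substrate-input Michaelis-Menten scheme the mean correction is
    exactly proportional to the inverse volume, so the crossing condition
    ``[S]_EMRE(Omega) = [P]_EMRE(Omega)`` is linear in ``1/Omega`` and has the
    closed-form root returned here (in litres).  Below the critical volume the
    substrate exceeds the product, inverting the macroscopic ordering.

    Returns ``(Omega_c, saturation)`` where ``saturation`` is the fractional
    enzyme saturation ``[ES]/E_T = k_in / (k2 E_T)``.
    """
    from .models import make_michaelis_menten

    sat = k_in / (k2 * E_T)
    if sat >= 1:
        raise ValueError(
            "no macroscopic steady state: input flux saturates the enzyme "
            f"(k_in/(k2*E_T) = {sat:g} >= 1)"
        )
    ref_vol = 1e-15  # any volume: the correction scales exactly as 1/volume
    net = make_michaelis_menten(
        volume_liters=ref_vol, k_in=k_in, k_out=k_out, k1=k1,
        k_minus1=k_minus1, k2=k2, E_T=E_T,
    )
    res = emre_steady(compile_system(net))
    iS, iP = net.species_index("S"), net.species_index("P")
    beta = net.system_size * (res.emre_ss - res.phi_ss)  # volume-independent
    gap_re = res.phi_ss[iP] - res.phi_ss[iS]
    excess = beta[iS] - beta[iP]
    if gap_re <= 0 or excess <= 0:
        raise ValueError("no concentration inversion for these rate constants")
    omega_eff_c = excess / gap_re
    from .constants import AVOGADRO

    return omega_eff_c / AVOGADRO, sat
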