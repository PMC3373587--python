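"""System-size expansion machinery.

The mesoscopic propensity ``a_j(n, Omega)`` of every reaction is expanded in
inverse powers of the effective system size after the substitution
``n = Omega * phi`` (counts to concentrations)::

    a_j(Omega * phi, Omega) / Omega = f0_j(phi) + Omega**-1 * f1_j(phi) + ...

For mass-action kinetics the series is exact and finite: ``f0`` is the
macroscopic rate law ``k * prod phi**s`` and ``f1`` collects the
falling-factorial cross terms (e.g. for a dimerisation ``2X -> 0`` with
propensity ``k n (n-1) / Omega``: ``f0 = k phi**2``, ``f1 = -k phi``).  For
non-elementary propensities (Michaelis-Menten/Hill forms) whose substitution
leaves no residual system-size dependence, ``f0`` equals the microscopic rate
and all higher coefficients vanish.  Propensities that cannot be expanded
degrade gracefully: ``f0`` is the microscopic propensity at the deterministic
concentrations (numeric system size), ``f1 = 0``, and a warning is recorded.

From the expansion the module builds the tensors that the rate equations,
the linear noise approximation and the mesoscopic mean correction need:

* ``F``      macroscopic rate vector (length R),
* ``A``      Jacobian ``A_ik = sum_j S_ij d f0_j / d phi_k``,
* ``D``      diffusion matrix ``D = S diag(F) S^T``,
* ``H_j``    Hessians of ``f0_j`` (the mixed-derivative SSE coefficients),
* ``Delta``  the mean-correction vector
  ``Delta_i = sum_j S_ij [ 1/2 tr(H_j Sigma) + f1_j ]``
  where ``Sigma`` is the fluctuation covariance of the linear noise
  approximation.  For purely unimolecular mass-action networks ``Delta`` is
  identically zero, so the corrected means coincide with the rate equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .constants import SYSTEM_SIZE
from .network import ReactionNetwork, conc_symbol, count_symbol

__all__ = [
    "PropensityExpansion",
    "SSETensors",
    "expand_propensity",
    "sse_coefficients",
    "emre_delta_vector",
    "export_equations",
]


@dataclass
class PropensityExpansion:
    """Leading expansion coefficients of every propensity."""

    f0: list  # macroscopic rate, sympy expr in phi symbols
    f1: list  # order Omega**-1 coefficient
    expandable: list  # bool per reaction
    higher_zero: bool = True  # all f^(n), n >= 2 are dropped by construction
    warnings: list = field(default_factory=list)


@dataclass
class SSETensors:
    """Symbolic SSE objects shared by the RE/LNA/EMRE solvers."""

    net: ReactionNetwork
    F: sp.Matrix  # R x 1 macroscopic rates
    A: sp.Matrix  # N x N Jacobian of S.F
    D: sp.Matrix  # N x N diffusion matrix
    hessians: list  # per reaction: N x N Hessian of f0_j
    f1: sp.Matrix  # R x 1
    delta: sp.Matrix  # N x 1, in phi and Sigma_kl symbols
    sigma_symbols: sp.Matrix  # N x N symmetric symbol matrix used in `delta`
    warnings: list = field(default_factory=list)

    @property
    def phi(self) -> list:
        return self.net.conc_symbols()


def _zero_norm(e: sp.Expr) -> sp.Expr:
    return sp.Integer(0) if e.is_zero else e


def _expand_single(prop: sp.Expr, net: ReactionNetwork):
    """Expand one propensity; returns (f0, f1, expandable)."""
    phi = net.conc_symbols()
    sub = {count_symbol(s.id): SYSTEM_SIZE * p for s, p in zip(net.species, phi)}
    h = sp.together(sp.expand(prop.subs(sub) / SYSTEM_SIZE))
    x = sp.Symbol("_inv_omega", positive=True)
    hx = sp.cancel(sp.together(h.subs(SYSTEM_SIZE, 1 / x)))
    try:
        poly = sp.Poly(sp.expand(hx), x)
        if poly.degree() >= 0:
            f0 = poly.coeff_monomial(1)
            f1 = poly.coeff_monomial(x)
            return sp.simplify(f0), _zero_norm(sp.expand(f1)), True
    except sp.PolynomialError:
        pass
    # Non-polynomial in 1/Omega: try a series expansion around Omega -> inf.
    try:
        ser = sp.series(hx, x, 0, 2).removeO()
        bad = any(
            e.has(x) for e in sp.Add.make_args(sp.expand(ser)) if not e.is_polynomial(x)
        )
        if not bad:
            f0 = ser.subs(x, 0)
            f1 = sp.expand(sp.diff(ser, x).subs(x, 0))
            if f0.has(sp.zoo) or f0.has(sp.nan):
                raise ValueError
            return sp.simplify(f0), _zero_norm(f1), True
    except Exception:
        pass
    # Unexpandable: freeze the microscopic form at the numeric system size.
    f0 = sp.simplify(h.subs(SYSTEM_SIZE, net.system_size))
    return f0, sp.Integer(0), False


def expand_propensity(net: ReactionNetwork) -> PropensityExpansion:
    """Expand every propensity in inverse powers of the system size."""
    f0s, f1s, flags, warns = [], [], [], []
    for rxn in net.reactions:
        f0, f1, ok = _expand_single(rxn.propensity, net)
        f0s.append(f0)
        f1s.append(f1)
        flags.append(ok)
        if not ok:
            warns.append(
                f"reaction {rxn.id!r}: propensity not expandable in the "
                "inverse system size; using the microscopic rate at "
                "deterministic concentrations and dropping all corrections"
            )
    return PropensityExpansion(f0=f0s, f1=f1s, expandable=flags, warnings=warns)


def sse_coefficients(
    net: ReactionNetwork, exp: PropensityExpansion | None = None
) -> SSETensors:
    """Build the macroscopic rate vector, Jacobian, diffusion matrix,
    Hessian coefficient tensors and the mean-correction vector."""
    if exp is None:
        exp = expand_propensity(net)
    phi = net.conc_symbols()
    N, R = net.n_species, net.n_reactions
    S = sp.Matrix(net.stoich_matrix)
    F = sp.Matrix(exp.f0)
    # Jacobian of S.F
    SF = S * F
    A = SF.jacobian(phi)
    D = S * sp.diag(*exp.f0) * S.T
    hessians = [sp.hessian(f0, phi) for f0 in exp.f0]
    f1 = sp.Matrix(exp.f1)

    sig = sp.zeros(N, N)
    for k in range(N):
        for l in range(k, N):
            s = sp.Symbol(f"Sigma_{k}_{l}")
            sig[k, l] = s
            sig[l, k] = s
    delta = sp.zeros(N, 1)
    for i in range(N):
        for j in range(R):
            if S[i, j] == 0:
                continue
            curv = sp.Rational(1, 2) * sum(
                hessians[j][k, l] * sig[k, l] for k in range(N) for l in range(N)
            )
            delta[i] += S[i, j] * (curv + f1[j])
    return SSETensors(
        net=net,
        F=F,
        A=A,
        D=D,
        hessians=hessians,
        f1=f1,
        delta=sp.Matrix([sp.expand(d) for d in delta]),
        sigma_symbols=sig,
        warnings=list(exp.warnings),
    )


def emre_delta_vector(tensors: SSETensors, exp: PropensityExpansion | None = None):
    """Symbolic mean-correction vector ``Delta(phi, Sigma)``.

    Returned as an ``N x 1`` sympy matrix in the concentration symbols and the
    symmetric covariance symbols ``Sigma_k_l`` (see
    ``tensors.sigma_symbols``).  It vanishes identically for networks of
    purely linear (zeroth/first-order) propensities.
    """
    return tensors.delta


def export_equations(tensors: SSETensors) -> str:
    """Plain-text listing of F, A, D and Delta, one expression per line."""
    net = tensors.net
    ids = net.species_ids
    lines = []
    for j, rxn in enumerate(net.reactions):
        lines.append(f"F[{rxn.id}] = {tensors.F[j]}")
    N = net.n_species
    for i in range(N):
        for k in range(N):
            if tensors.A[i, k] != 0:
                lines.append(f"A[{ids[i]},{ids[k]}] = {tensors.A[i, k]}")
    for i in range(N):
        for k in range(i, N):
            if tensors.D[i, k] != 0:
                lines.append(f"D[{ids[i]},{ids[k]}] = {tensors.D[i, k]}")
    for i in range(N):
        if tensors.delta[i] != 0:
            lines.append(f"Delta[{ids[i]}] = {tensors.delta[i]}")
    return "\n".join(lines) + "\n"
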