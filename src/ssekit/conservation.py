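"""Conservation-law analysis of the stoichiometric matrix.

Linear combinations of species counts that are invariant under every reaction
are the left null space of the stoichiometric matrix ``S``.  The basis is
computed in exact rational arithmetic (no floating tolerance), so
``basis @ S == 0`` holds exactly and the reduction/reconstruction maps are
exact.  Each conservation law eliminates one species; the remaining
*independent* species parameterise the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sp

from .network import ReactionNetwork

__all__ = ["ConservationBasis", "find_conservation_laws"]


@dataclass
class ConservationBasis:
    """Left null space of S and the induced state-space reduction.

    The affine reconstruction of a full state from the independent one is
    ``x_full = offset + T @ x_ind`` where ``offset`` encodes the conserved
    totals and ``T`` is the linear reconstruction matrix (N x N-M).  The
    matching projection simply selects the independent components.
    """

    basis: np.ndarray  # (M, N) float (entries are exact rationals)
    basis_rational: sp.Matrix  # exact form
    totals: np.ndarray  # (M,) conserved totals in the given frame
    independent_idx: list  # N - M species indices (pivot-free columns)
    dependent_idx: list  # M species indices eliminated by the laws
    T: np.ndarray  # (N, N-M) linear part of reconstruction
    offset: np.ndarray  # (N,) affine part of reconstruction

    @property
    def n_laws(self) -> int:
        return len(self.dependent_idx)

    def project(self, x_full: np.ndarray) -> np.ndarray:
        return np.asarray(x_full)[..., self.independent_idx]

    def reconstruct(self, x_ind: np.ndarray) -> np.ndarray:
        return self.offset + np.asarray(x_ind) @ self.T.T

    def with_totals(self, x_full: np.ndarray) -> "ConservationBasis":
        """Re-anchor the conserved totals to a different initial state."""
        return _assemble(
            self.basis_rational, np.asarray(x_full, dtype=float), self.independent_idx,
            self.dependent_idx,
        )


def _assemble(Brref: sp.Matrix, x0: np.ndarray, ind: list, dep: list):
    M, N = Brref.shape
    B = np.array(Brref, dtype=float)
    totals = B @ x0 if M else np.zeros(0)
    # Brref is in reduced row echelon form: row m reads
    #   x[dep[m]] + sum_{k in ind} B[m, k] x[k] = totals[m]
    T = np.zeros((N, N - M))
    offset = np.zeros(N)
    for c, i in enumerate(ind):
        T[i, c] = 1.0
    for m, d in enumerate(dep):
        offset[d] = totals[m]
        for c, i in enumerate(ind):
            T[d, c] = -B[m, i]
    return ConservationBasis(
        basis=B,
        basis_rational=Brref,
        totals=np.asarray(totals, dtype=float),
        independent_idx=list(ind),
        dependent_idx=list(dep),
        T=T,
        offset=offset,
    )


def find_conservation_laws(
    net: ReactionNetwork, frame: str = "concentration"
) -> ConservationBasis:
    """Compute the conservation basis of a network.

    ``frame`` selects whether the conserved totals are anchored to the
    initial concentrations or the initial molecule counts; the basis itself
    is frame independent.
    """
    S = sp.Matrix(net.stoich_matrix.tolist())
    # Left null space: null space of S^T, in exact rationals.
    ns = S.T.nullspace()
    N = net.n_species
    if not ns:
        Brref = sp.zeros(0, N)
        ind = list(range(N))
        dep: list = []
    else:
        Braw = sp.Matrix([v.T for v in ns])
        Brref, pivots = Braw.rref()
        Brref = Brref[: len(pivots), :]
        dep = list(pivots)
        ind = [i for i in range(N) if i not in dep]
    if frame == "concentration":
        x0 = net.initial_concentrations()
    else:
        x0 = net.initial_counts()
    return _assemble(Brref, x0, ind, dep)
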