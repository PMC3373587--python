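"""Built-in example models.

Seven study models (F1-F7) plus closed-form oracle networks:

* F1/F2 — substrate-input Michaelis-Menten enzyme (malate dehydrogenase rate
  constants) at the cellular scale (0.5 fl, ~1204 enzyme copies) and in a
  small sub-cellular compartment (1e-17 l, 24 copies);
* F3/F4 — four-subunit cooperative enzyme with substrate input at 1 fl
  (~602 enzyme copies) and 0.1 fl (~60 copies);
* F5/F6/F7 — a single-gene negative-feedback circadian clock circuit
  (transcription, translation, nuclear transport, cooperative promoter
  binding by the nuclear protein, enzymatic degradation of mRNA and cytosolic
  protein) at 2 fl and 0.2 fl, the F7 variant with the repression rate
  constant 100x stronger; time unit is days;
* birth-death, dimerization and linear-chain oracle models with known
  closed-form statistics.

All networks are built in the concentration frame (molar) with rates from
the published constant tables; mesoscopic propensities use falling-factorial
mass action.
"""

from __future__ import annotations

import numpy as np

from .constants import AVOGADRO
from .network import NetworkBuilder, ReactionNetwork

__all__ = [
    "make_paper_model",
    "make_michaelis_menten",
    "make_cooperative_enzyme",
    "make_circadian_clock",
    "make_birth_death",
    "make_dimerization",
    "make_linear_chain",
    "MODEL_NAMES",
]

MODEL_NAMES = ("F1", "F2", "F3", "F4", "F5", "F6", "F7",
               "birth_death", "dimerization", "linear_chain")


def make_michaelis_menten(
    volume_liters: float,
    k_in: float = 1.8e-5,  # M/s
    k_out: float = 7.0,  # 1/s
    k1: float = 5e7,  # 1/(M s)
    k_minus1: float = 5.0,  # 1/s
    k2: float = 5.0,  # 1/s
    E_T: float = 4e-6,  # M, total enzyme, initially all free
) -> ReactionNetwork:
    """Substrate-input Michaelis-Menten scheme: input, binding, catalysis,
    product removal.  Substrate and product start empty."""
    b = NetworkBuilder("michaelis_menten", volume_liters)
    b.add_species("S", 0.0).add_species("E", E_T).add_species("ES", 0.0)
    b.add_species("P", 0.0)
    b.add_mass_action("input", {}, {"S": 1}, k_in, "k_in")
    b.add_mass_action("bind", {"S": 1, "E": 1}, {"ES": 1}, k1, "k1")
    b.add_mass_action("unbind", {"ES": 1}, {"S": 1, "E": 1}, k_minus1, "k_minus1")
    b.add_mass_action("cat", {"ES": 1}, {"E": 1, "P": 1}, k2, "k2")
    b.add_mass_action("output", {"P": 1}, {}, k_out, "k_out")
    b.add_parameter("E_T", E_T)
    return b.build()


def make_cooperative_enzyme(
    volume_liters: float,
    E_T: float = 1e-6,  # M total enzyme
) -> ReactionNetwork:
    """Four-subunit cooperative enzyme with substrate input.

    Sequential substrate binding ``S + ES_{i-1} <-> ES_i`` with rate
    constants chosen so the stepwise Michaelis constants decrease
    (20, 2, 0.2, 0.02 uM): positive cooperativity.  Every complex releases
    product at the common catalytic rate.
    """
    uM = 1e-6
    k_in, k_out, k_cat = 9.0 * uM, 10.0, 10.0
    k_on = [1.0 / uM, 10.0 / uM, 1e2 / uM, 1e3 / uM]  # 1/(M s)
    k_off = [10.0, 10.0, 10.0, 10.0]
    b = NetworkBuilder("cooperative_enzyme", volume_liters)
    b.add_species("S", 0.0).add_species("E", E_T)
    for i in range(1, 5):
        b.add_species(f"ES{i}", 0.0)
    b.add_species("P", 0.0)
    b.add_mass_action("input", {}, {"S": 1}, k_in, "k_in")
    prev = "E"
    for i in range(1, 5):
        cur = f"ES{i}"
        b.add_mass_action(f"bind{i}", {"S": 1, prev: 1}, {cur: 1}, k_on[i - 1],
                          f"k{i}")
        b.add_mass_action(f"unbind{i}", {cur: 1}, {"S": 1, prev: 1},
                          k_off[i - 1], f"k_minus{i}")
        b.add_mass_action(f"cat{i}", {cur: 1}, {prev: 1, "P": 1}, k_cat)
        prev = cur
    b.add_mass_action("output", {"P": 1}, {}, k_out, "k_out")
    b.add_parameter("k_cat", k_cat).add_parameter("E_T", E_T)
    return b.build()


def make_circadian_clock(
    volume_liters: float,
    strong_feedback: bool = False,
    E_M_total: float = 1e-6,  # M, mRNA-degrading enzyme
    E_P_total: float = 1e-6,  # M, protein-degrading enzyme
) -> ReactionNetwork:
    """Single-copy-gene negative-feedback clock circuit; time unit days.

    The free gene G transcribes mRNA M, which is translated into cytosolic
    protein Pc; Pc shuttles into the nucleus (PN) where it represses its own
    gene by binding the promoter in two cooperative steps (the second binding
    10x faster).  M and Pc are degraded both spontaneously and through
    Michaelis-Menten enzymes (E_M, E_P).  Transcription and promoter binding
    rates are volume-rescaled (k = Omega N_A k') so the macroscopic rate
    equations are volume independent despite the fixed single gene copy.
    """
    uM = 1e-6
    omega_eff = volume_liters * AVOGADRO
    # primed constants carry an implicit micromolar concentration unit; the
    # volume rescaling k = Omega*N_A*k' keeps the macroscopic equations
    # volume independent despite the fixed single gene copy
    k0p = 500.0 * uM  # transcription, M/d
    k1p = 0.5 * (100.0 if strong_feedback else 1.0)  # promoter binding, 1/(uM d)
    km1p = 0.5 * uM  # promoter unbinding carries the same rescaling
    b = NetworkBuilder("circadian_clock", volume_liters, time_unit="day")
    b.add_species("G", 1.0, kind="amount")
    b.add_species("GP", 0.0, kind="amount")
    b.add_species("GP2", 0.0, kind="amount")
    b.add_species("M", 0.0)
    b.add_species("Pc", 0.0)
    b.add_species("PN", 0.0)
    b.add_species("EM", E_M_total)
    b.add_species("CM", 0.0)
    b.add_species("EP", E_P_total)
    b.add_species("CP", 0.0)
    # transcription/translation and linear turnover
    b.add_mass_action("transcription", {"G": 1}, {"G": 1, "M": 1},
                      omega_eff * k0p, "k0")
    b.add_mass_action("translation", {"M": 1}, {"M": 1, "Pc": 1}, 5.0, "k_s")
    b.add_mass_action("mrna_decay", {"M": 1}, {}, 5.0, "k_dm")
    b.add_mass_action("protein_decay", {"Pc": 1}, {}, 5.0, "k_dp")
    # nuclear shuttling
    b.add_mass_action("import", {"Pc": 1}, {"PN": 1}, 5.0, "k_in")
    b.add_mass_action("export", {"PN": 1}, {"Pc": 1}, 5.0, "k_out")
    # cooperative promoter binding (second step 10x faster); both on- and
    # off-constants are volume rescaled, so promoter occupancy depends on the
    # nuclear-protein concentration and the switching is fast
    b.add_mass_action("bind1", {"G": 1, "PN": 1}, {"GP": 1},
                      omega_eff * k1p, "k1")
    b.add_mass_action("unbind1", {"GP": 1}, {"G": 1, "PN": 1},
                      omega_eff * km1p, "k_minus1")
    b.add_mass_action("bind2", {"GP": 1, "PN": 1}, {"GP2": 1},
                      omega_eff * 10.0 * k1p, "k2")
    b.add_mass_action("unbind2", {"GP2": 1}, {"GP": 1, "PN": 1},
                      omega_eff * km1p, "k_minus2")
    # enzymatic degradation of mRNA and cytosolic protein
    b.add_mass_action("m_bind", {"M": 1, "EM": 1}, {"CM": 1}, 0.5 / uM, "k3")
    b.add_mass_action("m_unbind", {"CM": 1}, {"M": 1, "EM": 1}, 0.5, "k_minus3")
    b.add_mass_action("m_cat", {"CM": 1}, {"EM": 1}, 0.5, "k_cat3")
    b.add_mass_action("p_bind", {"Pc": 1, "EP": 1}, {"CP": 1}, 10.0 / uM, "k4")
    b.add_mass_action("p_unbind", {"CP": 1}, {"Pc": 1, "EP": 1}, 5.0, "k_minus4")
    b.add_mass_action("p_cat", {"CP": 1}, {"EP": 1}, 10.0, "k_cat4")
    return b.build()


def make_birth_death(
    k_in: float = 1e-6, k_out: float = 1.0, volume_liters: float = 1e-15
) -> ReactionNetwork:
    """Input/decay of one species; stationary law Poisson(k_in*Omega_eff/k_out)."""
    if min(k_in, k_out) <= 0:
        raise ValueError("rates must be positive")
    b = NetworkBuilder("birth_death", volume_liters)
    b.add_species("X", 0.0)
    b.add_mass_action("birth", {}, {"X": 1}, k_in, "k_in")
    b.add_mass_action("death", {"X": 1}, {}, k_out, "k_out")
    return b.build()


def make_dimerization(
    k_in: float = 1e-6, k_dim: float = 1e6, volume_liters: float = 1e-15
) -> ReactionNetwork:
    """Input plus dimerisation sink 2X -> 0; the simplest network with a
    non-vanishing mesoscopic mean correction."""
    b = NetworkBuilder("dimerization", volume_liters)
    b.add_species("X", 0.0)
    b.add_mass_action("birth", {}, {"X": 1}, k_in, "k_in")
    b.add_mass_action("dimerize", {"X": 2}, {}, k_dim, "k_dim")
    return b.build()


def make_linear_chain(volume_liters: float = 1e-15) -> ReactionNetwork:
    """Unimolecular input -> X1 -> X2 -> out chain (EMRE equals RE exactly)."""
    b = NetworkBuilder("linear_chain", volume_liters)
    b.add_species("X1", 0.0).add_species("X2", 0.0)
    b.add_mass_action("input", {}, {"X1": 1}, 1e-6, "k_in")
    b.add_mass_action("convert", {"X1": 1}, {"X2": 1}, 2.0, "k_c")
    b.add_mass_action("output", {"X2": 1}, {}, 1.0, "k_out")
    return b.build()


_FIXTURES = {
    "F1": lambda: make_michaelis_menten(5e-16),
    "F2": lambda: make_michaelis_menten(1e-17),
    "F3": lambda: make_cooperative_enzyme(1e-15),
    "F4": lambda: make_cooperative_enzyme(1e-16),
    "F5": lambda: make_circadian_clock(2e-15, strong_feedback=False),
    "F6": lambda: make_circadian_clock(2e-16, strong_feedback=False),
    "F7": lambda: make_circadian_clock(2e-16, strong_feedback=True),
    "birth_death": make_birth_death,
    "dimerization": make_dimerization,
    "linear_chain": make_linear_chain,
}


def make_paper_model(name: str, volume_liters: float | None = None,
                     **overrides) -> ReactionNetwork:
    """Build a registered study model by name (``F1`` ... ``F7`` or an
    oracle model), optionally overriding the compartment volume."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    if volume_liters is None and not overrides:
        net = _FIXTURES[name]()
    else:
        base = {
            "F1": (make_michaelis_menten, 5e-16),
            "F2": (make_michaelis_menten, 1e-17),
            "F3": (make_cooperative_enzyme, 1e-15),
            "F4": (make_cooperative_enzyme, 1e-16),
            "F5": (make_circadian_clock, 2e-15),
            "F6": (make_circadian_clock, 2e-16),
            "F7": (make_circadian_clock, 2e-16),
        }
        if name in base:
            fn, vol = base[name]
            if name == "F7":
                overrides.setdefault("strong_feedback", True)
            net = fn(volume_liters or vol, **overrides)
        else:
            net = _FIXTURES[name](volume_liters=volume_liters, **overrides) \
                if volume_liters else _FIXTURES[name](**overrides)
    net.name = name
    return net
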