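"""Replication studies: the noise statistics of the built-in models.

Each function rebuilds its model from the published rate constants, runs the
analysis end to end and returns the headline numbers (coefficients of
variation, mean corrections, oscillation periods).  These are the quantities
the package's validation is anchored to; the acceptance script reports them.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import welch

from .models import make_paper_model
from .solvers import (
    SolverConfig,
    compile_system,
    emre_steady,
    emre_timecourse,
)
from .ssa import SSAConfig, run_ensemble

__all__ = [
    "mm_cellular_noise",
    "mm_small_noise",
    "mm_small_lna_vs_ssa",
    "cooperative_noise",
    "clock_emre_period",
    "clock_ssa_period",
]


def mm_cellular_noise() -> dict:
    """Steady-state noise of the Michaelis-Menten model at the cellular
    scale (0.5 fl): LNA coefficients of variation of substrate and product."""
    net = make_paper_model("F1")
    res = emre_steady(compile_system(net))
    iS, iP = net.species_index("S"), net.species_index("P")
    return {
        "cv_substrate": float(res.cv[iS]),
        "cv_product": float(res.cv[iP]),
        "result": res,
    }


def mm_small_noise() -> dict:
    """Small-compartment (24-enzyme) Michaelis-Menten steady state: the
    percent excess of the corrected substrate mean over the macroscopic
    prediction, and the LNA substrate CV."""
    net = make_paper_model("F2")
    res = emre_steady(compile_system(net))
    iS = net.species_index("S")
    excess = 100.0 * (res.emre_ss[iS] - res.phi_ss[iS]) / res.phi_ss[iS]
    return {
        "excess_percent": float(excess),
        "cv_substrate": float(res.cv[iS]),
        "result": res,
    }


def mm_small_lna_vs_ssa(
    seed: int, n_realizations: int = 5000, t_final: float = 20.0
) -> dict:
    """Relative overestimation of the substrate CV by the LNA against an
    ensemble-averaged simulation in the small compartment.

    The simulated CV is taken from the quasi-stationary window (the second
    half of the run), as sqrt(time-averaged variance) / time-averaged mean.
    """
    net = make_paper_model("F2")
    iS = net.species_index("S")
    cv_lna = mm_small_noise()["cv_substrate"]
    ens = run_ensemble(
        net,
        SSAConfig(t_final=t_final, n_grid=int(20 * t_final) + 1,
                  n_realizations=n_realizations, seed=seed),
    )
    window = ens.t >= t_final / 2.0
    mean = ens.mean[window, iS].mean()
    var = ens.var[window, iS].mean()
    cv_ssa = float(np.sqrt(var) / mean)
    return {
        "cv_lna": cv_lna,
        "cv_ssa": cv_ssa,
        "overestimate_percent": 100.0 * (cv_lna - cv_ssa) / cv_ssa,
    }


def cooperative_noise() -> dict:
    """Four-subunit cooperative enzyme at the cellular scale (1 fl):
    LNA substrate CV and the substrate fluctuation size in molecules."""
    net = make_paper_model("F3")
    res = emre_steady(compile_system(net))
    iS = net.species_index("S")
    return {
        "cv_substrate": float(res.cv[iS]),
        "sd_substrate_molecules": float(res.sd[iS] * net.system_size),
        "result": res,
    }


def _peak_times(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Times of interior local maxima, after the first local minimum.

    Discarding everything before the first minimum removes the initial
    relaxation transient (e.g. the transcription burst before the negative
    feedback engages), which is not part of the damped oscillation."""
    maxima = (x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])
    minima = (x[1:-1] < x[:-2]) & (x[1:-1] < x[2:])
    if minima.any():
        first_min = t[1:-1][minima][0]
        maxima &= t[1:-1] > first_min
    return t[1:-1][maxima]


def clock_emre_period(t_final: float = 5.0, n_points: int = 501) -> dict:
    """Mean peak-to-peak interval of the corrected-mean (EMRE) mRNA
    trajectory of the strong-feedback clock model at 0.2 fl, together with
    the ringing amplitude contrast against the macroscopic equations."""
    net = make_paper_model("F7")
    tc = emre_timecourse(
        compile_system(net), SolverConfig(t_final=t_final, n_points=n_points)
    )
    iM = net.species_index("M")
    peaks = _peak_times(tc.t, tc.emre_mean[:, iM])
    period = float(np.diff(peaks).mean()) if len(peaks) >= 2 else np.nan
    late = tc.t >= 2.0  # ringing after the initial transient has passed
    amp_emre = float(np.ptp(tc.emre_mean[late, iM]))
    amp_re = float(np.ptp(tc.phi[late, iM]))
    return {
        "period_days": period,
        "ringing_emre": amp_emre,
        "ringing_re": amp_re,
        "result": tc,
    }


def clock_ssa_period(
    seed: int, t_final: float = 55.0, discard: float = 5.0
) -> dict:
    """Dominant period of the cytosolic-protein copy-number series in a
    single stochastic realization of the strong-feedback clock model,
    from the maximum of a Welch-averaged periodogram."""
    net = make_paper_model("F7")
    dt = 0.01
    ens = run_ensemble(
        net,
        SSAConfig(t_final=t_final, n_grid=int(t_final / dt) + 1,
                  n_realizations=1, seed=seed),
    )
    window = ens.t >= discard
    period = {}
    for sp in ("Pc", "M"):
        x = ens.mean_counts()[window, net.species_index(sp)]
        f, p = welch(x - x.mean(), fs=1.0 / dt, nperseg=int(10.0 / dt))
        sel = (f > 1 / 5.0) & (f < 1 / 0.3)  # search periods of 0.3-5 days
        period[sp] = float(1.0 / f[sel][np.argmax(p[sel])])
    return {
        "period_days": period["Pc"],
        "period_days_mrna": period["M"],
        "result": ens,
    }
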