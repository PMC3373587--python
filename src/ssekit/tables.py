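"""Tab-separated export of analysis results.

One writer per result kind, all with a header row, full-precision scientific
floats and deterministic column order (the species order of the model), so
re-reading a table reproduces the computed values exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .solvers import SteadyStateResult, TimeCourseResult
from .ssa import EnsembleResult

__all__ = ["write_table", "steady_state_frame", "timecourse_frame", "ensemble_frame"]


def steady_state_frame(res: SteadyStateResult, species=None) -> pd.DataFrame:
    ids = res.net.species_ids
    sel = [ids.index(s) for s in species] if species else range(len(ids))
    rows = []
    for i in sel:
        row = {
            "species": ids[i],
            "re_mean": res.phi_ss[i],
            "emre_mean": res.emre_ss[i] if res.emre_ss is not None else np.nan,
            "sd": res.sd[i] if res.cov_ss is not None else np.nan,
            "cv": res.cv[i] if res.cov_ss is not None else np.nan,
        }
        if res.cov_ss is not None:
            for j in sel:
                row[f"cov_{ids[j]}"] = res.cov_ss[i, j]
        rows.append(row)
    return pd.DataFrame(rows)


def timecourse_frame(res: TimeCourseResult, species=None) -> pd.DataFrame:
    ids = res.net.species_ids
    sel = [ids.index(s) for s in species] if species else list(range(len(ids)))
    data = {"time": res.t}
    for i in sel:
        data[f"re_{ids[i]}"] = res.phi[:, i]
    if res.cov is not None:
        sd = res.sd
        for i in sel:
            data[f"sd_{ids[i]}"] = sd[:, i]
        for a, i in enumerate(sel):
            for j in sel[a + 1:]:
                data[f"cov_{ids[i]}_{ids[j]}"] = res.cov[:, i, j]
    if res.emre_mean is not None:
        for i in sel:
            data[f"emre_{ids[i]}"] = res.emre_mean[:, i]
    return pd.DataFrame(data)


def ensemble_frame(res: EnsembleResult, species=None) -> pd.DataFrame:
    ids = res.species_ids
    sel = [ids.index(s) for s in species] if species else list(range(len(ids)))
    data = {"time": res.t}
    for i in sel:
        data[f"mean_{ids[i]}"] = res.mean[:, i]
    for i in sel:
        data[f"var_{ids[i]}"] = res.var[:, i]
    for a, i in enumerate(sel):
        for j in sel[a + 1:]:
            data[f"cov_{ids[i]}_{ids[j]}"] = res.cov[:, i, j]
    df = pd.DataFrame(data)
    df["n_realizations"] = res.n_realizations
    df["seed"] = res.seed
    return df


def write_table(result, path, species=None) -> None:
    """Write any result object as a TSV file (full float precision)."""
    if isinstance(result, SteadyStateResult):
        df = steady_state_frame(result, species)
    elif isinstance(result, TimeCourseResult):
        df = timecourse_frame(result, species)
    elif isinstance(result, EnsembleResult):
        df = ensemble_frame(result, species)
    else:
        raise TypeError(f"cannot tabulate {type(result).__name__}")
    df.to_csv(path, sep="\t", index=False, float_format="%.17e")
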