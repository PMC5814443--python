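"""Orthogonal (quasi-orthogonal) ribosome pools.

A pool is created by transcribing a synthetic 16S rRNA (rho) that
associates reversibly with the shared empty-ribosome protein p_R,
yielding circuit-only ribosomes P.  Pools are therefore only
quasi-orthogonal: they drain p_R from host ribosome assembly.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    CellModel,
    InvalidParameterError,
    OPoolSpec,
    solve_steady_state,
)

__all__ = ["OPoolSpec", "register_o_pool", "pool_size_response"]


def register_o_pool(model: CellModel, spec: OPoolSpec) -> CellModel:
    """Add an orthogonal ribosome pool to the model (in place).

    Registers species ``rho_<id>`` and ``P_<id>`` with the reversible
    assembly reaction against p_R and energy-dependent o-rRNA
    transcription; the pool translates only circuit genes allocated
    to it.
    """
    return model.add_pool(spec)


def pool_size_response(model: CellModel,
                       omega_rho_values: Sequence[float],
                       tol: Optional[float] = None) -> pd.DataFrame:
    """Steady-state pool size and host physiology vs o-rRNA supply.

    Sweeps the single registered pool's maximal o-rRNA transcription
    rate and reports steady-state P, free host R and growth rate, the
    numbers behind the strongly non-linear burden response of the host.
    """
    if len(model.pools) != 1:
        raise InvalidParameterError("model must have exactly one o-pool")
    vals = list(omega_rho_values)
    if not vals:
        raise InvalidParameterError("omega_rho grid is empty")
    pid = next(iter(model.pools))
    work = model.clone()
    ix = work.index
    rows = []
    warm = None
    for w in vals:
        work.pools[pid].omega_rho = float(w)
        work.invalidate()
        ss = solve_steady_state(work, warm_start=warm,
                                **({"tol": tol} if tol is not None else {}))
        warm = ss.state
        rows.append({"omega_rho": w,
                     "P": ss.state[ix[f"P_{pid}"]],
                     "rho": ss.state[ix[f"rho_{pid}"]],
                     "R": ss.state[ix["R"]],
                     "lam": ss.lam,
                     "converged": ss.converged})
    return pd.DataFrame(rows)
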