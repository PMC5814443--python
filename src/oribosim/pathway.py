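"""Five-enzyme metabolic pathway coupled to the expression model.

Models the violacein-style chain: a constant external substrate
(l-tryptophan held at ``substrate_level``) is converted through four
intermediates to the final product V by five enzymes.  Enzyme A is
constitutively transcribed from its own promoter; enzymes B-E form a
polycistronic cassette sharing one transcription rate and RBS strength
and differing only in length (B defaults to 3x the others, reflecting
its outsized ribosome sequestration).  Each step is irreversible
Michaelis-Menten: ``v_i = kcat_i * p_i * S_i / (Km_i + S_i)``.
Intermediates and product are diluted by growth.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    CellModel,
    CircuitGene,
    InvalidParameterError,
    PathwaySpec,
    solve_steady_state,
)

__all__ = ["PathwaySpec", "register_pathway", "induction_dose_response"]

ENZYMES = ("vioA", "vioB", "vioC", "vioD", "vioE")


def register_pathway(model: CellModel, spec: PathwaySpec,
                     vioA_pool: str = "host") -> CellModel:
    """Attach the enzyme genes, intermediates I1..I4 and product V.

    ``vioA_pool`` selects the ribosome pool translating the first,
    constitutive enzyme; the downstream cassette always uses the host
    pool.
    """
    if model.pathway is not None:
        raise InvalidParameterError("model already carries a pathway")
    if vioA_pool != "host" and vioA_pool not in model.pools:
        raise InvalidParameterError(f"unknown pool '{vioA_pool}'")
    lengths = spec.lengths
    model.add_gene(CircuitGene("vioA", omega=spec.omega_A, o=spec.o,
                               n=lengths[0], pool=vioA_pool, b=spec.b,
                               u=spec.u, delta_m=spec.delta_m))
    for name, n in zip(ENZYMES[1:], lengths[1:]):
        model.add_gene(CircuitGene(name, omega=spec.omega_BCDE, o=spec.o,
                                   n=n, pool="host", b=spec.b, u=spec.u,
                                   delta_m=spec.delta_m))
    model.pathway = spec
    model.pathway_enzymes = list(ENZYMES)
    model.invalidate()
    return model


def set_cassette_induction(model: CellModel, omega_BCDE: float) -> None:
    """Set the shared transcription rate of the vioBCDE cassette."""
    for name in ENZYMES[1:]:
        model.genes[name].omega = float(omega_BCDE)
    model.pathway.omega_BCDE = float(omega_BCDE)
    model.invalidate()


def induction_dose_response(model: CellModel,
                            omega_BCDE_grid: Sequence[float],
                            warm_start: Optional[np.ndarray] = None
                            ) -> pd.DataFrame:
    """Steady-state enzymes and product across cassette induction.

    ``V_scaled`` is the product scaled by the largest amount achieved
    across the grid, so its maximum is exactly 1.
    """
    grid = np.asarray(list(omega_BCDE_grid), dtype=float)
    if grid.size == 0:
        raise InvalidParameterError("omega_BCDE grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise InvalidParameterError("grid must be strictly increasing")
    if model.pathway is None:
        raise InvalidParameterError("no pathway registered")
    work = model.clone()
    ix = work.index
    rows = []
    warm = warm_start
    for w in grid:
        set_cassette_induction(work, w)
        ss = solve_steady_state(work, warm_start=warm)
        warm = ss.state
        row = {"omega_BCDE": w, "lam": ss.lam, "converged": ss.converged,
               "V": ss.state[ix["V"]]}
        for name in ENZYMES:
            row[f"p_{name}"] = ss.state[ix[f"p_{name}"]]
        for j in range(1, 5):
            row[f"I{j}"] = ss.state[ix[f"I{j}"]]
        rows.append(row)
    df = pd.DataFrame(rows)
    vmax = df.loc[df["converged"], "V"].max()
    df["V_scaled"] = df["V"] / vmax if vmax and vmax > 0 else 0.0
    return df
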