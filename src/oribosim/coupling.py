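"""Isocost-line quantification of resource-mediated gene coupling.

Two reporter genes share the cell's translational resources: one is
constitutively transcribed (GFP, by convention) and the other induced
over a transcription-rate sweep (RFP).  Plotting the constitutive
against the induced steady-state protein traces out an isocost line;
its slope measures how much constitutive expression is lost per unit
of induced expression, i.e. the gene-gene coupling.

Configuration labels
--------------------
Two-letter keys give the ribosome pool of the *induced* then the
*constitutive* gene:

====  ==========================  =========================
key   induced (RFP)               constitutive (GFP)
====  ==========================  =========================
hh    host pool                   host pool
oo    orthogonal pool             orthogonal pool
ho    host pool                   orthogonal pool
oh    orthogonal pool             host pool
====  ==========================  =========================
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    CellModel,
    CircuitGene,
    HostParameters,
    InvalidParameterError,
    OPoolSpec,
    solve_steady_state,
)

logger = logging.getLogger("oribosim")

__all__ = [
    "CircuitGene", "IsocostResult", "add_circuit_gene", "fit_isocost",
    "isocost_sweep", "build_reporter_model", "configuration_comparison",
    "two_pool_decoupling", "TwoPoolResult", "CONFIGURATIONS",
]

CONFIGURATIONS = ("hh", "oo", "ho", "oh")


def add_circuit_gene(model: CellModel, gene: CircuitGene) -> CellModel:
    """Register a heterologous gene (mRNA, complex, protein species).

    The gene's mRNA binds only the ribosome pool it is allocated to;
    its protein counts towards growth like any other translation
    product.
    """
    return model.add_gene(gene)


def fit_isocost(x, y) -> tuple[float, float, float]:
    """Ordinary least squares line through all points.

    Returns (slope, intercept, r_squared).  Centered closed form, so a
    constant ``y`` yields a slope of exactly zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidParameterError("x and y must have equal length")
    if x.size < 2:
        return float("nan"), float("nan"), float("nan")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        return float("nan"), float("nan"), float("nan")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    sst = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if sst == 0.0 else 1.0 - float(np.sum(resid ** 2)) / sst
    return slope, float(intercept), r2


@dataclass
class IsocostResult:
    """Induction sweep with the fitted coupling measure.

    ``slope`` is fitted on raw molecule counts; ``slope_norm`` on the
    reporters normalised by their maxima over the sweep (the scale on
    which configurations are compared).
    """

    omega_induced: np.ndarray
    rfp_ss: np.ndarray            # induced reporter, molecules
    gfp_ss: np.ndarray            # constitutive reporter, molecules
    converged: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    slope_norm: float
    intercept_norm: float
    induced: str = "RFP"
    constitutive: str = "GFP"
    config: str = ""
    omega_rho: Optional[float] = None
    states: Optional[np.ndarray] = None

    @property
    def rfp_norm(self) -> np.ndarray:
        mx = np.nanmax(self.rfp_ss)
        return self.rfp_ss / mx if mx > 0 else np.zeros_like(self.rfp_ss)

    @property
    def gfp_norm(self) -> np.ndarray:
        mx = np.nanmax(self.gfp_ss)
        return self.gfp_ss / mx if mx > 0 else np.zeros_like(self.gfp_ss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "omega_induced": self.omega_induced,
            "rfp_ss": self.rfp_ss,
            "gfp_ss": self.gfp_ss,
            "rfp_norm": self.rfp_norm,
            "gfp_norm": self.gfp_norm,
            "converged": self.converged,
        })

    def summary(self) -> dict:
        return {
            "config": self.config,
            "omega_rho": self.omega_rho,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "slope_norm": self.slope_norm,
            "intercept_norm": self.intercept_norm,
            "n_points": int(len(self.omega_induced)),
            "n_converged": int(np.sum(self.converged)),
        }


def isocost_sweep(model: CellModel, induced: str, constitutive: str,
                  omega_grid: Sequence[float],
                  warm_start: Optional[np.ndarray] = None,
                  keep_states: bool = False) -> IsocostResult:
    """Solve one steady state per induction level and fit the isocost line.

    Each grid point is warm-started from the previous solution.
    Non-converged points are retained in the tables but excluded from
    the straight-line fit.
    """
    grid = np.asarray(list(omega_grid), dtype=float)
    if grid.size == 0:
        raise InvalidParameterError("omega grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise InvalidParameterError("omega grid must be strictly increasing")
    for g in (induced, constitutive):
        if g not in model.genes:
            raise InvalidParameterError(f"gene '{g}' not registered")

    work = model.clone()
    ix = work.index
    i_rfp, i_gfp = ix[f"p_{induced}"], ix[f"p_{constitutive}"]
    rfp = np.empty(grid.size)
    gfp = np.empty(grid.size)
    conv = np.zeros(grid.size, dtype=bool)
    states = np.empty((grid.size, work.n_species)) if keep_states else None
    warm = warm_start
    for i, w in enumerate(grid):
        work.genes[induced].omega = float(w)
        work.invalidate()
        ss = solve_steady_state(work, warm_start=warm)
        warm = ss.state
        rfp[i], gfp[i] = ss.state[i_rfp], ss.state[i_gfp]
        conv[i] = ss.converged
        if keep_states:
            states[i] = ss.state
        if not ss.converged:
            logger.warning("isocost point omega=%g not converged "
                           "(residual %.2e); excluded from fit",
                           w, ss.residual_norm)

    slope, intercept, r2 = fit_isocost(rfp[conv], gfp[conv])
    mr = np.max(rfp[conv]) if conv.any() else 0.0
    mg = np.max(gfp[conv]) if conv.any() else 0.0
    if mr > 0 and mg > 0:
        sn, inn, _ = fit_isocost(rfp[conv] / mr, gfp[conv] / mg)
    else:
        sn, inn = float("nan"), float("nan")
    return IsocostResult(grid, rfp, gfp, conv, slope, intercept, r2,
                         sn, inn, induced=induced, constitutive=constitutive,
                         states=states)


def build_reporter_model(params: Optional[HostParameters] = None,
                         config: str = "hh",
                         omega_rho: float = 500.0,
                         omega_constitutive: float = 100.0,
                         pool_spec: Optional[OPoolSpec] = None) -> CellModel:
    """Host model plus one o-pool and the RFP/GFP reporter pair.

    ``config`` allocates the induced/constitutive genes to pools per
    the module-level table.  The o-pool is registered even for the
    all-host configuration so that pool-size effects stay comparable.
    """
    if config not in CONFIGURATIONS:
        raise InvalidParameterError(f"unknown configuration '{config}'")
    m = CellModel(params)
    spec = pool_spec if pool_spec is not None else OPoolSpec("o1")
    spec.omega_rho = float(omega_rho)
    m.add_pool(spec)
    ind_pool = "host" if config[0] == "h" else spec.pool_id
    con_pool = "host" if config[1] == "h" else spec.pool_id
    m.add_gene(CircuitGene("RFP", omega=1.0, pool=ind_pool))
    m.add_gene(CircuitGene("GFP", omega=float(omega_constitutive),
                           pool=con_pool))
    return m


def configuration_comparison(model_base: Optional[CellModel],
                             configs: Sequence[str] = CONFIGURATIONS,
                             omega_grid: Sequence[float] = None,
                             omega_rho: float = 500.0,
                             omega_constitutive: float = 100.0) -> pd.DataFrame:
    """Isocost slope of each RBS configuration under identical sweeps.

    ``model_base`` supplies the host parameters (its genes/pools are
    not reused); pass None for defaults.
    """
    if omega_grid is None:
        omega_grid = np.logspace(0, 3, 10)
    params = model_base.params if model_base is not None else None
    rows = []
    for cfg in configs:
        if cfg not in CONFIGURATIONS:
            raise InvalidParameterError(f"unknown configuration '{cfg}'")
        m = build_reporter_model(params, cfg, omega_rho=omega_rho,
                                 omega_constitutive=omega_constitutive)
        res = isocost_sweep(m, "RFP", "GFP", omega_grid)
        row = res.summary()
        row["config"] = cfg
        row["omega_rho"] = omega_rho
        row["gfp_max"] = float(np.nanmax(res.gfp_ss))
        row["rfp_max"] = float(np.nanmax(res.rfp_ss))
        # below ~one molecule per cell a reporter is effectively silent and
        # its isocost fit meaningless
        floor = 1.0
        degenerate = (not np.any(res.converged)) or row["rfp_max"] < floor \
            or row["gfp_max"] < floor or not np.isfinite(res.slope)
        row["degenerate"] = bool(degenerate)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TwoPoolResult:
    best_specs: tuple
    drop_pct: float
    table: pd.DataFrame
    best_sweep: IsocostResult


def gfp_drop_pct(sweep: IsocostResult) -> float:
    """Percent fall of the constitutive reporter from min to max induction."""
    g = sweep.gfp_ss[sweep.converged]
    if g.size < 2 or g[0] <= 0:
        return float("nan")
    return 100.0 * (g[0] - g[-1]) / g[0]


def two_pool_decoupling(model: CellModel, induced: str, constitutive: str,
                        omega_grid: Sequence[float],
                        omega_rho_grid: Sequence[float]) -> TwoPoolResult:
    """Dedicate one o-pool to each gene and optimise both pool sizes.

    Grid-searches the two pools' o-rRNA transcription rates to minimise
    the magnitude of the constitutive reporter's relative drop across
    the induction sweep; the winning sweep and the full grid table are
    returned so the trade-off surface stays inspectable.
    """
    if len(model.pools) != 2:
        raise InvalidParameterError("model must have exactly two o-pools")
    wvals = list(omega_rho_grid)
    if not wvals:
        raise InvalidParameterError("omega_rho grid is empty")
    pools = list(model.pools)
    con_pool = model.genes[constitutive].pool
    ind_pool = model.genes[induced].pool
    if {con_pool, ind_pool} != set(pools):
        raise InvalidParameterError("each gene must own one distinct pool")

    work = model.clone()
    rows = []
    best = None
    warm0 = None
    for w_con, w_ind in itertools.product(wvals, wvals):
        work.pools[con_pool].omega_rho = float(w_con)
        work.pools[ind_pool].omega_rho = float(w_ind)
        work.invalidate()
        res = isocost_sweep(work, induced, constitutive, omega_grid,
                            warm_start=warm0, keep_states=True)
        if res.converged[0]:
            warm0 = res.states[0]
        drop = gfp_drop_pct(res)
        rfp = res.rfp_ss[res.converged]
        rises = bool(rfp.size >= 2 and rfp[-1] > rfp[0])
        rows.append({"omega_rho_constitutive": w_con,
                     "omega_rho_induced": w_ind,
                     "gfp_drop_pct": drop,
                     "induced_rises": rises,
                     "slope_norm": res.slope_norm,
                     "n_converged": int(res.converged.sum())})
        if np.isfinite(drop) and (best is None or abs(drop) < abs(best[0])):
            best = (drop, w_con, w_ind, res)
    if best is None:
        raise InvalidParameterError("no grid point produced a valid sweep")
    drop, w_con, w_ind, res = best
    specs = (model.pools[con_pool].__class__(**{**vars(model.pools[con_pool]),
                                                "omega_rho": w_con}),
             model.pools[ind_pool].__class__(**{**vars(model.pools[ind_pool]),
                                                "omega_rho": w_ind}))
    return TwoPoolResult(specs, drop, pd.DataFrame(rows), res)
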