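"""Dynamic o-rRNA resource allocation controller.

A constitutively transcribed repressor is translated by the orthogonal
pool it controls and represses o-rRNA transcription through a Hill
factor ``1/(1+(p_F/k_D)^h)``.  Because its mRNA level is constant,
the repressor's translation rate senses competition for o-ribosomes:
when circuit demand rises, repressor production falls, repression is
relieved and more o-rRNA is made, co-opting additional empty
ribosomes from the host.  The module covers the step response of the
closed loop, matching an open-loop (fixed o-rRNA supply) reference,
grid-search design, one-at-a-time sensitivity sweeps and a Monte
Carlo robustness study.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import (
    CellModel,
    CircuitGene,
    ControllerParams,
    HostParameters,
    InvalidParameterError,
    OPoolSpec,
    repression_factor,
    simulate,
    solve_steady_state,
    state_frame,
)
from .coupling import IsocostResult, isocost_sweep

logger = logging.getLogger("oribosim")

__all__ = [
    "ControllerParams", "repression_factor", "register_controller",
    "build_controlled_reporter_model", "open_loop_variant",
    "closed_loop_step_response", "tune_open_loop_match",
    "design_controller", "sensitivity_sweep", "robustness_mc",
]

# parameters perturbed in the robustness Monte Carlo: everything
# controlling o-rRNA supply and the controller protein
PERTURBED_POOL = ("omega_rho", "o_rho", "b_rho", "u_rho", "delta_rho")
PERTURBED_CTRL = ("omega_F", "o_F", "b_F", "u_F", "n_F", "k_D", "h")

DESIGN_PARAMS = ("omega_rho_max", "b_F", "k_D", "h", "omega_F")


def register_controller(model: CellModel, ctrl: ControllerParams) -> CellModel:
    """Attach the repressor gene and gate the target pool's o-rRNA."""
    return model.set_controller(ctrl)


def build_controlled_reporter_model(params: Optional[HostParameters] = None,
                                    omega_rho: float = 500.0,
                                    omega_constitutive: float = 100.0,
                                    ctrl: Optional[ControllerParams] = None,
                                    with_controller: bool = True) -> CellModel:
    """One repressible o-pool, both reporters on it, optional controller."""
    m = CellModel(params)
    m.add_pool(OPoolSpec("o1", omega_rho=float(omega_rho), repressible=True))
    m.add_gene(CircuitGene("RFP", omega=1.0, pool="o1"))
    m.add_gene(CircuitGene("GFP", omega=float(omega_constitutive), pool="o1"))
    if with_controller:
        m.set_controller(ctrl if ctrl is not None
                         else ControllerParams(target_pool="o1"))
    return m


def open_loop_variant(model: CellModel,
                      omega_rho: Optional[float] = None) -> CellModel:
    """Same circuit without the controller (fixed o-rRNA supply)."""
    ol = model.clone()
    ol.controller = None
    if omega_rho is not None:
        for spec in ol.pools.values():
            spec.omega_rho = float(omega_rho)
    ol.invalidate()
    return ol


def closed_loop_step_response(model: CellModel,
                              induction: tuple,
                              horizon: float,
                              n_points: int = 400) -> pd.DataFrame:
    """Trajectories of the controller responding to a step in demand.

    ``induction = (gene, omega_before, omega_after, t_step)``.  The
    model is first solved to steady state at ``omega_before``, then
    integrated through the step to ``horizon``.  Returns the full time
    courses (all species plus the instantaneous repression factor).
    """
    gene, w0, w1, t_step = induction
    if gene not in model.genes:
        raise InvalidParameterError(f"gene '{gene}' not registered")
    if not 0 <= t_step <= horizon:
        raise InvalidParameterError("t_step must lie within the horizon")
    pre = model.clone()
    pre.genes[gene].omega = float(w0)
    pre.invalidate()
    ss = solve_steady_state(pre)
    t_pre = np.linspace(0.0, t_step, max(2, int(n_points * t_step / horizon))) \
        if t_step > 0 else np.array([0.0])
    if t_step > 0:
        sol = simulate(pre, ss.state, (0.0, t_step), t_eval=t_pre)
        y_mid = sol.y[:, -1]
        traj_t = [sol.t]
        traj_y = [sol.y]
    else:
        y_mid = ss.state
        traj_t, traj_y = [], []

    post = model.clone()
    post.genes[gene].omega = float(w1)
    post.invalidate()
    t_post = np.linspace(t_step, horizon, max(2, n_points - len(t_pre)))
    sol2 = simulate(post, y_mid, (t_step, horizon), t_eval=t_post)
    traj_t.append(sol2.t)
    traj_y.append(sol2.y)

    t = np.concatenate(traj_t)
    y = np.hstack(traj_y)
    df = state_frame(model, y.T, t=t)
    if model.controller is not None:
        ctrl = model.controller
        df["repression_factor"] = [
            repression_factor(v, ctrl.k_D, ctrl.h) for v in df["p_F"]]
    return df


def _constitutive_ss(model: CellModel, constitutive: str,
                     warm=None) -> tuple[float, np.ndarray]:
    ss = solve_steady_state(model, warm_start=warm)
    return float(ss.state[model.index[f"p_{constitutive}"]]), ss.state


def tune_open_loop_match(model_cl: CellModel,
                         model_ol: Optional[CellModel] = None,
                         constitutive: str = "GFP",
                         bracket: tuple = (1e-2, 1e4),
                         rel_tol: float = 1e-3) -> float:
    """Open-loop omega_rho matching the closed loop's resting expression.

    Solves for the fixed o-rRNA transcription rate at which the
    uncontrolled circuit produces the same pre-induction constitutive
    protein as the closed loop, within ``rel_tol`` relative.
    """
    target, _ = _constitutive_ss(model_cl, constitutive)
    if target <= 0:
        raise InvalidParameterError("closed loop expresses no protein to match")
    ol = model_ol.clone() if model_ol is not None else open_loop_variant(model_cl)
    pid = next(iter(ol.pools))
    cache: dict[float, float] = {}
    warm = {"state": None}

    def f(logw: float) -> float:
        w = 10.0 ** logw
        if w not in cache:
            ol.pools[pid].omega_rho = w
            ol.invalidate()
            cache[w], warm["state"] = _constitutive_ss(ol, constitutive,
                                                       warm=warm["state"])
        return cache[w] - target

    lo, hi = np.log10(bracket[0]), np.log10(bracket[1])
    grid = np.linspace(lo, hi, 13)
    vals = [f(g) for g in grid]
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            return float(10.0 ** a)
        if fa * fb < 0:
            logw = brentq(f, a, b, xtol=1e-6)
            w = float(10.0 ** logw)
            if abs(f(logw)) > rel_tol * target:
                raise InvalidParameterError(
                    "open-loop match did not reach the requested tolerance")
            return w
    raise InvalidParameterError(
        "no omega_rho in the bracket matches the closed-loop expression")


def _apply_design(model: CellModel, cand: dict) -> CellModel:
    m = model.clone()
    pid = m.controller.target_pool
    if "omega_rho_max" in cand:
        m.pools[pid].omega_rho = float(cand["omega_rho_max"])
    ctrl_updates = {k: float(v) for k, v in cand.items()
                    if k in ("b_F", "k_D", "h", "omega_F")}
    if ctrl_updates:
        m.controller = replace(m.controller, **ctrl_updates)
    m.invalidate()
    return m


def _evaluate_circuit(model: CellModel, omega_grid, induced="RFP",
                      constitutive="GFP", warm0=None) -> tuple:
    res = isocost_sweep(model, induced, constitutive, omega_grid,
                        warm_start=warm0, keep_states=True)
    g = res.gfp_ss[res.converged]
    expr = float(g[0]) if g.size else float("nan")
    warm = res.states[0] if res.converged[0] else None
    return res, expr, warm


def design_controller(model: CellModel,
                      bounds: dict,
                      weight: float = 0.0,
                      n_grid: int = 3,
                      omega_grid: Optional[Sequence[float]] = None,
                      expression_ref: Optional[float] = None,
                      induced: str = "RFP",
                      constitutive: str = "GFP") -> tuple:
    """Log-grid search for controller parameters.

    Minimises ``J = |slope_norm| + weight * shortfall`` where shortfall
    is the relative loss of resting constitutive expression against
    ``expression_ref`` (default: the uncontrolled circuit at the
    model's own pool size).  Returns ``(best_model, frontier)`` with
    the full evaluated frontier for inspection.
    """
    if model.controller is None:
        raise InvalidParameterError("model has no controller to design")
    for k in bounds:
        if k not in DESIGN_PARAMS:
            raise InvalidParameterError(f"unknown design parameter '{k}'")
        lo, hi = bounds[k]
        if not (0 < lo <= hi and np.isfinite(hi)):
            raise InvalidParameterError(f"bounds for '{k}' must be finite, positive")
    if omega_grid is None:
        omega_grid = np.logspace(0, 3, 6)
    if expression_ref is None:
        ol = open_loop_variant(model)
        _, expression_ref, _ = _evaluate_circuit(ol, omega_grid,
                                                 induced, constitutive)

    axes = {k: np.logspace(np.log10(lo), np.log10(hi), n_grid)
            for k, (lo, hi) in bounds.items()}
    keys = list(axes)
    rows = []
    best = None
    warm0 = None
    n_fail = 0
    for combo in itertools.product(*(axes[k] for k in keys)):
        cand = dict(zip(keys, combo))
        m = _apply_design(model, cand)
        try:
            res, expr, warm0 = _evaluate_circuit(m, omega_grid, induced,
                                                 constitutive, warm0)
        except Exception:  # pragma: no cover - solver failure on a candidate
            n_fail += 1
            continue
        if not np.isfinite(res.slope_norm) or not np.isfinite(expr):
            n_fail += 1
            continue
        shortfall = max(0.0, (expression_ref - expr) / expression_ref) \
            if expression_ref > 0 else 0.0
        J = abs(res.slope_norm) + weight * shortfall
        row = dict(cand)
        row.update({"slope_norm": res.slope_norm, "expression": expr,
                    "shortfall": shortfall, "J": J})
        rows.append(row)
        if best is None or J < best[0]:
            best = (J, m, cand)
    frontier = pd.DataFrame(rows)
    if best is None:
        raise InvalidParameterError("all design candidates failed to converge")
    return best[1], frontier


def sensitivity_sweep(model: CellModel, param: str,
                      values: Sequence[float],
                      omega_grid: Optional[Sequence[float]] = None,
                      induced: str = "RFP",
                      constitutive: str = "GFP") -> pd.DataFrame:
    """One-at-a-time sweep of a controller design parameter.

    Reports both the coupling (isocost slope) and the resting
    expression so the decoupling/expression trade-off is visible.
    """
    if param not in DESIGN_PARAMS:
        raise InvalidParameterError(f"unknown design parameter '{param}'")
    vals = [float(v) for v in values]
    if not vals or any(v <= 0 for v in vals):
        raise InvalidParameterError("values must be positive and non-empty")
    if omega_grid is None:
        omega_grid = np.logspace(0, 3, 6)
    rows = []
    warm0 = None
    for v in vals:
        m = _apply_design(model, {param: v})
        res, expr, warm0 = _evaluate_circuit(m, omega_grid, induced,
                                             constitutive, warm0)
        rows.append({param: v, "slope": res.slope,
                     "slope_norm": res.slope_norm, "expression": expr,
                     "n_converged": int(res.converged.sum())})
    return pd.DataFrame(rows)


def robustness_mc(model: CellModel,
                  n: int = 1000,
                  frac: float = 0.5,
                  seed: int = 0,
                  omega_grid: Optional[Sequence[float]] = None,
                  open_loop_slope: Optional[float] = None,
                  induced: str = "RFP",
                  constitutive: str = "GFP") -> tuple[pd.DataFrame, dict]:
    """Monte Carlo robustness of the closed loop to parameter mismatch.

    Every o-rRNA and controller-protein parameter is multiplied by an
    independent Uniform(1-frac, 1+frac) factor per draw; each draw's
    isocost slope and resting expression are recorded, together with
    the fraction of draws whose |slope| beats the matched open loop's.
    Deterministic given ``seed``; non-converged draws are excluded and
    counted.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if not 0 <= frac < 1:
        raise InvalidParameterError("frac must be in [0, 1)")
    if model.controller is None:
        raise InvalidParameterError("model has no controller")
    if omega_grid is None:
        omega_grid = np.logspace(0, 3, 6)
    if open_loop_slope is None:
        w_match = tune_open_loop_match(model, constitutive=constitutive)
        ol = open_loop_variant(model, omega_rho=w_match)
        ol_res, _, _ = _evaluate_circuit(ol, omega_grid, induced, constitutive)
        open_loop_slope = ol_res.slope_norm

    pid = model.controller.target_pool
    rng = np.random.default_rng(seed)
    names = list(PERTURBED_POOL) + list(PERTURBED_CTRL)
    rows = []
    warm0 = None
    for i in range(n):
        factors = rng.uniform(1.0 - frac, 1.0 + frac, size=len(names))
        m = model.clone()
        spec = m.pools[pid]
        for name, f in zip(PERTURBED_POOL, factors[:len(PERTURBED_POOL)]):
            setattr(spec, name, getattr(spec, name) * f)
        ctrl_kw = {}
        for name, f in zip(PERTURBED_CTRL, factors[len(PERTURBED_POOL):]):
            ctrl_kw[name] = getattr(m.controller, name) * f
        ctrl_kw["h"] = max(ctrl_kw["h"], 1.0)
        m.controller = replace(m.controller, **ctrl_kw)
        m.invalidate()
        row = {"draw": i}
        row.update({f"f_{nm}": f for nm, f in zip(names, factors)})
        try:
            res, expr, warm0 = _evaluate_circuit(m, omega_grid, induced,
                                                 constitutive, warm0)
            ok = np.isfinite(res.slope_norm) and res.converged.sum() >= 2
        except Exception:
            ok = False
            res, expr = None, float("nan")
        row["slope_norm"] = res.slope_norm if ok else float("nan")
        row["expression"] = expr
        row["converged"] = bool(ok)
        row["outperforms"] = bool(ok and abs(res.slope_norm)
                                  < abs(open_loop_slope))
        rows.append(row)
    df = pd.DataFrame(rows)
    n_ok = int(df["converged"].sum())
    summary = {
        "n": n,
        "n_excluded": n - n_ok,
        "seed": seed,
        "frac": frac,
        "open_loop_slope_norm": float(open_loop_slope),
        "fraction_outperforming": (float(df.loc[df["converged"],
                                                "outperforms"].mean())
                                   if n_ok else float("nan")),
    }
    return df, summary
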