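"""Growth-law data generation and model calibration.

The model's two canonical growth laws — growth rate and ribosomal
mass fraction rising together under nutrient upshift, and ribosomal
mass fraction rising while growth falls under translational inhibition
— make (lambda, Phi_R) measurements across conditions informative
about the translation parameters.  This module generates synthetic
growth-law datasets from the model itself (mirroring the structure of
classic nutrient x chloramphenicol growth-law experiments) and fits
chosen host parameters back by weighted least squares, so calibration
is validated by parameter recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import (
    CellModel,
    HostParameters,
    InvalidParameterError,
    solve_steady_state,
)

__all__ = ["GrowthLawDataset", "generate_growth_law_data", "fit_parameters",
           "FitResult"]

COLUMNS = ["condition", "n_s", "inhibitor", "lam_obs", "phi_R_obs", "sigma"]


@dataclass
class GrowthLawDataset:
    """(growth rate, ribosomal mass fraction) across culture conditions.

    ``n_s`` is the nutrient quality (energy per catabolised substrate)
    and ``inhibitor`` a multiplicative factor on the maximal elongation
    rate (1 = untreated), the coarse-grained analogue of a
    translation-inhibiting antibiotic.
    """

    data: pd.DataFrame
    seed: Optional[int] = None

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidParameterError(f"dataset missing columns {missing}")
        if (self.data["lam_obs"] < 0).any() or \
                (self.data["phi_R_obs"] < 0).any() or \
                (self.data["phi_R_obs"] > 1).any():
            raise InvalidParameterError("lam must be >= 0 and phi_R in [0,1]")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, seed: Optional[int] = None) -> "GrowthLawDataset":
        return cls(pd.read_csv(path), seed=seed)


def _condition_params(params: HostParameters, n_s: float,
                      inhibitor: float) -> HostParameters:
    return params.replace(n_s=float(n_s),
                          gamma_max=params.gamma_max * float(inhibitor))


def predict_growth_laws(params: HostParameters,
                        conditions: pd.DataFrame,
                        warm_states: Optional[dict] = None) -> pd.DataFrame:
    """Model (lambda, Phi_R) for each (n_s, inhibitor) condition row."""
    rows = []
    for _, cond in conditions.iterrows():
        p = _condition_params(params, cond["n_s"], cond["inhibitor"])
        m = CellModel(p)
        key = (cond["n_s"], cond["inhibitor"])
        warm = warm_states.get(key) if warm_states is not None else None
        ss = solve_steady_state(m, warm_start=warm)
        if warm_states is not None:
            warm_states[key] = ss.state
        rows.append({"n_s": cond["n_s"], "inhibitor": cond["inhibitor"],
                     "lam": ss.lam,
                     "phi_R": m.ribosome_mass_fraction(ss.state),
                     "converged": ss.converged})
    return pd.DataFrame(rows)


def generate_growth_law_data(params: Optional[HostParameters] = None,
                             nutrient_grid: Sequence[float] = (0.1, 0.2, 0.35, 0.5),
                             inhibitor_grid: Sequence[float] = (1.0, 0.7, 0.5),
                             sigma: float = 0.0,
                             seed: int = 0) -> GrowthLawDataset:
    """Simulate the growth-law experiment and add multiplicative noise.

    Each condition is the steady state at one (nutrient quality,
    elongation inhibition) pair; observations are the true model
    values times ``1 + sigma * N(0,1)``.  Non-converged conditions are
    flagged but retained.
    """
    if params is None:
        params = HostParameters()
    if sigma < 0:
        raise InvalidParameterError("sigma must be >= 0")
    nut = list(nutrient_grid)
    inh = list(inhibitor_grid)
    if not nut or not inh:
        raise InvalidParameterError("grids must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for ns in nut:
        for f in inh:
            p = _condition_params(params, ns, f)
            m = CellModel(p)
            ss = solve_steady_state(m)
            lam = ss.lam
            phi = m.ribosome_mass_fraction(ss.state)
            lam_obs = lam * (1.0 + sigma * rng.standard_normal())
            phi_obs = phi * (1.0 + sigma * rng.standard_normal())
            rows.append({"condition": f"ns={ns:g},inh={f:g}",
                         "n_s": ns, "inhibitor": f,
                         "lam_obs": max(lam_obs, 0.0),
                         "phi_R_obs": float(np.clip(phi_obs, 0.0, 1.0)),
                         "sigma": sigma,
                         "converged": ss.converged})
    return GrowthLawDataset(pd.DataFrame(rows), seed=seed)


@dataclass
class FitResult:
    estimates: dict
    loss: float
    residuals: pd.DataFrame
    success: bool
    message: str
    nfev: int


def fit_parameters(dataset: GrowthLawDataset,
                   free_params: Sequence[str],
                   bounds: Optional[dict] = None,
                   base_params: Optional[HostParameters] = None,
                   x0: Optional[dict] = None) -> FitResult:
    """Weighted least-squares fit of host parameters to growth-law data.

    Residuals are relative, weighting lambda and Phi_R equally by their
    dataset-mean scales.  Parameters are optimised in log space within
    ``bounds`` (default: a factor of 10 around the base value);
    deterministic given the starting point.
    """
    free = list(free_params)
    if not free:
        raise InvalidParameterError("free_params must be non-empty")
    base = base_params if base_params is not None else HostParameters()
    for name in free:
        if not hasattr(base, name):
            raise InvalidParameterError(f"unknown parameter '{name}'")
    bounds = bounds or {}
    lo, hi = [], []
    for name in free:
        default = getattr(base, name)
        blo, bhi = bounds.get(name, (default / 10.0, default * 10.0))
        if not (0 < blo <= default <= bhi):
            raise InvalidParameterError(
                f"bounds for '{name}' must bracket the base value")
        lo.append(np.log10(blo))
        hi.append(np.log10(bhi))
    start = np.array([np.log10(x0[name]) if x0 and name in x0
                      else np.log10(getattr(base, name)) for name in free])

    df = dataset.data
    conds = df[["n_s", "inhibitor"]]
    lam_scale = max(df["lam_obs"].mean(), 1e-12)
    phi_scale = max(df["phi_R_obs"].mean(), 1e-12)
    warm_states: dict = {}

    def residuals(logx: np.ndarray) -> np.ndarray:
        p = base.replace(**{name: 10.0 ** v for name, v in zip(free, logx)})
        pred = predict_growth_laws(p, conds, warm_states)
        return np.concatenate([
            (pred["lam"].to_numpy() - df["lam_obs"].to_numpy()) / lam_scale,
            (pred["phi_R"].to_numpy() - df["phi_R_obs"].to_numpy()) / phi_scale,
        ])

    try:
        sol = least_squares(residuals, start, bounds=(lo, hi),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
    except Exception as exc:  # pragma: no cover
        raise InvalidParameterError(f"optimiser failure: {exc}") from exc

    estimates = {name: float(10.0 ** v) for name, v in zip(free, sol.x)}
    r = sol.fun
    half = len(r) // 2
    resid = pd.DataFrame({
        "condition": df["condition"],
        "lam_resid": r[:half],
        "phi_R_resid": r[half:],
    })
    return FitResult(estimates=estimates, loss=float(0.5 * np.sum(r ** 2)),
                     residuals=resid, success=bool(sol.success),
                     message=str(sol.message), nfev=int(sol.nfev))
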