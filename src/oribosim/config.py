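"""Scenario configuration, orchestration and result serialisation.

A scenario is a YAML file declaring the host parameters, any
orthogonal pools, circuit genes, an optional pathway or controller,
and exactly one analysis to run.  Validation is strict: unknown keys
are rejected by name rather than silently ignored, so a misspelled
parameter cannot corrupt a study.  ``run_scenario`` writes CSV/JSON
outputs plus a manifest recording the config hash, seed, solver
tolerances, wall-clock time and a checksum for every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .model import (
    ATOL,
    RTOL,
    SS_TOL,
    T_MAX,
    CellModel,
    CircuitGene,
    ControllerParams,
    HostParameters,
    InvalidParameterError,
    OPoolSpec,
    PathwaySpec,
    simulate,
    solve_steady_state,
    state_frame,
)
from .coupling import (
    CONFIGURATIONS,
    configuration_comparison,
    isocost_sweep,
    two_pool_decoupling,
)
from .pathway import induction_dose_response, register_pathway
from .controller import design_controller, robustness_mc, sensitivity_sweep
from .calibration import fit_parameters, generate_growth_law_data

logger = logging.getLogger("oribosim")

ANALYSES = ("simulate", "isocost", "compare-configs", "two-pool", "vio",
            "controller-design", "sensitivity", "robustness", "calibrate")

STOCHASTIC_ANALYSES = ("robustness", "calibrate")


class ConfigError(InvalidParameterError):
    """Schema violation naming the offending key."""


def _check_keys(block: dict, allowed, where: str) -> None:
    for key in block:
        if key not in allowed:
            raise ConfigError(
                f"unknown key '{key}' in '{where}' "
                f"(expected one of: {', '.join(sorted(allowed))})")


def _build_dataclass(cls, block: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    _check_keys(block, names, where)
    try:
        return cls(**block)
    except TypeError as exc:
        raise ConfigError(f"invalid block '{where}': {exc}") from exc


def parse_grid(spec: Any, where: str) -> np.ndarray:
    """A grid is either an explicit list or {start, stop, num, spacing}."""
    if isinstance(spec, (list, tuple)):
        return np.asarray(spec, dtype=float)
    if isinstance(spec, dict):
        _check_keys(spec, {"start", "stop", "num", "spacing"}, where)
        for k in ("start", "stop", "num"):
            if k not in spec:
                raise ConfigError(f"grid '{where}' missing key '{k}'")
        spacing = spec.get("spacing", "log")
        if spacing == "log":
            return np.logspace(np.log10(spec["start"]),
                               np.log10(spec["stop"]), int(spec["num"]))
        if spacing == "linear":
            return np.linspace(spec["start"], spec["stop"], int(spec["num"]))
        raise ConfigError(f"grid '{where}': spacing must be 'log' or 'linear'")
    raise ConfigError(f"grid '{where}' must be a list or start/stop/num map")


_ANALYSIS_KEYS = {
    "simulate": {"kind", "t_max", "n_points"},
    "isocost": {"kind", "induced", "constitutive", "omega_grid"},
    "compare-configs": {"kind", "configs", "omega_grid", "omega_rho",
                        "omega_constitutive"},
    "two-pool": {"kind", "induced", "constitutive", "omega_grid",
                 "omega_rho_grid"},
    "vio": {"kind", "omega_BCDE_grid"},
    "controller-design": {"kind", "bounds", "weight", "n_grid", "omega_grid"},
    "sensitivity": {"kind", "param", "values", "omega_grid"},
    "robustness": {"kind", "n", "frac", "seed", "omega_grid"},
    "calibrate": {"kind", "free_params", "bounds", "nutrient_grid",
                  "inhibitor_grid", "sigma", "seed"},
}

_TOP_KEYS = {"host", "b_cross", "pools", "genes", "pathway", "vioA_pool",
             "controller", "analysis", "out_dir"}


@dataclass
class ScenarioConfig:
    """Fully validated scenario description."""

    host: HostParameters = field(default_factory=HostParameters)
    b_cross: float = 0.0
    pools: list = field(default_factory=list)
    genes: list = field(default_factory=list)
    pathway: Optional[PathwaySpec] = None
    vioA_pool: str = "host"
    controller: Optional[ControllerParams] = None
    analysis: dict = field(default_factory=lambda: {"kind": "simulate"})
    out_dir: str = "results"

    def __post_init__(self):
        kind = self.analysis.get("kind")
        if kind not in ANALYSES:
            raise ConfigError(
                f"analysis.kind '{kind}' not one of {ANALYSES}")
        _check_keys(self.analysis, _ANALYSIS_KEYS[kind], "analysis")
        if kind in STOCHASTIC_ANALYSES and "seed" not in self.analysis:
            raise ConfigError(f"analysis '{kind}' requires a seed")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate gene names")
        pool_ids = [p.pool_id for p in self.pools]
        if len(set(pool_ids)) != len(pool_ids):
            raise ConfigError("duplicate pool ids")
        for g in self.genes:
            if g.pool != "host" and g.pool not in pool_ids:
                raise ConfigError(
                    f"gene '{g.name}' references unknown pool '{g.pool}'")
        if self.controller is not None and \
                self.controller.target_pool not in pool_ids:
            raise ConfigError("controller references unknown pool "
                              f"'{self.controller.target_pool}'")

    # -- (de)serialisation --------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        _check_keys(raw, _TOP_KEYS, "scenario")
        host = _build_dataclass(HostParameters, raw.get("host", {}) or {},
                                "host")
        pools = [_build_dataclass(OPoolSpec, b, f"pools[{i}]")
                 for i, b in enumerate(raw.get("pools", []) or [])]
        genes = [_build_dataclass(CircuitGene, b, f"genes[{i}]")
                 for i, b in enumerate(raw.get("genes", []) or [])]
        pathway = None
        if raw.get("pathway") is not None:
            pw = dict(raw["pathway"])
            for key in ("kcat", "Km"):
                if key in pw:
                    pw[key] = tuple(pw[key])
            pathway = _build_dataclass(PathwaySpec, pw, "pathway")
        controller = None
        if raw.get("controller") is not None:
            controller = _build_dataclass(ControllerParams,
                                          raw["controller"], "controller")
        return cls(host=host, b_cross=float(raw.get("b_cross", 0.0)),
                   pools=pools, genes=genes, pathway=pathway,
                   vioA_pool=raw.get("vioA_pool", "host"),
                   controller=controller,
                   analysis=dict(raw.get("analysis",
                                         {"kind": "simulate"})),
                   out_dir=raw.get("out_dir", "results"))

    def to_dict(self) -> dict:
        out: dict = {
            "host": dataclasses.asdict(self.host),
            "b_cross": self.b_cross,
            "pools": [dataclasses.asdict(p) for p in self.pools],
            "genes": [dataclasses.asdict(g) for g in self.genes],
            "vioA_pool": self.vioA_pool,
            "analysis": dict(self.analysis),
            "out_dir": self.out_dir,
        }
        if self.pathway is not None:
            d = dataclasses.asdict(self.pathway)
            d["kcat"] = list(d["kcat"])
            d["Km"] = list(d["Km"])
            out["pathway"] = d
        if self.controller is not None:
            out["controller"] = dataclasses.asdict(self.controller)
        return out

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    def build_model(self) -> CellModel:
        m = CellModel(self.host, b_cross=self.b_cross)
        for p in self.pools:
            m.add_pool(dataclasses.replace(p))
        for g in self.genes:
            m.add_gene(dataclasses.replace(g))
        if self.pathway is not None:
            register_pathway(m, dataclasses.replace(self.pathway),
                             vioA_pool=self.vioA_pool)
        if self.controller is not None:
            m.set_controller(dataclasses.replace(self.controller))
        return m


def load_config(path) -> ScenarioConfig:
    """Parse and strictly validate a YAML scenario file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("scenario file must contain a mapping")
    return ScenarioConfig.from_dict(raw)


# ---------------------------------------------------------------------------
# Scenario dispatch
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def _run_analysis(config: ScenarioConfig, out: Path,
                  seed_override: Optional[int] = None) -> tuple[list, dict]:
    a = dict(config.analysis)
    kind = a.pop("kind")
    if seed_override is not None and kind in STOCHASTIC_ANALYSES:
        a["seed"] = seed_override
    files: list[Path] = []
    summary: dict = {"analysis": kind}
    model = config.build_model()

    if kind == "simulate":
        t_max = float(a.get("t_max", T_MAX))
        n_points = int(a.get("n_points", 200))
        if t_max <= 0:
            df = state_frame(model, model.initial_state(), t=[0.0])
        else:
            t_eval = np.linspace(0.0, t_max, n_points)
            sol = simulate(model, t_span=(0.0, t_max), t_eval=t_eval)
            df = state_frame(model, np.clip(sol.y.T, 0.0, None), t=sol.t)
        path = out / "trajectory.csv"
        _write_csv(df, path)
        files.append(path)
        ss = solve_steady_state(model)
        summary.update({"lam": ss.lam, "converged": bool(ss.converged),
                        "residual_norm": ss.residual_norm})

    elif kind == "isocost":
        res = isocost_sweep(model, a["induced"], a["constitutive"],
                            parse_grid(a["omega_grid"], "omega_grid"))
        path = out / "isocost.csv"
        _write_csv(res.to_frame(), path)
        files.append(path)
        summary.update(res.summary())

    elif kind == "compare-configs":
        df = configuration_comparison(
            CellModel(config.host),
            configs=a.get("configs", list(CONFIGURATIONS)),
            omega_grid=parse_grid(a.get("omega_grid",
                                        {"start": 1, "stop": 1000,
                                         "num": 10}), "omega_grid"),
            omega_rho=float(a.get("omega_rho", 500.0)),
            omega_constitutive=float(a.get("omega_constitutive", 100.0)))
        path = out / "configuration_slopes.csv"
        _write_csv(df, path)
        files.append(path)
        summary["slopes"] = dict(zip(df["config"], df["slope_norm"]))

    elif kind == "two-pool":
        res = two_pool_decoupling(
            model, a["induced"], a["constitutive"],
            parse_grid(a["omega_grid"], "omega_grid"),
            parse_grid(a["omega_rho_grid"], "omega_rho_grid"))
        path = out / "two_pool_grid.csv"
        _write_csv(res.table, path)
        files.append(path)
        path2 = out / "two_pool_best_sweep.csv"
        _write_csv(res.best_sweep.to_frame(), path2)
        files.append(path2)
        summary.update({
            "gfp_drop_pct": res.drop_pct,
            "omega_rho_constitutive": res.best_specs[0].omega_rho,
            "omega_rho_induced": res.best_specs[1].omega_rho})

    elif kind == "vio":
        df = induction_dose_response(
            model, parse_grid(a["omega_BCDE_grid"], "omega_BCDE_grid"))
        path = out / "vio_dose_response.csv"
        _write_csv(df, path)
        files.append(path)
        summary.update({"V_max": float(df["V"].max()),
                        "vioA_pool": config.vioA_pool})

    elif kind == "controller-design":
        bounds = {k: tuple(v) for k, v in a["bounds"].items()}
        best, frontier = design_controller(
            model, bounds, weight=float(a.get("weight", 0.0)),
            n_grid=int(a.get("n_grid", 3)),
            omega_grid=(parse_grid(a["omega_grid"], "omega_grid")
                        if "omega_grid" in a else None))
        path = out / "design_frontier.csv"
        _write_csv(frontier, path)
        files.append(path)
        pid = best.controller.target_pool
        summary.update({
            "best": {"omega_rho_max": best.pools[pid].omega_rho,
                     **{k: getattr(best.controller, k)
                        for k in ("omega_F", "b_F", "k_D", "h")}},
            "best_J": float(frontier["J"].min())})

    elif kind == "sensitivity":
        df = sensitivity_sweep(
            model, a["param"], [float(v) for v in a["values"]],
            omega_grid=(parse_grid(a["omega_grid"], "omega_grid")
                        if "omega_grid" in a else None))
        path = out / "sensitivity.csv"
        _write_csv(df, path)
        files.append(path)
        summary["param"] = a["param"]

    elif kind == "robustness":
        df, mc_summary = robustness_mc(
            model, n=int(a.get("n", 1000)), frac=float(a.get("frac", 0.5)),
            seed=int(a["seed"]),
            omega_grid=(parse_grid(a["omega_grid"], "omega_grid")
                        if "omega_grid" in a else None))
        path = out / "robustness_draws.csv"
        _write_csv(df, path)
        files.append(path)
        summary.update(mc_summary)

    elif kind == "calibrate":
        ds = generate_growth_law_data(
            config.host,
            nutrient_grid=[float(v) for v in a.get("nutrient_grid",
                                                   [0.1, 0.2, 0.35, 0.5])],
            inhibitor_grid=[float(v) for v in a.get("inhibitor_grid",
                                                    [1.0, 0.7, 0.5])],
            sigma=float(a.get("sigma", 0.0)), seed=int(a["seed"]))
        path = out / "growth_law_data.csv"
        ds.to_csv(path)
        files.append(path)
        bounds = {k: tuple(v) for k, v in (a.get("bounds") or {}).items()}
        fit = fit_parameters(ds, a["free_params"], bounds=bounds or None,
                             base_params=config.host)
        summary.update({"estimates": fit.estimates, "loss": fit.loss,
                        "success": fit.success})

    return files, summary


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_scenario(config: ScenarioConfig, out_dir=None,
                 seed: Optional[int] = None) -> dict:
    """Build the model, dispatch the configured analysis, write outputs.

    Returns the summary dict; on disk the output directory gains the
    analysis CSVs, a ``summary.json`` and a ``manifest.json`` with
    checksums of every file produced.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    files, summary = _run_analysis(config, out, seed_override=seed)
    wall = time.perf_counter() - t0

    spath = out / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, default=float))
    files.append(spath)

    from . import __version__
    config_text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "version": __version__,
        "analysis": config.analysis.get("kind"),
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": seed if seed is not None else config.analysis.get("seed"),
        "solver": {"rtol": RTOL, "atol": ATOL, "t_max": T_MAX,
                   "ss_tol": SS_TOL},
        "wall_clock_s": wall,
        "outputs": {p.name: _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("scenario '%s' finished in %.1fs -> %s",
                config.analysis.get("kind"), wall, out)
    return summary
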