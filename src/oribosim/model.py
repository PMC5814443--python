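"""Coarse-grained host-aware model of bacterial gene expression.

The cell is described by a deterministic ODE system capturing three
trade-offs of microbial physiology: finite anabolic capacity ("energy"
produced by substrate import and catabolism), finite translational
capacity (a shared ribosome pool), and a finite proteome (all species
are diluted by growth at rate ``lambda = gamma(e) * sum(c) / M``).

Four host gene classes are modelled: transporters (T), catabolic
enzymes (E), housekeeping proteins (H, autoinhibited) and ribosomes.
Ribosome biosynthesis is resolved into a protein component p_R (the
"empty ribosome", translated from m_R) and an rRNA component r; the
two associate reversibly into functional host ribosomes R.

Orthogonal ribosome pools are built from a synthetic 16S rRNA (rho)
that competes with the host rRNA for the shared p_R, yielding
circuit-only ribosomes P.  Heterologous circuit genes, metabolic
pathways and a negative-feedback o-rRNA controller plug into the same
state vector; the index map built by :class:`CellModel` is the single
source of truth for the species layout.

Units: time in minutes, amounts in molecules per cell, lengths in
amino acids.  Default parameter values follow the fitted coarse-grained
growth model of Weisse et al. (2015).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

logger = logging.getLogger("oribosim")

# Solver configuration (shared by every module).
RTOL = 1e-9          # relative tolerance for stiff integration
ATOL = 1e-12         # absolute tolerance for stiff integration
T_MAX = 1e5          # default integration horizon to steady state (min)
SS_TOL = 1e-6        # scaled residual tolerance declaring steady state
NEG_SLACK = -1e-9    # tolerated solver undershoot below zero


class OribosimError(Exception):
    """Base class for model errors."""


class InvalidParameterError(OribosimError, ValueError):
    """A kinetic parameter violates its domain."""


class NumericalStateError(OribosimError, FloatingPointError):
    """The state vector contains NaN/Inf; carries the offending index."""

    def __init__(self, index: int, name: str):
        self.index = index
        self.species = name
        super().__init__(f"non-finite value in species '{name}' (index {index})")


class RegistrationError(OribosimError, ValueError):
    """Duplicate/unknown species, pool or gene during model building."""


class SolverError(OribosimError, RuntimeError):
    """Integration failed; ``last_state`` holds the last valid state."""

    def __init__(self, message: str, last_state: Optional[np.ndarray] = None):
        self.last_state = last_state
        super().__init__(message)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HostParameters:
    """Kinetic constants of the base cell model.

    Rates are per minute, amounts molecules per cell, lengths amino
    acids.  ``M`` is the (protein) cell mass in amino acids.
    """

    s_ext: float = 1e4        # external substrate (held constant)
    v_T: float = 726.0        # import Vmax
    K_T: float = 1000.0       # import Michaelis constant
    v_E: float = 5800.0       # catabolism Vmax
    K_E: float = 1000.0       # catabolism Michaelis constant
    n_s: float = 0.5          # energy units per catabolised substrate

    # maximal transcription rates (transcripts per min)
    omega_T: float = 4.14
    omega_E: float = 4.14
    omega_H: float = 948.93
    omega_R: float = 930.0    # ribosomal protein mRNA
    omega_r: float = 930.0    # ribosomal RNA

    # transcriptional energy thresholds
    o_T: float = 4.38
    o_E: float = 4.38
    o_H: float = 4.38
    o_R: float = 426.87
    o_r: float = 426.87

    K_H: float = 152219.0     # housekeeping autoinhibition threshold
    h_H: float = 4.0          # housekeeping Hill coefficient

    # ribosome-mRNA association/dissociation (per molecule per min / per min)
    b_T: float = 1.0
    b_E: float = 1.0
    b_H: float = 1.0
    b_R: float = 1.0
    u_T: float = 1.0
    u_E: float = 1.0
    u_H: float = 1.0
    u_R: float = 1.0

    # protein lengths (amino acids)
    n_T: float = 300.0
    n_E: float = 300.0
    n_H: float = 300.0
    n_R: float = 7549.0

    gamma_max: float = 1260.0  # maximal elongation rate (aa/min/ribosome)
    K_gamma: float = 7.0       # translational energy threshold
    M: float = 1e8             # total protein mass (aa)

    b_r: float = 1.0           # p_R + r association
    u_r: float = 1.0           # R dissociation

    delta_m: float = 0.1       # host mRNA degradation
    delta_r: float = 0.1       # host rRNA degradation
    delta_R: float = 0.0       # functional ribosome degradation
    delta_pR: float = 0.0      # empty-ribosome protein degradation

    def __post_init__(self):
        positive = [
            "v_T", "K_T", "v_E", "K_E", "n_s", "K_H",
            "n_T", "n_E", "n_H", "n_R", "gamma_max", "K_gamma", "M",
            "o_T", "o_E", "o_H", "o_R", "o_r",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        nonneg = [
            "s_ext", "omega_T", "omega_E", "omega_H", "omega_R", "omega_r",
            "b_T", "b_E", "b_H", "b_R", "u_T", "u_E", "u_H", "u_R",
            "b_r", "u_r", "delta_m", "delta_r", "delta_R", "delta_pR",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.h_H < 1:
            raise InvalidParameterError("h_H must be >= 1")

    def replace(self, **kwargs) -> "HostParameters":
        return replace(self, **kwargs)


@dataclass
class OPoolSpec:
    """One quasi-orthogonal ribosome pool (synthetic 16S rRNA rho -> P)."""

    pool_id: str
    omega_rho: float = 500.0   # maximal o-rRNA transcription rate
    o_rho: float = 4.38        # transcriptional energy threshold
    b_rho: float = 1.0         # association with p_R
    u_rho: float = 1.0         # P dissociation
    delta_rho: float = 0.1     # o-rRNA degradation
    repressible: bool = False  # controller Hill factor gates omega_rho

    def __post_init__(self):
        if self.o_rho <= 0:
            raise InvalidParameterError("o_rho must be > 0")
        for name in ("omega_rho", "b_rho", "u_rho", "delta_rho"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


@dataclass
class CircuitGene:
    """A heterologous gene translated by one ribosome pool.

    ``omega`` is the transcription rate and doubles as the induction
    input for dose sweeps; ``pool`` is a registered pool_id or
    ``"host"``.
    """

    name: str
    omega: float
    o: float = 4.38
    n: float = 300.0
    pool: str = "host"
    b: float = 1.0
    u: float = 1.0
    delta_m: float = 0.1

    def __post_init__(self):
        if self.n <= 0 or self.o <= 0:
            raise InvalidParameterError("n and o must be > 0")
        for name in ("omega", "b", "u", "delta_m"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


@dataclass
class PathwaySpec:
    """Five-enzyme chain converting a constant substrate to a product.

    Enzyme A is its own transcription unit (``omega_A``); enzymes B-E
    form a polycistronic cassette sharing one transcription rate and
    one RBS strength, differing only in length (B defaults to 3x).
    """

    substrate_level: float = 1e5
    omega_A: float = 25.0
    omega_BCDE: float = 10.0
    kcat: Sequence[float] = (10.0, 10.0, 10.0, 10.0, 10.0)
    Km: Sequence[float] = (1000.0,) * 5
    n_A: float = 300.0
    n_B: float = 900.0
    n_C: float = 300.0
    n_D: float = 300.0
    n_E: float = 300.0
    b: float = 1.0
    u: float = 1.0
    o: float = 4.38
    delta_m: float = 0.1

    def __post_init__(self):
        if len(self.kcat) != 5 or len(self.Km) != 5:
            raise InvalidParameterError("kcat and Km must have 5 entries")
        if self.substrate_level < 0:
            raise InvalidParameterError("substrate_level must be >= 0")

    @property
    def lengths(self) -> tuple:
        return (self.n_A, self.n_B, self.n_C, self.n_D, self.n_E)


@dataclass
class ControllerParams:
    """Negative-feedback resource allocation controller.

    A constitutively transcribed repressor (F) is translated by the
    orthogonal pool it controls; its protein gates that pool's o-rRNA
    transcription by the Hill factor ``1/(1+(p_F/k_D)^h)``.
    """

    target_pool: str
    omega_F: float = 100.0
    o_F: float = 4.38
    n_F: float = 300.0
    b_F: float = 1.0
    u_F: float = 1.0
    delta_mF: float = 0.1
    k_D: float = 500.0
    h: float = 2.0

    def __post_init__(self):
        if self.k_D <= 0:
            raise InvalidParameterError("k_D must be > 0")
        if self.h < 1:
            raise InvalidParameterError("h must be >= 1")


@dataclass
class SteadyState:
    """Converged (or best-effort) fixed point of the cell model."""

    state: np.ndarray
    lam: float
    residual_norm: float
    converged: bool

    def __getitem__(self, idx):
        return self.state[idx]


# ---------------------------------------------------------------------------
# Elementary rate laws
# ---------------------------------------------------------------------------

def transcription_rate(omega: float, e: float, o: float,
                       autoinhibition: float = 1.0) -> float:
    """Energy-dependent transcription, ``omega * e/(o+e) * autoinhibition``."""
    if o <= 0:
        raise InvalidParameterError("transcription threshold o must be > 0")
    if e < 0:
        raise InvalidParameterError("energy e must be >= 0")
    if omega < 0:
        raise InvalidParameterError("omega must be >= 0")
    return omega * e / (o + e) * autoinhibition


def elongation_rate(e: float, gamma_max: float, K_gamma: float) -> float:
    """Energy-dependent elongation speed gamma(e) in aa/min per ribosome."""
    return gamma_max * e / (K_gamma + e)


def translation_rate(c: float, e: float, n: float,
                     gamma_max: float, K_gamma: float) -> float:
    """Protein completion rate ``c * gamma(e) / n`` (proteins per min)."""
    if n <= 0:
        raise InvalidParameterError("protein length n must be > 0")
    return c * elongation_rate(e, gamma_max, K_gamma) / n


def repression_factor(p_F: float, k_D: float, h: float) -> float:
    """Hill repression ``1/(1+(p_F/k_D)^h)``, monotone decreasing in p_F."""
    if k_D <= 0:
        raise InvalidParameterError("k_D must be > 0")
    pf = max(p_F, 0.0)
    return 1.0 / (1.0 + (pf / k_D) ** h)


# ---------------------------------------------------------------------------
# Model builder
# ---------------------------------------------------------------------------

# fixed core layout
_CORE = ["s_i", "e",
         "m_T", "c_T", "p_T",
         "m_E", "c_E", "p_E",
         "m_H", "c_H", "p_H",
         "m_R", "c_R", "p_R",
         "r", "R"]
I_SI, I_E = 0, 1
I_PT = 4
I_PE = 7
I_PH = 10
I_PR = 13
I_RRNA = 14
I_R = 15


class _Compiled:
    """Flattened arrays driving the vectorised RHS."""
    __slots__ = ("names", "index", "n_species",
                 "im", "ic", "ip", "omega", "o", "b", "u", "n", "dm",
                 "irib", "h_unit",
                 "pool_idx", "pool_rho", "pool_specs",
                 "ctrl", "ctrl_pool_row", "i_pF",
                 "path", "path_ip", "path_ii", "path_iv")


class CellModel:
    """Builder and evaluator for the full cell ODE system.

    Mutating registration methods invalidate the compiled index map;
    it is rebuilt lazily on first use, after which the species layout
    is fixed.
    """

    def __init__(self, params: Optional[HostParameters] = None,
                 b_cross: float = 0.0):
        self.params = params if params is not None else HostParameters()
        self.pools: dict[str, OPoolSpec] = {}
        self.genes: dict[str, CircuitGene] = {}
        self.pathway: Optional[PathwaySpec] = None
        self.pathway_enzymes: list[str] = []
        self.controller: Optional[ControllerParams] = None
        self.b_cross = float(b_cross)
        self._c: Optional[_Compiled] = None

    # -- construction -----------------------------------------------------

    def clone(self) -> "CellModel":
        m = copy.deepcopy(self)
        m._c = None
        return m

    def invalidate(self) -> None:
        self._c = None

    def add_pool(self, spec: OPoolSpec) -> "CellModel":
        if spec.pool_id in self.pools or spec.pool_id == "host":
            raise RegistrationError(f"duplicate pool_id '{spec.pool_id}'")
        self.pools[spec.pool_id] = spec
        self.invalidate()
        return self

    def add_gene(self, gene: CircuitGene) -> "CellModel":
        if gene.name in self.genes:
            raise RegistrationError(f"duplicate gene '{gene.name}'")
        if gene.pool != "host" and gene.pool not in self.pools:
            raise RegistrationError(
                f"gene '{gene.name}' allocated to unknown pool '{gene.pool}'")
        self.genes[gene.name] = gene
        self.invalidate()
        return self

    def set_controller(self, ctrl: ControllerParams) -> "CellModel":
        if ctrl.target_pool not in self.pools:
            raise RegistrationError(
                f"controller targets unknown pool '{ctrl.target_pool}'")
        if not self.pools[ctrl.target_pool].repressible:
            raise RegistrationError(
                f"pool '{ctrl.target_pool}' is not marked repressible")
        self.controller = ctrl
        self.invalidate()
        return self

    # -- compilation -------------------------------------------------------

    def _compile(self) -> _Compiled:
        if self._c is not None:
            return self._c
        p = self.params
        names = list(_CORE)
        pool_ids = list(self.pools)
        pool_idx = {}
        for pid in pool_ids:
            pool_idx[pid] = len(names)     # rho index; P is +1
            names += [f"rho_{pid}", f"P_{pid}"]

        # translation units: host classes first, then circuit genes,
        # then controller repressor, then optional cross-binding units
        units = []  # (im, ic, ip, omega, o, b, u, n, dm, irib, is_H)

        def rib_index(pool: str) -> int:
            return I_R if pool == "host" else pool_idx[pool] + 1

        units.append((2, 3, 4, p.omega_T, p.o_T, p.b_T, p.u_T, p.n_T,
                      p.delta_m, I_R, False))
        units.append((5, 6, 7, p.omega_E, p.o_E, p.b_E, p.u_E, p.n_E,
                      p.delta_m, I_R, False))
        units.append((8, 9, 10, p.omega_H, p.o_H, p.b_H, p.u_H, p.n_H,
                      p.delta_m, I_R, True))
        units.append((11, 12, 13, p.omega_R, p.o_R, p.b_R, p.u_R, p.n_R,
                      p.delta_m, I_R, False))

        gene_rows = {}
        for g in self.genes.values():
            im = len(names)
            names += [f"m_{g.name}", f"c_{g.name}", f"p_{g.name}"]
            gene_rows[g.name] = len(units)
            units.append((im, im + 1, im + 2, g.omega, g.o, g.b, g.u, g.n,
                          g.delta_m, rib_index(g.pool), False))

        i_pF = -1
        if self.controller is not None:
            f = self.controller
            im = len(names)
            names += ["m_F", "c_F", "p_F"]
            i_pF = im + 2
            units.append((im, im + 1, i_pF, f.omega_F, f.o_F, f.b_F, f.u_F,
                          f.n_F, f.delta_mF, rib_index(f.target_pool), False))

        if self.b_cross > 0:
            # o-ribosomes weakly translating host-RBS circuit mRNAs
            for g in self.genes.values():
                if g.pool != "host":
                    continue
                row = units[gene_rows[g.name]]
                for pid in pool_ids:
                    ic = len(names)
                    names.append(f"cx_{g.name}_{pid}")
                    units.append((row[0], ic, row[2], 0.0, g.o, self.b_cross,
                                  g.u, g.n, 0.0, pool_idx[pid] + 1, False))

        path_ip = path_ii = None
        path_iv = -1
        if self.pathway is not None:
            path_ip = np.array(
                [units[gene_rows[nm]][2] for nm in self.pathway_enzymes],
                dtype=int)
            first = len(names)
            names += ["I1", "I2", "I3", "I4", "V"]
            path_ii = np.arange(first, first + 4)
            path_iv = first + 4

        c = _Compiled()
        c.names = names
        c.index = {nm: i for i, nm in enumerate(names)}
        c.n_species = len(names)
        arr = np.array([u[:9] for u in units], dtype=float)
        c.im = np.array([u[0] for u in units], dtype=int)
        c.ic = np.array([u[1] for u in units], dtype=int)
        c.ip = np.array([u[2] for u in units], dtype=int)
        c.omega = arr[:, 3]
        c.o = arr[:, 4]
        c.b = arr[:, 5]
        c.u = arr[:, 6]
        c.n = arr[:, 7]
        c.dm = arr[:, 8]
        c.irib = np.array([u[9] for u in units], dtype=int)
        c.h_unit = np.array([u[10] for u in units], dtype=bool)
        c.pool_idx = pool_idx
        c.pool_rho = [pool_idx[pid] for pid in pool_ids]
        c.pool_specs = [self.pools[pid] for pid in pool_ids]
        c.ctrl = self.controller
        c.ctrl_pool_row = (pool_ids.index(self.controller.target_pool)
                           if self.controller is not None else -1)
        c.i_pF = i_pF
        c.path = self.pathway
        c.path_ip = path_ip
        c.path_ii = path_ii
        c.path_iv = path_iv
        self._c = c
        return c

    # -- public views ------------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return list(self._compile().names)

    @property
    def index(self) -> dict[str, int]:
        return dict(self._compile().index)

    @property
    def n_species(self) -> int:
        return self._compile().n_species

    def translation_units(self) -> list[tuple[str, str]]:
        """(mRNA species, free-ribosome species) per binding reaction."""
        c = self._compile()
        return [(c.names[im], c.names[ir]) for im, ir in zip(c.im, c.irib)]

    def initial_state(self) -> np.ndarray:
        """Small seed inoculum: energy plus a few ribosomes/enzymes."""
        y = np.zeros(self.n_species)
        ix = self._compile().index
        y[I_E] = 1000.0
        y[I_R] = 10.0
        y[ix["p_T"]] = 10.0
        y[ix["p_E"]] = 10.0
        y[I_PR] = 10.0
        y[I_RRNA] = 10.0
        return y

    # -- dynamics ----------------------------------------------------------

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Right-hand side dy/dt of the full model."""
        c = self._compile()
        if not np.all(np.isfinite(y)):
            bad = int(np.flatnonzero(~np.isfinite(y))[0])
            raise NumericalStateError(bad, c.names[bad])
        p = self.params
        s_i = y[I_SI]
        e = y[I_E]

        gam = p.gamma_max * e / (p.K_gamma + e)
        m = y[c.im]
        cx = y[c.ic]
        rib = y[c.irib]
        csum = cx.sum()
        lam = gam * csum / p.M

        tx = c.omega * e / (c.o + e)
        # housekeeping negative autoregulation
        pH = max(y[I_PH], 0.0)
        inh = 1.0 / (1.0 + (pH / p.K_H) ** p.h_H)
        tx = np.where(c.h_unit, tx * inh, tx)

        TL = gam * cx / c.n
        bind = c.b * rib * m
        unbind = c.u * cx

        dy = np.zeros_like(y)
        np.add.at(dy, c.im, tx - c.dm * m - bind + unbind + TL)
        np.add.at(dy, c.ic, bind - unbind - TL)
        np.add.at(dy, c.ip, TL)
        np.add.at(dy, c.irib, TL + unbind - bind)

        # metabolism
        v_imp = y[I_PT] * p.v_T * p.s_ext / (p.K_T + p.s_ext)
        v_cat = y[I_PE] * p.v_E * s_i / (p.K_E + s_i)
        dy[I_SI] += v_imp - v_cat
        dy[I_E] += p.n_s * v_cat - gam * csum

        # host ribosome assembly p_R + r <-> R
        pR = y[I_PR]
        r = y[I_RRNA]
        R = y[I_R]
        asm = p.b_r * pR * r - p.u_r * R
        dy[I_RRNA] += p.omega_r * e / (p.o_r + e) - p.delta_r * r - asm
        dy[I_R] += asm - p.delta_R * R
        dy[I_PR] += -p.delta_pR * pR - asm

        # orthogonal pools: p_R + rho <-> P
        for k, spec in enumerate(c.pool_specs):
            irho = c.pool_rho[k]
            rho = y[irho]
            P = y[irho + 1]
            rep = 1.0
            if (c.ctrl is not None and c.ctrl_pool_row == k
                    and spec.repressible):
                pf = max(y[c.i_pF], 0.0)
                rep = 1.0 / (1.0 + (pf / c.ctrl.k_D) ** c.ctrl.h)
            pasm = spec.b_rho * pR * rho - spec.u_rho * P
            dy[irho] += (spec.omega_rho * e / (spec.o_rho + e) * rep
                         - spec.delta_rho * rho - pasm)
            dy[irho + 1] += pasm - p.delta_R * P
            dy[I_PR] += -pasm

        # metabolic pathway chain
        if c.path is not None:
            pw = c.path
            enz = y[c.path_ip]
            S = np.empty(5)
            S[0] = pw.substrate_level
            S[1:] = y[c.path_ii]
            v = np.asarray(pw.kcat) * enz * S / (np.asarray(pw.Km) + S)
            dy[c.path_ii] += v[:4] - v[1:]
            dy[c.path_iv] += v[4]

        # dilution of every species by growth
        dy -= lam * y
        return dy

    def growth_rate(self, state: np.ndarray) -> float:
        """lambda = gamma(e)/M * sum of all translating complexes."""
        c = self._compile()
        p = self.params
        gam = p.gamma_max * state[I_E] / (p.K_gamma + state[I_E])
        return max(gam * state[c.ic].sum() / p.M, 0.0)

    def ribosome_mass_fraction(self, state: np.ndarray) -> float:
        """Protein-mass fraction locked in ribosomal species.

        Counts free host ribosomes, empty-ribosome protein, every
        mRNA-bound complex and every o-pool ribosome, each weighted by
        the ribosome length; rRNA carries no protein mass.
        """
        c = self._compile()
        p = self.params
        total = state[I_R] + state[I_PR] + state[c.ic].sum()
        for irho in c.pool_idx.values():
            total += state[irho + 1]
        return float(np.clip(p.n_R * total / p.M, 0.0, 1.0))


def growth_rate(state: np.ndarray, model: CellModel) -> float:
    return model.growth_rate(state)


def ribosome_mass_fraction(state: np.ndarray, model: CellModel) -> float:
    return model.ribosome_mass_fraction(state)


# ---------------------------------------------------------------------------
# Steady-state solving
# ---------------------------------------------------------------------------

def _scaled_residual(model: CellModel, y: np.ndarray) -> float:
    r = model.rhs(0.0, y)
    return float(np.max(np.abs(r) / np.maximum(1.0, np.abs(y))))


def _try_newton(model: CellModel, y: np.ndarray) -> Optional[np.ndarray]:
    """One Newton (Powell hybrid) refinement pass; None if it degrades."""
    try:
        sol = root(lambda x: model.rhs(0.0, x), y, method="hybr",
                   options={"xtol": 1e-13})
    except NumericalStateError:
        return None
    x = sol.x
    if not np.all(np.isfinite(x)) or x.min() < NEG_SLACK * max(1.0, np.abs(x).max()):
        return None
    if _scaled_residual(model, x) <= _scaled_residual(model, y):
        return x
    return None


def simulate(model: CellModel, y0: Optional[np.ndarray] = None,
             t_span: tuple = (0.0, T_MAX),
             t_eval: Optional[np.ndarray] = None,
             rtol: float = RTOL, atol: float = ATOL):
    """Stiff (BDF) integration of the model; returns the solve_ivp result."""
    if y0 is None:
        y0 = model.initial_state()
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (model.n_species,):
        raise InvalidParameterError(
            f"state length {y0.shape} != {model.n_species}")
    sol = solve_ivp(model.rhs, t_span, y0, method="BDF",
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise SolverError(f"integration failed: {sol.message}",
                          last_state=sol.y[:, -1] if sol.y.size else y0)
    return sol


def solve_steady_state(model: CellModel,
                       initial: Optional[np.ndarray] = None,
                       t_max: float = T_MAX,
                       tol: float = SS_TOL,
                       warm_start: Optional[np.ndarray] = None) -> SteadyState:
    """Find a non-negative fixed point of the model.

    A warm start, when supplied, is refined directly by root finding;
    otherwise the model is integrated with a stiff method to ``t_max``
    and the endpoint polished by one Newton pass.  ``converged`` is
    reported instead of raising when the residual tolerance is unmet.
    """
    if t_max <= 0:
        raise InvalidParameterError("t_max must be > 0")
    if warm_start is not None:
        w = np.asarray(warm_start, dtype=float)
        best, bres = w, _scaled_residual(model, w)
        x = _try_newton(model, w)
        if x is not None and _scaled_residual(model, x) < bres:
            best, bres = x, _scaled_residual(model, x)
        if bres <= tol and best.min() >= NEG_SLACK * max(1.0, np.abs(best).max()):
            y = np.clip(best, 0.0, None)
            return SteadyState(y, model.growth_rate(y),
                               _scaled_residual(model, y), True)
        logger.debug("warm start rejected; falling back to integration")

    y0 = model.initial_state() if initial is None else np.asarray(initial, float)
    if np.any(y0 < 0):
        raise InvalidParameterError("initial state must be non-negative")
    sol = simulate(model, y0, (0.0, t_max))
    y = sol.y[:, -1]
    x = _try_newton(model, y)
    if x is not None:
        y = x
    res = _scaled_residual(model, y)
    y = np.clip(y, 0.0, None)
    return SteadyState(y, model.growth_rate(y), res, res <= tol)


# ---------------------------------------------------------------------------
# Serialisation helpers
# ---------------------------------------------------------------------------

def state_frame(model: CellModel, states, t=None) -> pd.DataFrame:
    """Tabulate state vector(s) with species symbols as column names."""
    arr = np.atleast_2d(np.asarray(states, dtype=float))
    df = pd.DataFrame(arr, columns=model.species_names)
    if t is not None:
        df.insert(0, "t", np.asarray(t))
    return df


def write_state_csv(path, model: CellModel, states, t=None) -> None:
    state_frame(model, states, t).to_csv(path, index=False)
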