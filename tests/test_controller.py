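"""Feedback controller: repression law, reduction, matching, design, MC."""

import numpy as np
import pandas as pd
import pytest

from oribosim.model import (
    CellModel,
    ControllerParams,
    InvalidParameterError,
    OPoolSpec,
    RegistrationError,
    repression_factor,
    solve_steady_state,
)
from oribosim.controller import (
    build_controlled_reporter_model,
    closed_loop_step_response,
    design_controller,
    open_loop_variant,
    robustness_mc,
    sensitivity_sweep,
    tune_open_loop_match,
    _evaluate_circuit,
)

GRID = np.logspace(0, 3, 5)


@pytest.fixture(scope="module")
def cl_model():
    return build_controlled_reporter_model(
        omega_rho=1000.0,
        ctrl=ControllerParams(target_pool="o1", omega_F=100.0,
                              k_D=500.0, h=2.0))


class TestRepressionFactor:
    def test_no_repressor_no_repression(self):
        assert repression_factor(0.0, 10.0, 2.0) == 1.0

    def test_half_repression_at_kD(self):
        assert repression_factor(10.0, 10.0, 2.0) == pytest.approx(0.5)

    def test_steep_hill_approaches_step(self):
        assert repression_factor(20.0, 10.0, 50.0) < 1e-10

    def test_monotone_decreasing(self):
        vals = [repression_factor(p, 10.0, 2.0) for p in (0, 5, 10, 50, 500)]
        assert np.all(np.diff(vals) < 0)

    def test_invalid_kD_rejected(self):
        with pytest.raises(InvalidParameterError):
            repression_factor(1.0, 0.0, 2.0)


class TestRegistration:
    def test_requires_repressible_pool(self):
        m = CellModel()
        m.add_pool(OPoolSpec("o1", repressible=False))
        with pytest.raises(RegistrationError):
            m.set_controller(ControllerParams(target_pool="o1"))

    def test_unknown_pool_rejected(self):
        m = CellModel()
        with pytest.raises(RegistrationError):
            m.set_controller(ControllerParams(target_pool="ghost"))


class TestReduction:
    """omega_F=0 closed loop must reproduce the open loop exactly."""

    def test_rhs_identity_on_embedded_states(self, cl_model):
        cl0 = cl_model.clone()
        cl0.controller = ControllerParams(target_pool="o1", omega_F=0.0,
                                          k_D=500.0, h=2.0)
        cl0.invalidate()
        ol = open_loop_variant(cl_model)
        n = ol.n_species
        rng = np.random.default_rng(7)
        for _ in range(10):
            y = rng.uniform(0.0, 1e4, n)
            ye = np.concatenate([y, [0.0, 0.0, 0.0]])  # m_F, c_F, p_F
            d = cl0.rhs(0.0, ye)
            assert np.array_equal(d[:n], ol.rhs(0.0, y))
            assert np.all(d[n:] == 0.0)

    def test_steady_states_identical(self, cl_model):
        cl0 = cl_model.clone()
        cl0.controller = ControllerParams(target_pool="o1", omega_F=0.0,
                                          k_D=500.0, h=2.0)
        cl0.invalidate()
        ol = open_loop_variant(cl_model)
        ss_cl = solve_steady_state(cl0)
        ss_ol = solve_steady_state(ol)
        n = ol.n_species
        rel = np.max(np.abs(ss_cl.state[:n] - ss_ol.state)
                     / np.maximum(np.abs(ss_ol.state), 1e-30))
        assert rel <= 1e-10


class TestStepResponse:
    def test_zero_step_stays_at_steady_state(self, cl_model):
        traj = closed_loop_step_response(cl_model, ("RFP", 1.0, 1.0, 100.0),
                                         horizon=500.0, n_points=60)
        gfp = traj["p_GFP"].to_numpy()
        assert np.ptp(gfp) <= 1e-4 * gfp.mean()

    def test_induction_relieves_repression(self, cl_model):
        traj = closed_loop_step_response(cl_model, ("RFP", 1.0, 500.0, 200.0),
                                         horizon=3000.0, n_points=150)
        pre = traj[traj["t"] < 200.0]["repression_factor"].iloc[-1]
        post = traj["repression_factor"].iloc[-1]
        assert post > pre
        # repressor translation flux falls: fewer controller complexes
        c_pre = traj[traj["t"] < 200.0]["c_F"].iloc[-1]
        c_post = traj["c_F"].iloc[-1]
        assert c_post < c_pre

    def test_step_must_lie_in_horizon(self, cl_model):
        with pytest.raises(InvalidParameterError):
            closed_loop_step_response(cl_model, ("RFP", 1.0, 2.0, 900.0),
                                      horizon=500.0)


class TestOpenLoopMatch:
    def test_matched_expression_within_tolerance(self, cl_model):
        w = tune_open_loop_match(cl_model)
        ol = open_loop_variant(cl_model, omega_rho=w)
        gfp_cl = solve_steady_state(cl_model).state[cl_model.index["p_GFP"]]
        gfp_ol = solve_steady_state(ol).state[ol.index["p_GFP"]]
        assert gfp_ol == pytest.approx(gfp_cl, rel=1e-3)

    def test_inactive_controller_returns_own_omega_rho(self):
        # omega_F=0: no repressor is ever made, so the closed loop IS the
        # open loop and matching must return the pool's own o-rRNA rate
        m = build_controlled_reporter_model(
            omega_rho=300.0,
            ctrl=ControllerParams(target_pool="o1", omega_F=0.0,
                                  k_D=500.0, h=2.0))
        w = tune_open_loop_match(m)
        assert w == pytest.approx(300.0, rel=0.05)

    def test_matched_open_loop_drops_more_upon_induction(self, cl_model):
        w = tune_open_loop_match(cl_model)
        ol = open_loop_variant(cl_model, omega_rho=w)
        drops = {}
        for name, mdl in (("cl", cl_model), ("ol", ol)):
            vals = []
            for omega in (1.0, 1000.0):
                m2 = mdl.clone()
                m2.genes["RFP"].omega = omega
                m2.invalidate()
                vals.append(solve_steady_state(m2).state[m2.index["p_GFP"]])
            drops[name] = (vals[0] - vals[1]) / vals[0]
        assert drops["cl"] < drops["ol"]


class TestDesign:
    def test_single_candidate_grid_returns_it(self, cl_model):
        bounds = {"k_D": (500.0, 500.0)}
        best, frontier = design_controller(cl_model, bounds, weight=0.0,
                                           n_grid=1, omega_grid=GRID)
        assert len(frontier) == 1
        assert best.controller.k_D == pytest.approx(500.0)

    def test_optimum_minimises_slope_when_unweighted(self, cl_model):
        bounds = {"k_D": (100.0, 2000.0), "h": (1.0, 4.0)}
        best, frontier = design_controller(cl_model, bounds, weight=0.0,
                                           n_grid=2, omega_grid=GRID)
        assert frontier["J"].min() == pytest.approx(
            abs(frontier["slope_norm"]).min())
        best_res, _, _ = _evaluate_circuit(best, GRID)
        assert abs(best_res.slope_norm) <= abs(frontier["slope_norm"]).min() \
            * (1 + 1e-9)

    def test_invalid_bounds_rejected(self, cl_model):
        with pytest.raises(InvalidParameterError):
            design_controller(cl_model, {"k_D": (-1.0, 10.0)})
        with pytest.raises(InvalidParameterError):
            design_controller(cl_model, {"nope": (1.0, 2.0)})


class TestSensitivity:
    def test_single_value_equals_direct_evaluation(self, cl_model):
        df = sensitivity_sweep(cl_model, "k_D", [500.0], omega_grid=GRID)
        res, expr, _ = _evaluate_circuit(cl_model, GRID)
        assert df.loc[0, "slope_norm"] == pytest.approx(res.slope_norm,
                                                        rel=1e-6)
        assert df.loc[0, "expression"] == pytest.approx(expr, rel=1e-6)

    def test_steeper_hill_decouples_at_least_as_well(self, cl_model):
        df = sensitivity_sweep(cl_model, "h", [1.0, 4.0], omega_grid=GRID)
        assert abs(df.loc[1, "slope_norm"]) <= abs(df.loc[0, "slope_norm"])

    def test_kD_tunes_expression_more_than_coupling(self, cl_model):
        df = sensitivity_sweep(cl_model, "k_D", [200.0, 632.0, 2000.0],
                               omega_grid=GRID)
        rel_span = lambda s: (s.max() - s.min()) / s.abs().mean()
        assert rel_span(df["expression"]) > rel_span(df["slope_norm"])

    def test_unknown_parameter_rejected(self, cl_model):
        with pytest.raises(InvalidParameterError):
            sensitivity_sweep(cl_model, "mystery", [1.0])


class TestRobustnessMC:
    def test_zero_perturbation_reproduces_optimum(self, cl_model):
        df, summary = robustness_mc(cl_model, n=3, frac=0.0, seed=5,
                                    omega_grid=GRID, open_loop_slope=-0.9)
        assert summary["n_excluded"] == 0
        assert df["slope_norm"].nunique() == 1

    def test_seeded_runs_are_identical(self, cl_model):
        kw = dict(n=4, frac=0.5, seed=11, omega_grid=GRID,
                  open_loop_slope=-0.9)
        df1, s1 = robustness_mc(cl_model, **kw)
        df2, s2 = robustness_mc(cl_model, **kw)
        pd.testing.assert_frame_equal(df1, df2)
        assert s1 == s2

    def test_draw_accounting_conserves_n(self, cl_model):
        df, summary = robustness_mc(cl_model, n=5, frac=0.4, seed=2,
                                    omega_grid=GRID, open_loop_slope=-0.9)
        assert len(df) == 5
        assert summary["n_excluded"] + df["converged"].sum() == 5

    def test_argument_validation(self, cl_model):
        with pytest.raises(InvalidParameterError):
            robustness_mc(cl_model, n=0)
        with pytest.raises(InvalidParameterError):
            robustness_mc(cl_model, n=1, frac=1.5)


def test_resource_competition_is_the_sensor(cl_model):
    """Steady-state repressor level falls as circuit demand rises."""
    levels = []
    for omega in (1.0, 100.0, 1000.0):
        m = cl_model.clone()
        m.genes["RFP"].omega = omega
        m.invalidate()
        ss = solve_steady_state(m)
        levels.append(ss.state[m.index["p_F"]])
    assert np.all(np.diff(levels) < 0)
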