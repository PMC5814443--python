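"""Core cell model: rate laws, ODE structure, steady-state solving."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from oribosim.model import (
    CellModel,
    HostParameters,
    InvalidParameterError,
    NumericalStateError,
    simulate,
    solve_steady_state,
    state_frame,
    transcription_rate,
    translation_rate,
)


class TestRateLaws:
    @pytest.mark.parametrize("e,expected", [(0.0, 0.0), (4.38, 50.0)])
    def test_transcription_zero_and_half_saturation(self, e, expected):
        assert transcription_rate(100.0, e, 4.38) == pytest.approx(expected)

    def test_transcription_saturates_at_omega(self):
        assert transcription_rate(100.0, 1e12, 4.38) == pytest.approx(100.0, rel=1e-9)

    def test_transcription_rejects_bad_domain(self):
        with pytest.raises(InvalidParameterError):
            transcription_rate(100.0, -1.0, 4.38)
        with pytest.raises(InvalidParameterError):
            transcription_rate(100.0, 1.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(omega=st.floats(0, 1e4), o=st.floats(0.01, 1e4),
           e1=st.floats(0, 1e6), e2=st.floats(0, 1e6))
    def test_transcription_bounded_and_monotone(self, omega, o, e1, e2):
        lo, hi = sorted((e1, e2))
        r_lo, r_hi = (transcription_rate(omega, e, o) for e in (lo, hi))
        assert 0.0 <= r_lo <= r_hi <= omega

    def test_translation_no_complexes(self):
        assert translation_rate(0.0, 123.0, 300.0, 1260.0, 7.0) == 0.0

    def test_translation_half_max_elongation(self):
        # gamma(K_gamma) = gamma_max/2 -> 10 complexes * 630 aa/min / 300 aa
        assert translation_rate(10, 7.0, 300, 1260.0, 7.0) == pytest.approx(21.0)

    def test_translation_linear_in_complexes(self):
        one = translation_rate(3.0, 50.0, 400.0, 1260.0, 7.0)
        two = translation_rate(6.0, 50.0, 400.0, 1260.0, 7.0)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_translation_rejects_nonpositive_length(self):
        with pytest.raises(InvalidParameterError):
            translation_rate(1.0, 1.0, 0.0, 1260.0, 7.0)


class TestParameterValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            HostParameters(delta_m=-0.1)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(InvalidParameterError):
            HostParameters(K_gamma=0.0)


class TestOdeStructure:
    def test_all_zero_state_is_fixed_point(self, base_model):
        dy = base_model.rhs(0.0, np.zeros(base_model.n_species))
        assert np.all(dy == 0.0)

    def test_nan_state_names_species(self, base_model):
        y = np.zeros(base_model.n_species)
        y[3] = np.nan
        with pytest.raises(NumericalStateError) as err:
            base_model.rhs(0.0, y)
        assert err.value.index == 3
        assert err.value.species == "c_T"

    def test_no_binding_means_complexes_only_decay(self):
        p = HostParameters(b_T=0.0, b_E=0.0, b_H=0.0, b_R=0.0)
        m = CellModel(p)
        sol = simulate(m, t_span=(0.0, 200.0),
                       t_eval=np.linspace(0, 200, 20))
        c_idx = [m.index[f"c_{x}"] for x in "TEHR"]
        for i in c_idx:
            dy = [m.rhs(0.0, sol.y[:, k])[i] for k in range(sol.t.size)]
            assert max(dy) <= 1e-12

    def test_growth_rate_zero_without_complexes(self, base_model):
        y = np.zeros(base_model.n_species)
        y[1] = 100.0
        assert base_model.growth_rate(y) == 0.0

    def test_growth_rate_single_complex_closed_form(self, base_model):
        p = base_model.params
        y = np.zeros(base_model.n_species)
        y[1] = p.K_gamma        # half-max elongation
        y[base_model.index["c_H"]] = 1.0
        assert base_model.growth_rate(y) == pytest.approx(
            p.gamma_max / (2 * p.M), rel=1e-12)


class TestSteadyState:
    def test_converged_residual_below_tolerance(self, base_ss):
        assert base_ss.converged
        assert base_ss.residual_norm <= 1e-6
        assert base_ss.lam > 0

    def test_idempotent_from_converged_state(self, base_model, base_ss):
        again = solve_steady_state(base_model, warm_start=base_ss.state)
        rel = np.max(np.abs(again.state - base_ss.state)
                     / np.maximum(1.0, np.abs(base_ss.state)))
        assert rel < 1e-6

    def test_growth_rate_matches_long_integration(self, base_model, base_ss):
        sol = simulate(base_model, t_span=(0.0, 1e5))
        lam_traj = base_model.growth_rate(sol.y[:, -1])
        assert base_ss.lam == pytest.approx(lam_traj, rel=1e-6)

    def test_unique_interior_state_from_two_starts(self, base_model, base_ss):
        y0 = base_model.initial_state() * 37.0
        y0[0] = 5000.0
        other = solve_steady_state(base_model, initial=y0)
        assert other.converged
        rel = np.max(np.abs(other.state - base_ss.state)
                     / np.maximum(np.abs(base_ss.state), 1e-12))
        assert rel < 1e-6

    def test_no_substrate_means_no_growth(self):
        m = CellModel(HostParameters(s_ext=0.0))
        ss = solve_steady_state(m)
        assert ss.lam < 1e-9
        assert ss.state[1] < 1e-6  # energy exhausted

    def test_rejects_negative_initial_state(self, base_model):
        y0 = base_model.initial_state()
        y0[0] = -1.0
        with pytest.raises(InvalidParameterError):
            solve_steady_state(base_model, initial=y0)


class TestTrajectoryInvariants:
    def test_nonnegativity_and_flux_bounds(self, base_model):
        sol = simulate(base_model, t_span=(0.0, 5000.0),
                       t_eval=np.linspace(0, 5000, 50))
        assert sol.y.min() >= -1e-9
        p = base_model.params
        for k in range(sol.t.size):
            y = sol.y[:, k]
            e = max(y[1], 0.0)
            for x in "TEHR":
                omega = getattr(p, f"omega_{x}")
                o = getattr(p, f"o_{x}")
                assert transcription_rate(omega, e, o) <= omega + 1e-12
                c = y[base_model.index[f"c_{x}"]]
                n = getattr(p, f"n_{x}")
                tl = translation_rate(max(c, 0.0), e, n, p.gamma_max, p.K_gamma)
                assert tl <= max(c, 0.0) * p.gamma_max / n + 1e-12


class TestMassFraction:
    def test_empty_state_gives_zero(self, base_model):
        assert base_model.ribosome_mass_fraction(
            np.zeros(base_model.n_species)) == 0.0

    def test_all_mass_in_ribosomes_gives_one(self, base_model):
        p = base_model.params
        y = np.zeros(base_model.n_species)
        y[base_model.index["R"]] = p.M / p.n_R
        assert base_model.ribosome_mass_fraction(y) == pytest.approx(1.0)

    def test_growth_law_rank_correlation_over_substrate(self):
        lams, phis = [], []
        for s in (100, 300, 1000, 3000, 10000, 30000):
            m = CellModel(HostParameters(s_ext=float(s)))
            ss = solve_steady_state(m)
            assert ss.converged
            lams.append(ss.lam)
            phis.append(m.ribosome_mass_fraction(ss.state))
        rho, _ = spearmanr(lams, phis)
        assert rho == pytest.approx(1.0)


class TestSerialisation:
    def test_state_frame_uses_species_symbols(self, base_model, base_ss):
        df = state_frame(base_model, base_ss.state)
        assert list(df.columns[:2]) == ["s_i", "e"]
        assert {"p_R", "r", "R"} <= set(df.columns)
        assert df.shape == (1, base_model.n_species)
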