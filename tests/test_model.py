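"""Unit tests for the competition model, PSA read-out and equilibrium solve."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from psadapt.model import (
    InvalidParameterError,
    InvalidWeightsError,
    ModelParams,
    NoFeasibleEquilibriumError,
    Populations,
    PSAWeights,
    carrying_capacities,
    make_rhs,
    psa,
    rhs,
    untreated_equilibrium,
)

BEST_A = np.array([[1.0, 0.7, 0.8], [0.4, 1.0, 0.5], [0.6, 0.9, 1.0]])


def params_with(A):
    return ModelParams(A=np.asarray(A, dtype=float))


class TestValidation:
    def test_negative_population_rejected(self):
        with pytest.raises(ValueError):
            Populations(-1.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"r_tp": 0.0},
            {"r_tminus": -1.0},
            {"K_tp_off": 0.0},
            {"K_tminus": -5.0},
        ],
    )
    def test_bad_rates_and_capacities_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ModelParams(A=BEST_A, **kwargs)

    @pytest.mark.parametrize(
        "A",
        [
            np.array([[0.9, 0.7, 0.8], [0.4, 1.0, 0.5], [0.6, 0.9, 1.0]]),  # diag != 1
            np.array([[1.0, 0.0, 0.8], [0.4, 1.0, 0.5], [0.6, 0.9, 1.0]]),  # zero entry
            np.array([[1.0, 1.2, 0.8], [0.4, 1.0, 0.5], [0.6, 0.9, 1.0]]),  # entry > 1
        ],
    )
    def test_bad_competition_matrix_rejected(self, A):
        with pytest.raises(InvalidParameterError):
            params_with(A)

    @pytest.mark.parametrize("alpha,beta", [(-0.1, 0.0), (1.1, 0.0), (0.5, 0.6)])
    def test_infeasible_weights_rejected(self, alpha, beta):
        with pytest.raises(InvalidWeightsError):
            PSAWeights(alpha, beta)


class TestCarryingCapacities:
    def test_tplus_capacity_tracks_tp_density_off_treatment(self):
        pops = Populations(606.06, 757.58, 0.0)
        k_tplus, k_tp, k_tminus = carrying_capacities(pops, params_with(BEST_A), False)
        assert k_tplus == pytest.approx(1136.37, abs=1e-10)  # 1.5 * 757.58
        assert k_tp == 10000.0
        assert k_tminus == 10000.0

    def test_treatment_collapses_tp_capacity(self):
        pops = Populations(100.0, 500.0, 100.0)
        k_tplus, k_tp, k_tminus = carrying_capacities(pops, params_with(BEST_A), True)
        assert k_tp == 100.0
        assert k_tplus == pytest.approx(0.5 * 500.0)
        assert k_tminus == 10000.0

    @pytest.mark.parametrize("on", [False, True])
    def test_degenerate_zero_tp_gives_zero_tplus_capacity(self, on):
        pops = Populations(50.0, 0.0, 50.0)
        k_tplus, _, _ = carrying_capacities(pops, params_with(BEST_A), on)
        assert k_tplus == 0.0


class TestVectorField:
    def test_extinct_state_is_fixed_point(self):
        out = rhs(Populations(0.0, 0.0, 0.0), params_with(BEST_A), False)
        assert np.all(out == 0.0)

    def test_lone_tminus_logistic_rate(self):
        # r * x * (1 - x/K) = 0.0066542 * 5000 * 0.5
        out = rhs(Populations(0.0, 0.0, 5000.0), params_with(BEST_A), False)
        assert out[2] == pytest.approx(16.6355, rel=1e-12)
        assert out[0] == 0.0 and out[1] == 0.0

    def test_population_at_capacity_is_stationary(self):
        out = rhs(Populations(0.0, 10000.0, 0.0), params_with(BEST_A), False)
        assert out[1] == pytest.approx(0.0, abs=1e-12)

    def test_floored_capacity_gives_steep_finite_decline(self):
        # T+ present with no TP: its capacity floors and T+ must crash, finitely.
        out = rhs(Populations(10.0, 0.0, 0.0), params_with(BEST_A), False)
        assert np.isfinite(out[0]) and out[0] < 0

    def test_trajectories_stay_nonnegative(self):
        # x_i = 0 is invariant; integrate from a boundary state and check.
        f = make_rhs(params_with(BEST_A), treatment_on=True)
        sol = solve_ivp(
            f, (0, 2000), [606.06, 757.58, 0.0], method="LSODA",
            rtol=1e-8, atol=1e-12,
        )
        assert sol.y.min() >= -1e-9


class TestPSA:
    TABLE1_BEST = Populations(606.06, 757.58, 1.94e-10)

    @pytest.mark.parametrize(
        "alpha,beta,expected",
        [
            (1.0, 0.0, 606.06),
            (0.0, 0.0, 1.94e-10),
            (1 / 3, 1 / 3, (606.06 + 757.58 + 1.94e-10) / 3),
        ],
    )
    def test_weighted_readout(self, alpha, beta, expected):
        assert psa(self.TABLE1_BEST, PSAWeights(alpha, beta)) == pytest.approx(
            expected, rel=1e-12
        )

    @given(
        x=st.tuples(*[st.floats(0, 1e6)] * 3),
        alpha=st.floats(0, 1),
        frac=st.floats(0, 1),
    )
    @settings(max_examples=200, derandomize=True)
    def test_psa_is_convex_combination_of_populations(self, x, alpha, frac):
        pops = Populations(*x)
        w = PSAWeights(alpha, frac * (1.0 - alpha))
        value = psa(pops, w)
        assert min(x) - 1e-9 <= value <= max(x) + 1e-9


class TestUntreatedEquilibrium:
    def test_best_responder_boundary_equilibrium(self):
        # Independent closed form: x_T- = 0, x_T+ = 0.8 x_TP, 1.32 x_TP = K.
        eq, support = untreated_equilibrium(params_with(BEST_A), scale_K=1000.0)
        x_tp = 1000.0 / 1.32
        assert support == ("T+", "TP")
        assert eq.x_tp == pytest.approx(x_tp, rel=1e-10)
        assert eq.x_tplus == pytest.approx(0.8 * x_tp, rel=1e-10)
        assert eq.x_tminus == 0.0

    def test_interior_equilibrium_matches_direct_solve(self):
        # Non-responder matrix: oracle is a direct dense solve of the full
        # 3x3 linear system (T+ row rearranged for K_T+ = mu x_TP).
        A = np.array([[1.0, 0.7, 0.9], [0.4, 1.0, 0.6], [0.5, 0.8, 1.0]])
        M = A.copy()
        M[0, 1] -= 1.5
        expected = np.linalg.solve(M, np.array([0.0, 1000.0, 1000.0]))
        eq, support = untreated_equilibrium(params_with(A), scale_K=1000.0)
        assert support == ("T+", "TP", "T-")
        np.testing.assert_allclose(eq.as_array(), expected, rtol=1e-10)
        # and the solve lands on the printed non-responder state
        np.testing.assert_allclose(eq.as_array(), [319.63, 707.76, 273.97], atol=0.01)

    def test_symmetric_matrix_closed_form(self):
        # All off-diagonals 0.4: by symmetry x_TP = x_T-, x_T+ = 0.7 x_TP,
        # and the TP row gives 1.68 x_TP = K.
        A = np.full((3, 3), 0.4)
        np.fill_diagonal(A, 1.0)
        eq, _ = untreated_equilibrium(params_with(A), scale_K=1000.0)
        x_tp = 1000.0 / 1.68
        assert eq.x_tp == pytest.approx(x_tp, rel=1e-9)
        assert eq.x_tminus == pytest.approx(x_tp, rel=1e-9)
        assert eq.x_tplus == pytest.approx(0.7 * x_tp, rel=1e-9)

    @pytest.mark.parametrize("c", [0.1, 2.0, 10.0])
    def test_linearity_in_carrying_capacity(self, c):
        eq1, _ = untreated_equilibrium(params_with(BEST_A), scale_K=1000.0)
        eq2, _ = untreated_equilibrium(params_with(BEST_A), scale_K=c * 1000.0)
        np.testing.assert_allclose(eq2.as_array(), c * eq1.as_array(), rtol=1e-9)

    @pytest.mark.parametrize(
        "A",
        [
            BEST_A,
            np.array([[1.0, 0.7, 0.8], [0.4, 1.0, 0.6], [0.5, 0.9, 1.0]]),
            np.array([[1.0, 0.7, 0.9], [0.4, 1.0, 0.6], [0.5, 0.8, 1.0]]),
        ],
        ids=["best", "responder", "non_responder"],
    )
    def test_equilibrium_confirmed_by_long_time_integration(self, A):
        # Oracle: integrate the drug-free system for 1e5 days from a strictly
        # positive perturbation of the solved point; it must return there.
        params = params_with(A)
        eq, _ = untreated_equilibrium(params, scale_K=1000.0)
        scaled = replace(params, K_tp_off=1000.0, K_tminus=1000.0)
        x0 = eq.as_array() * 1.01 + 1e-6
        sol = solve_ivp(
            make_rhs(scaled, False), (0, 1e5), x0, method="LSODA",
            rtol=1e-10, atol=1e-12,
        )
        np.testing.assert_allclose(
            sol.y[:, -1], eq.as_array(), rtol=1e-4, atol=1e-6
        )

    def test_invalid_scale_rejected(self):
        with pytest.raises(InvalidParameterError):
            untreated_equilibrium(params_with(BEST_A), scale_K=0.0)
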