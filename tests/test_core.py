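"""Interaction matrix, eigenstructure, stability and trajectory solutions."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import genestab as gs
from genestab.core import LinearRegimeWarning

from conftest import draw_params, params_with_rates

rate_st = st.floats(min_value=1e-2, max_value=10.0)


class TestInteractionMatrix:
    def test_symmetric_unit_case(self):
        p = gs.ModelParams(beta=1, p=1, K=1, G=1, c=1, delta=1, f_p=0.3, f_g=0.7)
        I = gs.build_interaction_matrix(p)
        np.testing.assert_allclose(I.matrix, [[-1, 1], [1, -1]])
        np.testing.assert_allclose(I.force, [0.3, 0.7])

    def test_trace_is_minus_total_repair_rate(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = draw_params(rng)
            I = gs.build_interaction_matrix(p)
            assert I.trace == pytest.approx(-(p.c + p.delta), rel=1e-12)

    def test_determinant_vanishes_on_separatrix(self):
        p = params_with_rates(Lambda=0.0)
        I = gs.build_interaction_matrix(p)
        assert I.det == pytest.approx(0.0, abs=1e-10)

    def test_force_vector_scales_genome_damage_by_G(self):
        p = gs.ModelParams(G=500, f_p=0.1, f_g=0.002)
        I = gs.build_interaction_matrix(p)
        np.testing.assert_allclose(I.force, [0.1, 1.0])

    def test_rejects_invalid_params(self):
        with pytest.raises(ValueError):
            gs.ModelParams(beta=-0.1)
        with pytest.raises(ValueError):
            gs.ModelParams(G=0.5)
        with pytest.raises(ValueError):
            gs.ModelParams(c=0.0, delta=0.0)

    def test_coupling_flag_moves_G_out_of_the_gain(self):
        p = gs.ModelParams(beta=0.01, K=2, G=100, coupling_includes_G=False)
        I = gs.build_interaction_matrix(p)
        assert I.matrix[1, 0] == pytest.approx(0.02)


class TestEigendecompose:
    def test_symmetric_matrix_modes(self):
        p = gs.ModelParams(beta=1, p=1, K=1, G=1, c=1, delta=1)
        es = gs.eigendecompose(gs.build_interaction_matrix(p))
        assert es.lambda1 == pytest.approx(0.0, abs=1e-14)
        assert es.lambda2 == pytest.approx(-2.0)
        # slow mode along (1, 1)
        assert abs(es.b1[0]) == pytest.approx(abs(es.b1[1]), rel=1e-12)

    def test_hand_derived_roots(self):
        # c=1, delta=2, p*beta*K*G=6: lambda^2 + 3 lambda - 4 = 0
        p = gs.ModelParams(beta=6, p=1, K=1, G=1, c=1, delta=2)
        es = gs.eigendecompose(gs.build_interaction_matrix(p))
        assert es.lambda1 == pytest.approx(1.0, rel=1e-12)
        assert es.lambda2 == pytest.approx(-4.0, rel=1e-12)

    def test_eigenvalues_always_real_and_ordered(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            es = gs.eigendecompose(gs.build_interaction_matrix(draw_params(rng)))
            assert np.isreal(es.lambda1) and np.isreal(es.lambda2)
            assert es.lambda1 >= es.lambda2

    def test_biorthonormality(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            es = gs.eigendecompose(gs.build_interaction_matrix(draw_params(rng)))
            if es.degenerate:
                continue
            prod = es.left_matrix @ es.right_matrix
            np.testing.assert_allclose(prod, np.eye(2), atol=1e-10)

    def test_eigen_identities(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p = draw_params(rng)
            I = gs.build_interaction_matrix(p)
            es = gs.eigendecompose(I)
            assert es.lambda1 + es.lambda2 == pytest.approx(-(p.c + p.delta), rel=1e-9)
            assert es.lambda1 * es.lambda2 == pytest.approx(I.det, rel=1e-8, abs=1e-12)

    def test_degenerate_case_is_flagged(self):
        # K = 0 decouples the compartments; c = delta makes the roots collide
        p = gs.ModelParams(beta=1, p=1, K=0, G=1, c=1, delta=1)
        es = gs.eigendecompose(gs.build_interaction_matrix(p))
        assert es.degenerate


class TestStability:
    def test_unit_case_is_critical(self):
        rep = gs.stability(gs.ModelParams(beta=1, p=1, K=1, G=1, c=1, delta=1))
        assert rep.R0 == pytest.approx(1.0)
        assert rep.Lambda == pytest.approx(0.0, abs=1e-15)
        assert rep.regime == "critical"

    def test_overwhelming_repair_is_stable(self):
        rep = gs.stability(gs.ModelParams(beta=1, p=1, K=1, G=1, c=1e6, delta=1))
        assert rep.regime == "stable"

    def test_hand_derived_unstable_case(self):
        rep = gs.stability(gs.ModelParams(beta=6, p=1, K=1, G=1, c=1, delta=2))
        assert rep.R0 == pytest.approx(3.0)
        assert rep.Lambda == pytest.approx(4.0 / 3.0)
        assert rep.lambda1_exact == pytest.approx(1.0, rel=1e-12)
        assert rep.mrdt == pytest.approx(np.log(2) / (4.0 / 3.0))

    def test_no_repair_at_all_is_an_error(self):
        with pytest.raises(ValueError):
            gs.ModelParams(c=0.0, delta=0.0)

    def test_zero_repair_product_gives_infinite_R0(self):
        rep = gs.stability(gs.ModelParams(c=1.0, delta=0.0))
        assert np.isinf(rep.R0)
        assert rep.regime == "unstable"

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(beta=rate_st, p=rate_st, K=rate_st, c=rate_st, delta=rate_st,
           G=st.integers(min_value=1, max_value=2000))
    def test_sign_agreement_is_exact(self, beta, p, K, c, delta, G):
        """sign(lambda1) = sign(R0 - 1) = sign(Lambda), with no tolerance."""
        params = gs.ModelParams(beta=beta, p=p, K=K, G=G, c=c, delta=delta)
        rep = gs.stability(params)
        s = np.sign(params.loop_gain - params.repair_gain)
        assert np.sign(rep.Lambda) == s
        assert np.sign(rep.R0 - 1.0) == s
        # the exact eigenvalue may only differ from zero by rounding at the
        # separatrix itself, which the strategy cannot hit exactly
        assert np.sign(rep.lambda1_exact) == s

    def test_taylor_limit_towards_separatrix(self):
        """lambda1/Lambda -> 1 and lambda2/-(c+delta) -> 1 as R0 -> 1."""
        ratios1, ratios2 = [], []
        for Lam in [0.3, 0.1, 0.03, 0.01, 0.003]:
            p = params_with_rates(Lambda=Lam)
            rep = gs.stability(p)
            ratios1.append(rep.lambda1_exact / rep.Lambda)
            ratios2.append(-gs.eigendecompose(gs.build_interaction_matrix(p)).lambda2 / p.E)
        err1 = np.abs(np.array(ratios1) - 1.0)
        err2 = np.abs(np.array(ratios2) - 1.0)
        assert np.all(np.diff(err1) < 0) and err1[-1] < 1e-3
        assert np.all(np.diff(err2) < 0) and err2[-1] < 1e-3


def _ode_oracle(params, x0, t):
    I = gs.build_interaction_matrix(params)
    sol = solve_ivp(
        lambda _t, x: I.matrix @ x + I.force,
        (t[0], t[-1]), np.asarray(x0, float),
        t_eval=t, rtol=1e-11, atol=1e-13, method="DOP853",
    )
    assert sol.success
    return sol.y.T


class TestSolveDynamics:
    def test_null_dynamics(self, fly_params):
        p = gs.ModelParams(f_p=0.0, f_g=0.0)
        traj = gs.solve_dynamics(p, (0.0, 0.0), np.linspace(0, 10, 11))
        np.testing.assert_allclose(traj["e_p"], 0.0, atol=1e-12)
        np.testing.assert_allclose(traj["e_g"], 0.0, atol=1e-12)

    def test_stable_system_reaches_fixed_point(self, stable_params):
        I = gs.build_interaction_matrix(stable_params)
        xstar = -np.linalg.solve(I.matrix, I.force)
        traj = gs.solve_dynamics(stable_params, (0.0, 0.0), np.array([0.0, 200.0]))
        np.testing.assert_allclose(
            [traj["e_p"][-1], traj["e_g"][-1]], xstar, rtol=1e-10)

    @pytest.mark.parametrize("Lam", [0.5, -0.5])
    def test_matches_ode_oracle(self, Lam):
        p = params_with_rates(Lambda=Lam, f_p=0.01, f_g=1e-5)
        t = np.linspace(0, 10, 60)
        traj = gs.solve_dynamics(p, (1.0, 2.0), t, linear_threshold=1.0)
        ref = _ode_oracle(p, (1.0, 2.0), t)
        got = np.column_stack([traj["e_p"], traj["e_g"]])
        err = np.max(np.abs(got - ref)) / np.max(np.abs(ref))
        assert err < 1e-6

    def test_separatrix_falls_back_to_integration(self):
        p = params_with_rates(Lambda=0.0, f_p=0.01, f_g=1e-5)
        t = np.linspace(0, 5, 30)
        traj = gs.solve_dynamics(p, (0.0, 0.0), t)
        ref = _ode_oracle(p, (0.0, 0.0), t)
        got = np.column_stack([traj["e_p"], traj["e_g"]])
        assert np.max(np.abs(got - ref)) / np.max(np.abs(ref)) < 1e-6

    def test_non_monotone_grid_rejected(self, fly_params):
        with pytest.raises(ValueError):
            gs.solve_dynamics(fly_params, (0, 0), np.array([0.0, 2.0, 1.0]))

    def test_linear_regime_warning(self):
        p = params_with_rates(Lambda=0.5, G=100.0, f_p=0.5, f_g=0.01)
        with pytest.warns(LinearRegimeWarning):
            gs.solve_dynamics(p, (0.0, 0.0), np.linspace(0, 30, 20))

    def test_hazard_column_is_omega_scaled_gene_fraction(self, fly_params):
        t = np.linspace(0, 20, 10)
        traj = gs.solve_dynamics(fly_params, (0.0, 0.0), t)
        np.testing.assert_allclose(
            traj["M"], fly_params.omega * traj["e_g"] / fly_params.G, rtol=1e-12)


class TestAdiabaticMortality:
    def _sup_err(self, params, t):
        traj = gs.solve_dynamics(params, (0.0, 0.0), t, linear_threshold=1.0)
        Mad = gs.adiabatic_mortality(params, t)
        return np.max(np.abs(Mad - traj["M"])) / np.max(np.abs(traj["M"]))

    def test_critical_network_gives_linear_mortality(self):
        p = params_with_rates(Lambda=0.0, f_p=0.01, f_g=1e-5)
        t = np.array([1.0, 2.0, 4.0, 8.0])
        M = gs.adiabatic_mortality(p, t)
        np.testing.assert_allclose(M / t, M[0] / t[0], rtol=1e-9)

    def test_near_separatrix_form_linear_at_small_Lambda(self):
        p = params_with_rates(Lambda=1e-9, f_p=0.01, f_g=1e-5)
        t = np.array([1.0, 2.0, 4.0])
        M = gs.adiabatic_mortality(p, t, rate="near_separatrix")
        np.testing.assert_allclose(M / t, M[0] / t[0], rtol=1e-6)

    def test_stable_network_mortality_plateaus(self):
        p = params_with_rates(Lambda=-0.1, f_p=0.01, f_g=1e-5)
        es = gs.eigendecompose(gs.build_interaction_matrix(p))
        I = gs.build_interaction_matrix(p)
        mbar = p.omega * float(es.a1 @ I.force) * es.b1[1] / p.G / abs(es.lambda1)
        late = float(gs.adiabatic_mortality(p, 200.0))
        assert late == pytest.approx(mbar, rel=1e-10)

    @pytest.mark.parametrize("Lam", [0.01, -0.01])
    def test_within_two_percent_at_strong_separation(self, Lam):
        # E = c + delta = 5 >= 100 |Lambda|
        p = params_with_rates(Lambda=Lam, f_p=0.01, f_g=1e-5)
        t = np.linspace(0.0, 5.0 / abs(Lam), 300)
        assert self._sup_err(p, t) < 0.02

    def test_discrepancy_grows_as_separation_shrinks(self):
        errs = []
        for ratio in [400.0, 100.0, 25.0, 8.0]:
            Lam = -5.0 / ratio
            p = params_with_rates(Lambda=Lam, f_p=0.01, f_g=1e-5)
            t = np.linspace(0.0, 5.0 / abs(Lam), 300)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                errs.append(self._sup_err(p, t))
        assert np.all(np.diff(errs) > 0)

    def test_weak_separation_warns(self):
        p = params_with_rates(Lambda=1.0, f_p=0.01, f_g=1e-5)
        with pytest.warns(UserWarning, match="separation"):
            gs.adiabatic_mortality(p, 1.0)
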