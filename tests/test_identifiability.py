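"""Sensitivities, FIM / Cramér-Rao machinery, local SIA rank, sign agreement."""

import numpy as np
import pandas as pd
import pytest

from mcid.estimation import EstimationProblem
from mcid.fixtures import glv2, glv3
from mcid.identifiability import (compute_fim, compute_sensitivities,
                                  cramer_rao_intervals, local_sia_rank,
                                  sign_agreement)
from mcid.model_core import (ExperimentDesign, ModelSpec,
                             make_observation_map)
from mcid.synthetic_data import COLUMNS, Dataset


def _scalar_rate_problem(times, sigma=1.0):
    """x' = k, x(0)=0, y=x: the sensitivity dy/dk at time t is exactly t."""
    model = ModelSpec(
        n_x=1, state_names=["x"], rhs=lambda x, th, u, t: np.array([th[0]]),
        param_names=["k"], bounds=np.array([[0.01, 10.0]]),
        jacobian_x=lambda x, th, u, t: np.zeros((1, 1)),
        jacobian_theta=lambda x, th, u, t: np.array([[1.0]]))
    obs = make_observation_map("FO", 1, state_names=["x"])
    design = ExperimentDesign("e", [0.0], (0, max(times) + 1), times, obs)
    rows = [("e", "x", float(t), float(t), sigma) for t in times]
    prob = EstimationProblem(model, [design],
                             Dataset(pd.DataFrame(rows, columns=COLUMNS)))
    return prob


class TestSensitivities:
    @pytest.mark.parametrize("method", ["forward_ode", "finite_difference"])
    def test_scalar_model_closed_form(self, method):
        prob = _scalar_rate_problem([1.0, 2.0])
        S = compute_sensitivities(prob, np.array([1.0]), method)
        np.testing.assert_allclose(S.S.ravel(), [1.0, 2.0], rtol=1e-6)

    def test_forward_matches_finite_difference_on_glv2(
            self, glv2_noisy_problem, glv2_fixture):
        p = glv2_noisy_problem.nominal_free(glv2_fixture["theta_nominal"])
        Sf = compute_sensitivities(glv2_noisy_problem, p, "forward_ode").S
        Sd = compute_sensitivities(glv2_noisy_problem, p,
                                   "finite_difference").S
        assert np.max(np.abs(Sf - Sd)) / np.max(np.abs(Sf)) < 1e-4

    def test_inert_parameter_has_zero_sensitivity(self):
        """A parameter appearing in neither rhs nor observation: S = 0."""
        model = ModelSpec(
            n_x=1, state_names=["x"],
            rhs=lambda x, th, u, t: np.array([th[0]]),
            param_names=["k", "unused"],
            bounds=np.array([[0.01, 10.0], [0.01, 10.0]]))
        obs = make_observation_map("FO", 1, state_names=["x"])
        design = ExperimentDesign("e", [0.0], (0, 3), [1.0, 2.0], obs)
        rows = [("e", "x", 1.0, 1.0, 1.0), ("e", "x", 2.0, 2.0, 1.0)]
        prob = EstimationProblem(model, [design],
                                 Dataset(pd.DataFrame(rows, columns=COLUMNS)))
        S = compute_sensitivities(prob, np.array([1.0, 5.0]),
                                  "finite_difference")
        np.testing.assert_allclose(S.S[:, 1], 0.0, atol=1e-9)

    def test_blowup_point_raises_with_guidance(self):
        from mcid.model_core import build_glv
        model = build_glv([0.0], [[1.0]])
        obs = make_observation_map("FO", 1)
        design = ExperimentDesign("e", [1.0], (0, 3), [0.5, 2.5], obs)
        rows = [("e", "x1", 0.5, 1.0, 1.0), ("e", "x1", 2.5, 1.0, 1.0)]
        prob = EstimationProblem(model, [design],
                                 Dataset(pd.DataFrame(rows, columns=COLUMNS)))
        with pytest.raises(RuntimeError, match="stability"):
            compute_sensitivities(prob, np.array([0.0, 1.0]), "forward_ode")


class TestFIM:
    def test_scalar_fim_is_sum_of_squared_times(self):
        prob = _scalar_rate_problem([1.0, 2.0])
        S = compute_sensitivities(prob, np.array([1.0]))
        rep = compute_fim(S)
        assert rep.fim[0, 0] == pytest.approx(5.0, rel=1e-8)

    def test_fim_symmetric_psd_for_random_inputs(
            self, glv2_noisy_problem, glv2_fixture):
        p = glv2_noisy_problem.nominal_free(glv2_fixture["theta_nominal"])
        rep = compute_fim(compute_sensitivities(glv2_noisy_problem, p))
        np.testing.assert_allclose(rep.fim, rep.fim.T, atol=1e-10)
        assert np.min(rep.eigenvalues) > -1e-8 * np.max(rep.eigenvalues)

    def test_collinear_parameters_give_singular_fim(self):
        """y = (th1 + th2) * t: sensitivity columns are identical."""
        model = ModelSpec(
            n_x=1, state_names=["x"],
            rhs=lambda x, th, u, t: np.array([th[0] + th[1]]),
            param_names=["k1", "k2"],
            bounds=np.array([[0.01, 10.0], [0.01, 10.0]]))
        obs = make_observation_map("FO", 1, state_names=["x"])
        design = ExperimentDesign("e", [0.0], (0, 3), [1.0, 2.0], obs)
        rows = [("e", "x", 1.0, 1.0, 1.0), ("e", "x", 2.0, 2.0, 1.0)]
        prob = EstimationProblem(model, [design],
                                 Dataset(pd.DataFrame(rows, columns=COLUMNS)))
        rep = compute_fim(compute_sensitivities(
            prob, np.array([0.5, 0.5]), "finite_difference"))
        assert rep.singular_flag
        rank = np.sum(rep.eigenvalues > 1e-10 * rep.eigenvalues[-1])
        assert rank == 1

    def test_empty_sensitivities_rejected(self):
        prob = _scalar_rate_problem([1.0])
        S = compute_sensitivities(prob, np.array([1.0]))
        S.S = np.empty((0, 1))
        S.records = S.records.iloc[:0]
        with pytest.raises(ValueError):
            compute_fim(S)


class TestCramerRao:
    def test_scalar_half_width_closed_form(self):
        prob = _scalar_rate_problem([1.0, 2.0])
        rep = compute_fim(compute_sensitivities(prob, np.array([1.0])))
        rep = cramer_rao_intervals(rep, np.array([1.0]), confidence=0.95)
        assert rep.ci["half_width"][0] == pytest.approx(
            1.959964 * np.sqrt(1.0 / 5.0), rel=1e-5)
        np.testing.assert_allclose(np.diag(rep.correlation), 1.0)

    def test_doubling_sigma_doubles_half_widths(self):
        prob1 = _scalar_rate_problem([1.0, 2.0], sigma=1.0)
        prob2 = _scalar_rate_problem([1.0, 2.0], sigma=2.0)
        reps = []
        for prob in (prob1, prob2):
            rep = compute_fim(compute_sensitivities(prob, np.array([1.0])))
            reps.append(cramer_rao_intervals(rep, np.array([1.0])))
        assert reps[1].ci["half_width"][0] == pytest.approx(
            2 * reps[0].ci["half_width"][0], rel=1e-8)

    def test_half_width_matches_monte_carlo_sampling_sd(self):
        """Linear-Gaussian model y = a + b t: the Cramér-Rao bound is exact,
        so the CI half-width must match the sampling sd of the least-squares
        estimator over 10^4 replicates within 3 MC standard errors."""
        times = np.linspace(0.5, 4.0, 8)
        sigma = 0.3
        a, b = 1.0, -0.5

        model = ModelSpec(
            n_x=1, state_names=["y"],
            rhs=lambda x, th, u, t: np.array([th[0]]),
            param_names=["slope"], bounds=np.array([[-5.0, 5.0]]))
        obs = make_observation_map("FO", 1, state_names=["y"])
        design = ExperimentDesign("e", [0.0], (0, 5), times, obs,
                                  x0_estimate=(0,),
                                  x0_bounds=np.array([[-5.0, 5.0]]))
        rows = [("e", "y", float(t), a + b * t, sigma) for t in times]
        prob = EstimationProblem(model, [design],
                                 Dataset(pd.DataFrame(rows, columns=COLUMNS)))
        rep = compute_fim(compute_sensitivities(prob, np.array([b, a])))
        rep = cramer_rao_intervals(rep, np.array([b, a]), confidence=0.95)
        # Monte-Carlo: the LS estimator is linear in the noise, so replicate
        # fits reduce to the normal-equation projection of noisy data
        rng = np.random.default_rng(99)
        A = np.column_stack([times, np.ones_like(times)])  # [slope, intercept]
        P = np.linalg.inv(A.T @ A) @ A.T
        n_rep = 10_000
        noise = rng.normal(0, sigma, size=(n_rep, times.size))
        est = noise @ P.T + [b, a]
        for k in range(2):
            mc_sd = np.std(est[:, k])
            cr_sd = rep.ci["half_width"][k] / 1.959964
            mc_se = mc_sd / np.sqrt(2 * n_rep)
            assert abs(mc_sd - cr_sd) < 3 * mc_se

    def test_singular_fim_uses_pseudoinverse_and_flags(self):
        model = ModelSpec(
            n_x=1, state_names=["x"],
            rhs=lambda x, th, u, t: np.array([th[0] + th[1]]),
            param_names=["k1", "k2"],
            bounds=np.array([[0.01, 10.0], [0.01, 10.0]]))
        obs = make_observation_map("FO", 1, state_names=["x"])
        design = ExperimentDesign("e", [0.0], (0, 3), [1.0, 2.0], obs)
        rows = [("e", "x", 1.0, 1.0, 1.0), ("e", "x", 2.0, 2.0, 1.0)]
        prob = EstimationProblem(model, [design],
                                 Dataset(pd.DataFrame(rows, columns=COLUMNS)))
        rep = compute_fim(compute_sensitivities(
            prob, np.array([0.5, 0.5]), "finite_difference"))
        rep = cramer_rao_intervals(rep, np.array([0.5, 0.5]))
        assert rep.singular_flag
        assert np.all(np.isfinite(rep.covariance))


class TestLocalSIA:
    def test_glv2_fully_observed_identifiable(self, glv2_fixture):
        model = glv2_fixture["model"]
        obs = make_observation_map("FO", 2, state_names=model.state_names)
        rep = local_sia_rank(model, obs, glv2_fixture["theta_nominal"],
                             x0=np.array([0.2, 0.1]), t_span=(0, 10), seed=0)
        assert rep.verdict == "locally_identifiable"
        assert rep.deficiency == 0

    def test_glv2_single_species_unknown_x0_deficient(self, glv2_fixture):
        """Observing one species with unknown initial conditions leaves a
        continuous unidentifiable direction."""
        model = glv2_fixture["model"]
        obs = make_observation_map("PO_subset", 2, indices=[0],
                                   state_names=model.state_names)
        rep = local_sia_rank(model, obs, glv2_fixture["theta_nominal"],
                             x0=np.array([0.2, 0.1]), t_span=(0, 10),
                             estimate_x0=True, seed=0)
        assert rep.verdict == "locally_non_identifiable"
        assert rep.deficiency >= 1
        assert len(rep.implicated) == rep.deficiency

    def test_glv2_total_biomass_shows_global_local_gap(self, glv2_fixture):
        """Total biomass on two species: the ambiguity is the discrete
        permutation symmetry, which a local rank test rightly passes — the
        documented global/local gap of the numeric surrogate."""
        model = glv2_fixture["model"]
        obs = make_observation_map("PO_sum", 2, indices=[0, 1],
                                   state_names=model.state_names)
        rep = local_sia_rank(model, obs, glv2_fixture["theta_nominal"],
                             x0=np.array([0.2, 0.1]), t_span=(0, 10),
                             estimate_x0=True, seed=0)
        assert rep.verdict == "locally_identifiable"
        # but the weakest direction is orders of magnitude softer than FO
        sv = rep.singular_values
        assert sv[-1] / sv[0] < 1e-5

    def test_collinear_toy_model_direction(self):
        """y = (th1 + th2) t: rank 1, null direction (1, -1)/sqrt(2)."""
        model = ModelSpec(
            n_x=1, state_names=["x"],
            rhs=lambda x, th, u, t: np.array([th[0] + th[1]]),
            param_names=["k1", "k2"],
            bounds=np.array([[0.01, 10.0], [0.01, 10.0]]))
        obs = make_observation_map("FO", 1, state_names=["x"])
        rep = local_sia_rank(model, obs, np.array([0.5, 0.5]),
                             x0=np.array([0.0]), t_span=(0, 5), seed=0)
        assert rep.rank == 1
        assert rep.deficiency == 1
        direction = np.abs(rep.implicated[0])
        np.testing.assert_allclose(direction, [1 / np.sqrt(2)] * 2, atol=1e-6)

    def test_verdict_invariant_to_time_rescaling(self, glv2_fixture):
        """Rescaling time units (and rates accordingly) must not change the
        identifiability verdict."""
        model = glv2_fixture["model"]
        theta = glv2_fixture["theta_nominal"]
        obs = make_observation_map("FO", 2, state_names=model.state_names)
        rep1 = local_sia_rank(model, obs, theta, x0=np.array([0.2, 0.1]),
                              t_span=(0, 10), seed=0)
        rep2 = local_sia_rank(model, obs, 10.0 * theta,
                              x0=np.array([0.2, 0.1]), t_span=(0, 1), seed=0)
        assert rep1.verdict == rep2.verdict == "locally_identifiable"

    def test_adding_second_observable_restores_rank(self, glv3_fixture):
        """The partial-aggregate scheme on three species is rank deficient;
        fully disaggregated observation restores full rank."""
        model = glv3_fixture["model"]
        theta = glv3_fixture["theta_nominal"]
        x0 = glv3_fixture["x0"]["e1"]
        agg = make_observation_map("PO_sum", 3, indices=[0, 1],
                                   state_names=model.state_names)
        rep_agg = local_sia_rank(model, agg, theta, x0=x0, t_span=(0, 6),
                                 estimate_x0=True, seed=0)
        assert rep_agg.deficiency >= 1
        full = make_observation_map("FO", 3, state_names=model.state_names)
        rep_full = local_sia_rank(model, full, theta, x0=x0, t_span=(0, 6),
                                  estimate_x0=True, seed=0)
        assert rep_full.deficiency == 0


class TestSignAgreement:
    def test_perfect_and_inverted(self):
        theta = np.array([0.5, -0.3, 1.2])
        assert sign_agreement(theta, theta)[0] == 1.0
        assert sign_agreement(-theta, theta)[0] == 0.0

    def test_half_negated(self):
        theta = np.array([1.0, -1.0, 2.0, -2.0])
        flipped = theta * np.array([1, 1, -1, -1])
        assert sign_agreement(flipped, theta)[0] == 0.5

    def test_zero_nominal_uses_dead_band(self):
        frac, table = sign_agreement(np.array([1e-10, 0.5]),
                                     np.array([0.0, 0.5]))
        assert frac == 1.0
        frac, _ = sign_agreement(np.array([0.3, 0.5]), np.array([0.0, 0.5]))
        assert frac == 0.5

    def test_mask_and_mismatch(self):
        theta = np.array([1.0, -1.0])
        frac, table = sign_agreement(theta * [-1, 1], theta,
                                     mask=[True, False])
        assert frac == 0.0
        assert len(table) == 1
        with pytest.raises(ValueError):
            sign_agreement(np.array([1.0]), np.array([1.0, 2.0]))
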