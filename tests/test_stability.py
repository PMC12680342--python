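"""Equilibria, eigenvalue classification, and post-fit stability screening."""

import numpy as np
import pandas as pd
import pytest

from mcid.estimation import EstimationProblem, FitResult, wls_cost
from mcid.fixtures import glv2
from mcid.model_core import (ExperimentDesign, ModelSpec, build_glv, glv_pack,
                             make_observation_map)
from mcid.stability import (classify_equilibrium, find_equilibria,
                            stability_screen)
from mcid.synthetic_data import COLUMNS, Dataset


class TestFindEquilibria:
    def test_logistic_has_zero_and_carrying_capacity(self):
        model = build_glv([1.0], [[-1.0]])
        eqs = find_equilibria(model, glv_pack([1.0], [[-1.0]]))
        points = sorted(float(e.x_star[0]) for e in eqs)
        assert points == pytest.approx([0.0, 1.0])

    def test_decoupled_pair_has_four_equilibria(self):
        model = build_glv([1.0, 1.0], np.diag([-1.0, -1.0]))
        eqs = find_equilibria(model, glv_pack([1.0, 1.0],
                                              np.diag([-1.0, -1.0])))
        pts = sorted(tuple(np.round(e.x_star, 10)) for e in eqs)
        assert pts == [(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)]

    def test_count_bounded_by_supports(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = 3
            mu = rng.uniform(0.2, 1.5, n)
            beta = rng.normal(0, 0.6, (n, n)) - np.diag(rng.uniform(0.8, 1.5, n))
            model = build_glv(mu, beta)
            eqs = find_equilibria(model, glv_pack(mu, beta),
                                  nonnegative_only=False)
            assert len(eqs) <= 2 ** n

    def test_interior_equilibrium_matches_linear_solve(self):
        """When the interior equilibrium exists it equals -inv(beta) mu."""
        fx = glv2()
        mu, beta = fx["theta_nominal"][:2], fx["theta_nominal"][2:].reshape(2, 2)
        expected = -np.linalg.solve(beta, mu)
        eqs = find_equilibria(fx["model"], fx["theta_nominal"])
        interior = [e for e in eqs if len(e.support) == 2]
        assert len(interior) == 1
        np.testing.assert_allclose(interior[0].x_star, expected, rtol=1e-10)

    def test_residuals_small_at_every_equilibrium(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = 3
            mu = rng.uniform(0.2, 1.5, n)
            beta = rng.normal(0, 0.6, (n, n)) - np.diag(rng.uniform(0.8, 1.5, n))
            model = build_glv(mu, beta)
            theta = glv_pack(mu, beta)
            for e in find_equilibria(model, theta):
                if e.degenerate:
                    continue
                res = np.linalg.norm(model.rhs(e.x_star, theta, None, 0.0))
                assert res <= 1e-9 * (1 + np.linalg.norm(e.x_star))

    def test_singular_support_recorded_degenerate(self):
        model = build_glv([1.0, 1.0], np.zeros((2, 2)))
        eqs = find_equilibria(model, glv_pack([1.0, 1.0], np.zeros((2, 2))),
                              nonnegative_only=False)
        assert any(e.degenerate for e in eqs)

    def test_general_model_multistart_rootfinding(self):
        """A non-gLV system with known fixed points found via search box."""
        model = ModelSpec(
            n_x=1, state_names=["x"],
            rhs=lambda x, th, u, t: np.array([np.sin(x[0]) * th[0]]),
            param_names=["k"], bounds=np.array([[0.1, 5.0]]), kind="general")
        eqs = find_equilibria(model, np.array([1.0]),
                              search_box=np.array([[-0.5, 7.0]]), seed=2)
        pts = sorted(float(e.x_star[0]) for e in eqs)
        assert pts == pytest.approx([0.0, np.pi, 2 * np.pi], abs=1e-6)


class TestClassification:
    def test_logistic_equilibria_classes(self):
        model = build_glv([1.0], [[-1.0]])
        theta = glv_pack([1.0], [[-1.0]])
        # J = mu + 2 beta x*: at x*=1 -> -1 (stable), at x*=0 -> +1 (unstable)
        stable = classify_equilibrium(model, theta, np.array([1.0]))
        unstable = classify_equilibrium(model, theta, np.array([0.0]))
        assert stable.klass == "stable_node"
        assert stable.eigenvalues[0].real == pytest.approx(-1.0)
        assert unstable.klass == "unstable_node"
        assert unstable.eigenvalues[0].real == pytest.approx(1.0)

    def test_predator_prey_center_is_neutral(self):
        """x' = x - xy, y' = xy - y: eigenvalues at (1,1) are +/- i."""
        model = build_glv([1.0, -1.0], [[0.0, -1.0], [1.0, 0.0]])
        theta = glv_pack([1.0, -1.0], [[0.0, -1.0], [1.0, 0.0]])
        eq = classify_equilibrium(model, theta, np.array([1.0, 1.0]))
        assert eq.klass == "neutral"
        np.testing.assert_allclose(sorted(eq.eigenvalues.imag), [-1.0, 1.0],
                                   atol=1e-10)
        np.testing.assert_allclose(eq.eigenvalues.real, 0.0, atol=1e-10)

    def test_saddle_detected(self):
        fx = glv2()
        eqs = {tuple(e.support): e for e in find_equilibria(
            fx["model"], fx["theta_nominal"])}
        # single-species boundary equilibria of the coexistence case are
        # saddles: stable within their own axis, invadable by the other
        assert eqs[(0,)].klass == "saddle"
        assert eqs[(1,)].klass == "saddle"
        assert eqs[(0, 1)].klass == "stable_node"

    def test_non_equilibrium_rejected(self):
        model = build_glv([1.0], [[-1.0]])
        with pytest.raises(ValueError, match="not an equilibrium"):
            classify_equilibrium(model, glv_pack([1.0], [[-1.0]]),
                                 np.array([0.5]))

    def test_classification_invariant_to_state_permutation(self):
        rng = np.random.default_rng(3)
        mu = np.array([1.0, 0.6, 1.3])
        beta = rng.normal(0, 0.4, (3, 3)) - np.diag([1.2, 1.0, 1.5])
        perm = [2, 0, 1]
        model = build_glv(mu, beta)
        model_p = build_glv(mu[perm], beta[np.ix_(perm, perm)])
        classes = sorted(e.klass for e in find_equilibria(
            model, glv_pack(mu, beta)))
        classes_p = sorted(e.klass for e in find_equilibria(
            model_p, glv_pack(mu[perm], beta[np.ix_(perm, perm)])))
        assert classes == classes_p


def _fit_problem(model, theta, design, values):
    rows = [("e", model.state_names[0], float(t), float(v), 0.1)
            for t, v in values]
    prob = EstimationProblem(model, [design],
                             Dataset(pd.DataFrame(rows, columns=COLUMNS)))
    out = wls_cost(prob, theta)
    fit = FitResult(theta=np.asarray(theta, float), J=out["J"],
                    status="converged")
    return fit, prob


class TestStabilityScreen:
    def test_logistic_fit_plausible(self):
        model = build_glv([1.0], [[-1.0]])
        theta = glv_pack([1.0], [[-1.0]])
        design = ExperimentDesign("e", [0.5], (0, 5), [1.0, 3.0, 5.0],
                                  make_observation_map("FO", 1))
        fit, prob = _fit_problem(model, theta, design,
                                 [(1.0, 0.7), (3.0, 0.95), (5.0, 0.99)])
        out = stability_screen(fit, prob)
        assert out["verdict"] == "plausible"
        assert out["evidence"]["experiments"]["e"]["stable_on_horizon"]

    def test_disguised_blowup_flagged(self):
        """x' = x^2 fitted on a window ending before its blow-up: locally
        valid but globally unstable."""
        model = build_glv([0.0], [[1.0]])
        theta = glv_pack([0.0], [[1.0]])  # blow-up at t = 1/x0 = 10
        design = ExperimentDesign("e", [0.1], (0, 5), [1.0, 3.0, 5.0],
                                  make_observation_map("FO", 1))
        fit, prob = _fit_problem(model, theta, design,
                                 [(1.0, 0.111), (3.0, 0.143), (5.0, 0.2)])
        out = stability_screen(fit, prob, horizon_factor=3.0)
        assert out["verdict"] == "locally_valid_but_unstable"
        exp = out["evidence"]["experiments"]["e"]
        assert exp["diverges_after_data_window"]

    def test_zero_dynamics_plausible(self):
        model = build_glv([0.0], [[0.0]])
        theta = glv_pack([0.0], [[0.0]])
        design = ExperimentDesign("e", [0.4], (0, 5), [1.0, 5.0],
                                  make_observation_map("FO", 1))
        fit, prob = _fit_problem(model, theta, design,
                                 [(1.0, 0.4), (5.0, 0.4)])
        assert stability_screen(fit, prob)["verdict"] == "plausible"

    def test_unconverged_fit_rejected(self):
        model = build_glv([0.0], [[0.0]])
        design = ExperimentDesign("e", [0.4], (0, 5), [1.0],
                                  make_observation_map("FO", 1))
        fit, prob = _fit_problem(model, glv_pack([0.0], [[0.0]]), design,
                                 [(1.0, 0.4)])
        fit.status = "blowup_abort"
        with pytest.raises(ValueError):
            stability_screen(fit, prob)
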