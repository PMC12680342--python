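"""Reproduction benchmarks: the study conditions behind the headline numbers.

Each function here re-runs one quantitative experiment of the workflow
end-to-end — generating data at the fixture's nominal parameters, running
the estimation / identifiability / validation machinery, and measuring the
outcome.  They are used by the acceptance machinery and are convenient
entry points for anyone wanting to reproduce the package's numbers.

Study conditions (fixed choices, documented in the methods note):

* The multistart robustness benchmark trains on a single experiment of the
  three-species fixture (12 sampling times per species on [0, 2], 10%
  proportional noise, initial conditions estimated alongside the
  parameters) with 200 uniform starts in the parameter box.
* The scatter-search good-fit suite uses both experiments per fixture
  (richer data, where the good-fit class is well defined) for the
  two- and three-species fixtures, and a reduced-scale (N=5) variant of
  the microbiome-style fixture.
* Good fit (GF) / overfit (OF) / local optimum (LO) classification uses
  delta = 0.25 in log10 units throughout.
"""

from __future__ import annotations

import numpy as np

from .estimation import (ESSSettings, EstimationProblem, ess_optimize,
                         multistart_local, wls_cost)
from .fixtures import default_designs, glv2, glv3, logistic, mglv
from .identifiability import (compute_fim, compute_sensitivities,
                              cramer_rao_intervals, local_sia_rank)
from .model_core import (ExperimentDesign, build_glv, glv_pack,
                         make_observation_map)
from .simulator import simulate
from .stability import find_equilibria, stability_screen
from .synthetic_data import NoiseModel, generate_dataset
from .validation import prediction_metrics, predict_dataset
from .workflow import spawn_seeds

__all__ = [
    "glv3_multistart_benchmark", "ess_goodfit_suite", "mglv_ess_benchmark",
    "glv2_recovery", "cramer_rao_coverage", "sia_concordance",
    "of_gf_validation_ordering", "analytic_oracles", "mglv_sign_agreement",
]

#: Integration tolerances for benchmark objective evaluations (speed/accuracy
#: trade-off for repeated fits; oracles and sensitivities use tighter ones).
BENCH_RTOL, BENCH_ATOL = 1e-7, 1e-9


def _glv3_training_problem(data_seed: int, noise_level: float = 0.10):
    """Single-experiment GLV3 calibration problem, 12 sampling times on
    [0, 2], with unknown initial conditions (the realistic scenario):
    the three initial states are estimated alongside the 12 parameters."""
    fx = glv3()
    train = [
        ExperimentDesign(d.experiment_id, d.x0, d.t_span,
                         dict(d.sampling_times), d.observation_map,
                         x0_estimate=(0, 1, 2),
                         x0_bounds=np.tile([0.01, 3.0], (3, 1)))
        for d in default_designs(fx, experiments=["e1"])
    ]
    ds = generate_dataset(fx["model"], fx["theta_nominal"], train,
                          NoiseModel("proportional", noise_level),
                          seed=data_seed)
    prob = EstimationProblem(fx["model"], train, ds,
                             rtol=BENCH_RTOL, atol=BENCH_ATOL)
    J_nom = wls_cost(prob, prob.nominal_free(fx["theta_nominal"]))["J"]
    return fx, prob, J_nom


#: Per-start objective-evaluation budget for benchmark multistart runs;
#: generous for a 12-parameter least-squares refinement (~14 evaluations per
#: trust-region iteration with a finite-difference Jacobian).
MULTISTART_MAX_NFEV = 200


def glv3_multistart_benchmark(seed: int, n_starts: int = 200) -> dict:
    """Multistart local optimization on the three-species benchmark.

    Single training experiment, 10% proportional noise, ``n_starts`` uniform
    starts.  Returns the ensemble summary fractions (converged / blowup /
    OF / GF / LO).
    """
    s_data, s_opt = spawn_seeds(seed, 2)
    _, prob, J_nom = _glv3_training_problem(s_data)
    ens = multistart_local(prob, n_starts=n_starts, seed=s_opt,
                           J_nominal=J_nom, max_nfev=MULTISTART_MAX_NFEV)
    out = dict(ens.summary)
    out["J_nominal"] = J_nom
    return out


def ess_goodfit_suite(seed: int, n_runs_per_case: int = 3,
                      max_nfev: dict | None = None) -> dict:
    """Scatter-search good-fit rate on the small-model suite.

    Both experiments per fixture, 10% proportional noise; each run is an
    independent scatter search.  Returns per-case classifications and the
    pooled GF fraction.
    """
    budgets = max_nfev or {"glv2": 2500, "glv3": 3500}
    seeds = spawn_seeds(seed, 2 + 2 * n_runs_per_case)
    results = {}
    pooled = []
    for ci, fxf in enumerate((glv2, glv3)):
        fx = fxf()
        designs = default_designs(fx)
        ds = generate_dataset(fx["model"], fx["theta_nominal"], designs,
                              NoiseModel("proportional", 0.10), seed=seeds[ci])
        prob = EstimationProblem(fx["model"], designs, ds,
                                 rtol=BENCH_RTOL, atol=BENCH_ATOL)
        J_nom = wls_cost(prob, prob.nominal_free(fx["theta_nominal"]))["J"]
        case = "glv2" if fxf is glv2 else "glv3"
        cls = []
        for k in range(n_runs_per_case):
            fit = ess_optimize(
                prob, seed=seeds[2 + ci * n_runs_per_case + k],
                settings=ESSSettings(max_nfev=budgets[case], local_every=4),
                J_nominal=J_nom)
            cls.append(fit.classification)
        results[case] = cls
        pooled += cls
    results["gf_fraction"] = float(np.mean([c == "GF" for c in pooled]))
    return results


def mglv_ess_benchmark(seed: int, n_species: int = 5, n_runs: int = 2,
                       max_nfev: int = 6000) -> dict:
    """Scatter-search good-fit rate on the reduced microbiome-style fixture.

    N=5 keeps the dense-interaction structure (30 parameters) at a tractable
    cost; the full N=12 fixture follows the same construction.
    """
    seeds = spawn_seeds(seed, 1 + n_runs)
    fx = mglv(n_species)
    designs = default_designs(fx)
    ds = generate_dataset(fx["model"], fx["theta_nominal"], designs,
                          NoiseModel("proportional", 0.10), seed=seeds[0])
    prob = EstimationProblem(fx["model"], designs, ds, rtol=1e-6, atol=1e-8)
    J_nom = wls_cost(prob, prob.nominal_free(fx["theta_nominal"]))["J"]
    cls = []
    for k in range(n_runs):
        fit = ess_optimize(
            prob, seed=seeds[1 + k],
            settings=ESSSettings(max_nfev=max_nfev, local_every=8,
                                 local_max_nfev=300),
            J_nominal=J_nom)
        cls.append(fit.classification)
    return {"classifications": cls,
            "gf_fraction": float(np.mean([c == "GF" for c in cls])),
            "J_nominal": J_nom}


def glv2_recovery(seed: int, n_seeds: int = 10, tol_rel: float = 0.01) -> dict:
    """Noise-free parameter recovery: scatter search on exact GLV2 data.

    Returns the fraction of optimizer seeds recovering every nominal
    parameter within ``tol_rel`` relative error.
    """
    fx = glv2()
    designs = default_designs(fx)
    ds = generate_dataset(fx["model"], fx["theta_nominal"], designs,
                          NoiseModel("proportional", 0.0), seed=7)
    prob = EstimationProblem(fx["model"], designs, ds)  # exact tolerances
    theta_nom = fx["theta_nominal"]
    seeds = spawn_seeds(seed, n_seeds)
    hits, errs = [], []
    for s in seeds:
        fit = ess_optimize(prob, seed=s,
                           settings=ESSSettings(max_nfev=1500, local_every=3))
        rel = np.max(np.abs(fit.theta - theta_nom) /
                     np.maximum(np.abs(theta_nom), 1e-12))
        errs.append(float(rel))
        hits.append(rel <= tol_rel)
    return {"success_fraction": float(np.mean(hits)),
            "max_rel_errors": errs, "n_seeds": n_seeds}


def cramer_rao_coverage(seed: int, n_replicates: int = 50,
                        noise_level: float = 0.05,
                        confidence: float = 0.95) -> dict:
    """Empirical coverage of Cramér-Rao confidence intervals on GLV2.

    For each replicate noise draw the model is refit (local least-squares
    refinement started from a perturbed nominal point — the estimator's own
    basin), the FIM is evaluated at the estimate, and the nominal parameter
    is checked against the per-parameter interval.  Returns the pooled
    per-parameter coverage fraction, to be compared with ``confidence``.
    """
    fx = glv2()
    designs = default_designs(fx)
    theta_nom = fx["theta_nominal"]
    seeds = spawn_seeds(seed, n_replicates)
    rng = np.random.default_rng(spawn_seeds(seed + 1, 1)[0])
    n_cover = n_total = 0
    for s in seeds:
        ds = generate_dataset(fx["model"], theta_nom, designs,
                              NoiseModel("proportional", noise_level), seed=s)
        prob = EstimationProblem(fx["model"], designs, ds)
        start = prob.nominal_free(theta_nom) * rng.uniform(0.9, 1.1,
                                                           size=len(theta_nom))
        ens = multistart_local(prob, n_starts=1, seed=s,
                               starts=start[None, :])
        fit = ens.results[0]
        if not fit.converged:
            continue
        rep = compute_fim(compute_sensitivities(prob, fit.theta,
                                                method="forward_ode"))
        rep = cramer_rao_intervals(rep, fit.theta, confidence=confidence)
        half = rep.ci["half_width"].to_numpy()
        inside = np.abs(fit.theta - theta_nom) <= half
        n_cover += int(inside.sum())
        n_total += inside.size
    return {"coverage": n_cover / n_total if n_total else float("nan"),
            "n_intervals": n_total, "confidence": confidence}


def sia_concordance(seed: int = 0) -> dict:
    """Local structural-identifiability verdicts for the concordance table.

    Full observation on GLV2/GLV3 (known x0) versus realistic partial
    observation (unknown initial conditions): a single measured species on
    GLV2, and aggregate/biomass schemes on GLV3.
    """
    out = {}
    fx2, fx3 = glv2(), glv3()
    m2, m3 = fx2["model"], fx3["model"]
    x02, x03 = fx2["x0"]["e1"], fx3["x0"]["e1"]

    rep = local_sia_rank(m2, make_observation_map("FO", 2,
                                                  state_names=m2.state_names),
                         fx2["theta_nominal"], x0=x02, t_span=(0, 10),
                         seed=seed)
    out["glv2_FO"] = {"verdict": rep.verdict, "deficiency": rep.deficiency}

    rep = local_sia_rank(m3, make_observation_map("FO", 3,
                                                  state_names=m3.state_names),
                         fx3["theta_nominal"], x0=x03, t_span=(0, 6),
                         seed=seed)
    out["glv3_FO"] = {"verdict": rep.verdict, "deficiency": rep.deficiency}

    rep = local_sia_rank(m2, make_observation_map("PO_subset", 2, indices=[0],
                                                  state_names=m2.state_names),
                         fx2["theta_nominal"], x0=x02, t_span=(0, 10),
                         estimate_x0=True, seed=seed)
    out["glv2_single_species"] = {"verdict": rep.verdict,
                                  "deficiency": rep.deficiency}

    rep = local_sia_rank(m3, make_observation_map("PO_sum", 3,
                                                  indices=[0, 1, 2],
                                                  state_names=m3.state_names),
                         fx3["theta_nominal"], x0=x03, t_span=(0, 6),
                         estimate_x0=True, seed=seed)
    out["glv3_total_biomass"] = {"verdict": rep.verdict,
                                 "deficiency": rep.deficiency}

    rep = local_sia_rank(m3, make_observation_map("PO_sum", 3, indices=[0, 1],
                                                  state_names=m3.state_names),
                         fx3["theta_nominal"], x0=x03, t_span=(0, 6),
                         estimate_x0=True, seed=seed)
    out["glv3_partial_aggregate"] = {"verdict": rep.verdict,
                                     "deficiency": rep.deficiency}
    return out


def of_gf_validation_ordering(seed: int, n_reps: int = 10,
                              n_starts: int = 25) -> dict:
    """Cross-validation ordering of overfit vs good-fit solutions on GLV3.

    Per repetition: fresh 10%-noise training data (one experiment), a
    multistart ensemble plus one scatter-search run, classification against
    the nominal objective, then simulation at the held-out experiment
    (different initial conditions) scored against its own noisy data.
    The per-repetition class representatives are the best-objective OF
    solution and the best-objective GF solution passing a stability screen
    over every study-design initial condition (overfit exemplars are
    characteristically unstable and enter unscreened); the result compares
    their pooled mean validation NRMSE.
    """
    fx = glv3()
    val_designs = default_designs(fx, experiments=["e2"])
    all_designs = default_designs(fx)
    seeds = spawn_seeds(seed, 4 * n_reps)
    of_vals, gf_vals = [], []
    for rep in range(n_reps):
        s_data, s_ms, s_ess, s_val = seeds[4 * rep: 4 * rep + 4]
        _, prob, J_nom = _glv3_training_problem(s_data)
        # the stability screen covers every study-design initial condition
        # (training and held-out), which needs no measurement data: a model
        # intended to predict from new initial states must be stable there
        screen_prob = EstimationProblem(fx["model"], all_designs,
                                        prob.dataset, rtol=BENCH_RTOL,
                                        atol=BENCH_ATOL)
        vds = generate_dataset(fx["model"], fx["theta_nominal"], val_designs,
                               NoiseModel("proportional", 0.10), seed=s_val)
        vprob = EstimationProblem(fx["model"], val_designs, vds,
                                  rtol=BENCH_RTOL, atol=BENCH_ATOL)
        fits = list(multistart_local(prob, n_starts=n_starts, seed=s_ms,
                                     J_nominal=J_nom,
                                     max_nfev=MULTISTART_MAX_NFEV).results)
        fits.append(ess_optimize(
            prob, seed=s_ess,
            settings=ESSSettings(max_nfev=1600, local_every=4),
            J_nominal=J_nom))
        from dataclasses import replace
        n_model_theta = fx["model"].n_theta
        of = [f for f in fits if f.classification == "OF"]
        gf = [f for f in fits if f.classification == "GF"
              and stability_screen(
                  replace(f, theta=f.theta[:n_model_theta]),
                  screen_prob)["verdict"] == "plausible"]
        n_th = fx["model"].n_theta
        if of:
            best = min(of, key=lambda f: f.J)
            of_vals.append(prediction_metrics(
                predict_dataset(vprob, best.theta[:n_th]), vds)["NRMSE"])
        if gf:
            best = min(gf, key=lambda f: f.J)
            gf_vals.append(prediction_metrics(
                predict_dataset(vprob, best.theta[:n_th]), vds)["NRMSE"])
    return {
        "mean_OF_validation_NRMSE": float(np.mean(of_vals)) if of_vals else float("nan"),
        "mean_GF_validation_NRMSE": float(np.mean(gf_vals)) if gf_vals else float("nan"),
        "n_OF": len(of_vals), "n_GF": len(gf_vals), "n_reps": n_reps,
    }


def analytic_oracles() -> dict:
    """Deterministic closed-form checks exercised through the package."""
    out = {}

    # finite-time blow-up: x' = x^2, x0 = 1 diverges at t = 1
    quad = build_glv([0.0], [[1.0]])
    design = ExperimentDesign("e", [1.0], (0, 2), np.linspace(0.1, 1.9, 10),
                              make_observation_map("FO", 1))
    traj = simulate(quad, glv_pack([0.0], [[1.0]]), design,
                    guard_threshold=1e9)
    out["blowup_t_stop"] = float(traj.t_stop)

    # logistic closed form at t = 5
    fx = logistic()
    design = ExperimentDesign("e", [0.5], (0, 5), [5.0],
                              make_observation_map("FO", 1))
    traj = simulate(fx["model"], fx["theta_nominal"], design)
    x5 = float(traj.state_at(5.0)[0])
    out["logistic_x5"] = x5
    out["logistic_abs_error"] = abs(x5 - 1.0 / (1.0 + np.exp(-5.0)))

    # gLV interior equilibrium equals -inv(beta) mu
    fx2 = glv2()
    mu, beta = fx2["theta_nominal"][:2], fx2["theta_nominal"][2:].reshape(2, 2)
    interior = [e for e in find_equilibria(fx2["model"], fx2["theta_nominal"])
                if len(e.support) == 2][0]
    out["interior_equilibrium_error"] = float(np.max(np.abs(
        interior.x_star - (-np.linalg.solve(beta, mu)))))
    out["interior_equilibrium_class"] = interior.klass

    # scalar FIM: x' = k, y observed at t in {1, 2}, sigma = 1 -> F = 5
    import pandas as pd

    from .model_core import ModelSpec
    from .synthetic_data import COLUMNS, Dataset
    m = ModelSpec(n_x=1, state_names=["x"],
                  rhs=lambda x, th, u, t: np.array([th[0]]),
                  param_names=["k"], bounds=np.array([[0.01, 10.0]]),
                  jacobian_x=lambda x, th, u, t: np.zeros((1, 1)),
                  jacobian_theta=lambda x, th, u, t: np.array([[1.0]]))
    d = ExperimentDesign("e", [0.0], (0, 3), [1.0, 2.0],
                         make_observation_map("FO", 1, state_names=["x"]))
    ds = Dataset(pd.DataFrame([("e", "x", 1.0, 1.0, 1.0),
                               ("e", "x", 2.0, 2.0, 1.0)], columns=COLUMNS))
    prob = EstimationProblem(m, [d], ds)
    rep = compute_fim(compute_sensitivities(prob, np.array([1.0])))
    rep = cramer_rao_intervals(rep, np.array([1.0]), confidence=0.95)
    out["scalar_fim"] = float(rep.fim[0, 0])
    out["scalar_halfwidth"] = float(rep.ci["half_width"][0])
    return out


def mglv_sign_agreement(seed: int, n_species: int = 5,
                        noise_levels=(0.0, 0.05, 0.10),
                        max_nfev: int = 6000) -> dict:
    """Sign agreement of estimated self-interaction coefficients beta_ii on
    the microbiome-style fixture, per noise level."""
    from .identifiability import sign_agreement
    fx = mglv(n_species)
    designs = default_designs(fx)
    theta_nom = fx["theta_nominal"]
    diag_mask = np.zeros(theta_nom.size, dtype=bool)
    n = n_species
    for i in range(n):
        diag_mask[n + i * n + i] = True
    seeds = spawn_seeds(seed, 2 * len(noise_levels))
    out = {}
    for li, level in enumerate(noise_levels):
        ds = generate_dataset(fx["model"], theta_nom, designs,
                              NoiseModel("proportional", level),
                              seed=seeds[2 * li])
        prob = EstimationProblem(fx["model"], designs, ds,
                                 rtol=1e-6, atol=1e-8)
        fit = ess_optimize(prob, seed=seeds[2 * li + 1],
                           settings=ESSSettings(max_nfev=max_nfev,
                                                local_every=8,
                                                local_max_nfev=300))
        frac, _ = sign_agreement(fit.theta, theta_nom, mask=diag_mask)
        out[f"noise_{int(level * 100)}pct"] = frac
    return out
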