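"""Built-in case-study model fixtures.

Three dense gLV community benchmarks of increasing size are provided:

* ``glv2`` — two species (competition or coexistence subcase), the kind of
  system used for head-to-head strain competition experiments;
* ``glv3`` — three species with mixed-sign interactions on a short data
  window, small enough to study exhaustively yet rich enough to exhibit
  local optima, overfitting and blow-up during calibration;
* ``mglv`` — a gut-microbiome-scale dense gLV (12 species by default,
  ``n_theta = 156``), generated from a fixed seed with self-limiting
  diagonals so the nominal community is bounded.

The nominal parameter values are synthetic stand-ins chosen to be
ecologically plausible (positive growth rates, negative self-interaction,
inter-specific effects weaker than or comparable to self-limitation); they
are documented defaults, not transcriptions of any published community.
Fixture models can also be stored/loaded as JSON (kind, N, mu, beta, bounds,
state names).
"""

from __future__ import annotations

import json

import numpy as np

from .model_core import (ExperimentDesign, ModelSpec, build_glv, glv_pack,
                         glv_unpack, make_observation_map)

__all__ = ["glv2", "glv3", "mglv", "logistic", "FIXTURES",
           "model_to_json", "model_from_json", "default_designs"]


def _bounds(n, mu_lo, mu_hi, b_half):
    lo = np.concatenate([np.full(n, mu_lo), np.full(n * n, -b_half)])
    hi = np.concatenate([np.full(n, mu_hi), np.full(n * n, b_half)])
    return np.column_stack([lo, hi])


def logistic(mu: float = 1.0, beta: float = -1.0) -> dict:
    """Single-species logistic growth as a gLV with N=1 (testing workhorse)."""
    model = build_glv([mu], [[beta]], bounds_policy=_bounds(1, 0.0, 3.0, 5.0))
    return {
        "name": "logistic",
        "model": model,
        "theta_nominal": glv_pack([mu], [[beta]]),
        "x0": {"e1": np.array([0.5])},
        "t_span": (0.0, 10.0),
        "n_times": 15,
    }


def glv2(subcase: str = "coexistence") -> dict:
    """Two-species gLV benchmark.

    ``coexistence``: intra-specific competition dominates, giving a stable
    interior equilibrium.  ``competition``: inter-specific competition
    dominates, giving competitive exclusion (bistability).
    """
    mu = np.array([1.0, 0.9])
    if subcase == "coexistence":
        beta = np.array([[-1.0, -0.5],
                         [-0.6, -1.2]])
    elif subcase == "competition":
        beta = np.array([[-1.0, -1.5],
                         [-1.4, -0.9]])
    else:
        raise ValueError(f"unknown GLV2 subcase {subcase!r}")
    model = build_glv(mu, beta, bounds_policy=_bounds(2, 0.0, 3.0, 5.0))
    return {
        "name": f"glv2_{subcase}",
        "model": model,
        "theta_nominal": glv_pack(mu, beta),
        "x0": {"e1": np.array([0.2, 0.1]), "e2": np.array([0.05, 0.4])},
        "t_span": (0.0, 10.0),
        "n_times": 15,
    }


def glv3() -> dict:
    """Three-species gLV with mixed competition/facilitation on a short
    data window ([0, 2]), prone to blow-up over much of its parameter box."""
    mu = np.array([2.5, 1.8, 3.0])
    beta = np.array([
        [-1.0, -0.4,  0.3],
        [ 0.8, -1.5, -0.5],
        [-0.6,  0.5, -1.8],
    ])
    model = build_glv(mu, beta, bounds_policy=_bounds(3, 0.0, 6.0, 6.0))
    return {
        "name": "glv3",
        "model": model,
        "theta_nominal": glv_pack(mu, beta),
        "x0": {"e1": np.array([0.5, 0.8, 0.3]),
               "e2": np.array([1.0, 0.2, 0.6])},
        "t_span": (0.0, 2.0),
        "n_times": 12,
    }


def mglv(n: int = 12, seed: int = 2049, interaction_scale: float = 0.15) -> dict:
    """Gut-microbiome-scale dense gLV generated from a fixed seed.

    Growth rates ~ U(0.3, 1.0); diagonal interactions ~ -U(0.8, 1.6)
    (self-limitation); off-diagonals ~ N(0, interaction_scale).  Diagonal
    dominance keeps the nominal community bounded while leaving most of the
    surrounding parameter box blow-up-prone.  ``n`` below 12 gives a
    reduced-scale variant of the same construction for cheaper benchmarks.
    """
    rng = np.random.default_rng(seed)
    mu = rng.uniform(0.3, 1.0, size=n)
    beta = rng.normal(0.0, interaction_scale, size=(n, n))
    np.fill_diagonal(beta, -rng.uniform(0.8, 1.6, size=n))
    model = build_glv(mu, beta, bounds_policy=_bounds(n, 0.0, 2.0, 2.0))
    x0_a = rng.uniform(0.05, 0.3, size=n)
    x0_b = rng.uniform(0.05, 0.3, size=n)
    return {
        "name": f"mglv_n{n}",
        "model": model,
        "theta_nominal": glv_pack(mu, beta),
        "x0": {"e1": x0_a, "e2": x0_b},
        "t_span": (0.0, 10.0),
        "n_times": 12,
    }


FIXTURES = {
    "logistic": logistic,
    "glv2": glv2,
    "glv2_coexistence": lambda: glv2("coexistence"),
    "glv2_competition": lambda: glv2("competition"),
    "glv3": glv3,
    "mglv": mglv,
}


def default_designs(fixture: dict, scheme: str = "FO",
                    experiments=None, indices=None) -> list:
    """Build one :class:`ExperimentDesign` per fixture initial condition.

    Sampling grid: ``n_times`` points evenly spaced on the data window,
    excluding t0 (where the state is known) and including tf.
    """
    model: ModelSpec = fixture["model"]
    obs = make_observation_map(scheme, model.n_x, indices=indices,
                               state_names=model.state_names)
    t0, tf = fixture["t_span"]
    times = np.linspace(t0, tf, fixture["n_times"] + 1)[1:]
    designs = []
    for exp_id in (experiments or fixture["x0"].keys()):
        designs.append(ExperimentDesign(
            experiment_id=exp_id, x0=fixture["x0"][exp_id],
            t_span=(t0, tf), sampling_times=times, observation_map=obs,
        ))
    return designs


def model_to_json(fixture: dict, path: str) -> None:
    """Store a gLV fixture as JSON (kind, N, mu, beta, bounds, names)."""
    model: ModelSpec = fixture["model"]
    if model.kind != "glv":
        raise ValueError("only gLV fixtures have a JSON form")
    mu, beta = glv_unpack(fixture["theta_nominal"], model.n_x)
    payload = {
        "kind": "glv",
        "name": fixture["name"],
        "N": model.n_x,
        "mu": mu.tolist(),
        "beta": beta.tolist(),
        "bounds": model.bounds.tolist(),
        "state_names": list(model.state_names),
        "x0": {k: v.tolist() for k, v in fixture["x0"].items()},
        "t_span": list(fixture["t_span"]),
        "n_times": fixture["n_times"],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def model_from_json(path: str) -> dict:
    """Load a gLV fixture stored by :func:`model_to_json`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("kind") != "glv":
        raise ValueError("only gLV fixture files are supported")
    model = build_glv(payload["mu"], payload["beta"],
                      bounds_policy=np.asarray(payload["bounds"]),
                      state_names=payload["state_names"])
    return {
        "name": payload.get("name", "glv"),
        "model": model,
        "theta_nominal": glv_pack(payload["mu"], payload["beta"]),
        "x0": {k: np.asarray(v, dtype=float) for k, v in payload["x0"].items()},
        "t_span": tuple(payload["t_span"]),
        "n_times": int(payload["n_times"]),
    }
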