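"""Equilibrium analysis and post-fit stability screening.

A calibrated community model can fit the data window well yet diverge
shortly beyond it.  This module (a) finds equilibria, (b) classifies each by
the eigenvalues of the Jacobian of the linearization — all real parts
negative: asymptotically stable; at least one positive: unstable; all
non-positive with some zero: neutrally stable (node/spiral/saddle/center
refinements from the eigenvalue pattern) — and (c) screens fitted parameter
sets by re-simulating on an extended horizon, flagging solutions that are
"locally valid but globally unstable".

For gLV systems equilibria are enumerated exactly: every support (subset of
surviving species) contributes at most one equilibrium, the solution of the
linear system ``beta_ss x_s = -mu_s`` restricted to the support.  General
models fall back to multistart root finding inside a search box.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import root
from scipy.stats import qmc

from .estimation import EstimationProblem, FitResult
from .model_core import ModelSpec, glv_unpack
from .simulator import long_horizon_check

__all__ = ["Equilibrium", "find_equilibria", "classify_equilibrium",
           "stability_screen", "EPS_STAB"]

#: Real parts with magnitude below EPS_STAB count as zero when classifying.
EPS_STAB = 1e-8


@dataclass
class Equilibrium:
    """A fixed point with its linearization-based classification."""

    x_star: np.ndarray
    eigenvalues: Optional[np.ndarray] = None
    klass: str = "unclassified"
    residual_norm: float = np.nan
    support: tuple = ()
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.x_star = np.asarray(self.x_star, dtype=float)
        if not self.support:
            self.support = tuple(np.flatnonzero(self.x_star > 0.0))


def _eig_class(eigenvalues: np.ndarray, eps: float = EPS_STAB) -> str:
    re = np.real(eigenvalues)
    im = np.imag(eigenvalues)
    has_imag = np.any(np.abs(im) > eps)
    pos = np.any(re > eps)
    neg = np.any(re < -eps)
    zero = np.any(np.abs(re) <= eps)
    if pos and neg:
        return "saddle"
    if pos:
        return "unstable_spiral" if has_imag else "unstable_node"
    if zero:
        # all real parts <= eps with at least one ~zero: linearization is
        # inconclusive; flagged for simulation-based follow-up
        return "neutral"
    return "stable_spiral" if has_imag else "stable_node"


def classify_equilibrium(
    model: ModelSpec,
    theta: np.ndarray,
    x_star: np.ndarray,
    residual_tol: float = 1e-8,
    eps_stab: float = EPS_STAB,
    t: float = 0.0,
) -> Equilibrium:
    """Classify a candidate equilibrium from the Jacobian eigenvalues.

    Raises when the right-hand side at ``x_star`` is not (numerically) zero.
    """
    theta = np.asarray(theta, dtype=float)
    x_star = np.asarray(x_star, dtype=float)
    u = model.input_at(t)
    res = float(np.linalg.norm(np.asarray(model.rhs(x_star, theta, u, t))))
    if res > residual_tol * (1.0 + float(np.linalg.norm(x_star))):
        raise ValueError(
            f"|rhs| = {res:.3g} at the candidate point: not an equilibrium "
            f"(tolerance {residual_tol:g})"
        )
    if model.jacobian_x is not None:
        J = np.asarray(model.jacobian_x(x_star, theta, u, t), dtype=float)
    else:
        J = _fd_jac(model, x_star, theta, u, t)
    lam = np.linalg.eigvals(J)
    return Equilibrium(x_star=x_star, eigenvalues=lam,
                       klass=_eig_class(lam, eps_stab), residual_norm=res)


def _fd_jac(model, x, theta, u, t):
    J = np.empty((model.n_x, model.n_x))
    for j in range(model.n_x):
        h = 1e-7 * max(abs(x[j]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (np.asarray(model.rhs(xp, theta, u, t)) -
                   np.asarray(model.rhs(xm, theta, u, t))) / (2 * h)
    return J


def _glv_equilibria(model: ModelSpec, theta: np.ndarray,
                    nonnegative_only: bool) -> list:
    n = model.n_x
    mu, beta = glv_unpack(theta, n)
    out = []
    for mask in itertools.product([0, 1], repeat=n):
        support = tuple(i for i in range(n) if mask[i])
        x = np.zeros(n)
        if support:
            sub = beta[np.ix_(support, support)]
            try:
                xs = np.linalg.solve(sub, -mu[list(support)])
            except np.linalg.LinAlgError:
                out.append(Equilibrium(x_star=x, support=support, degenerate=True))
                continue
            if np.linalg.cond(sub) > 1e12:
                out.append(Equilibrium(x_star=x, support=support, degenerate=True))
                continue
            if nonnegative_only and np.any(xs <= 0.0):
                continue  # support entries must be strictly positive
            x[list(support)] = xs
        out.append(Equilibrium(x_star=x, support=support))
    return out


def find_equilibria(
    model: ModelSpec,
    theta: np.ndarray,
    search_box: Optional[np.ndarray] = None,
    nonnegative_only: bool = True,
    n_starts: int = 50,
    dedup_tol: float = 1e-6,
    residual_tol: float = 1e-9,
    seed: int = 0,
    classify: bool = True,
) -> list:
    """Find (and classify) equilibria of the model at ``theta``.

    gLV: exact support enumeration over all ``2**N`` species subsets
    (``N <= 15``); singular interaction submatrices are recorded as
    degenerate and skipped.  Only non-negative equilibria are returned by
    default (abundances); ``nonnegative_only=False`` exposes the full set.

    General models: multistart Newton root finding from a space-filling
    sample of ``search_box`` (required), deduplicated by distance.
    """
    theta = np.asarray(theta, dtype=float)
    if model.kind == "glv":
        if model.n_x > 15:
            raise ValueError("support enumeration limited to N <= 15 species")
        cands = _glv_equilibria(model, theta, nonnegative_only)
    else:
        if search_box is None:
            raise ValueError("general models require a search_box")
        box = np.asarray(search_box, dtype=float)
        sampler = qmc.LatinHypercube(d=model.n_x, seed=seed)
        starts = box[:, 0] + sampler.random(n_starts) * (box[:, 1] - box[:, 0])
        u = model.input_at(0.0)
        fun = lambda x: np.asarray(model.rhs(x, theta, u, 0.0))
        found = []
        for x0 in starts:
            sol = root(fun, x0, method="hybr")
            if not sol.success:
                continue
            x = sol.x
            if np.any(x < box[:, 0] - 1e-9) or np.any(x > box[:, 1] + 1e-9):
                continue
            if nonnegative_only and np.any(x < -dedup_tol):
                continue
            if any(np.linalg.norm(x - e.x_star) < dedup_tol * (1 + np.linalg.norm(x))
                   for e in found):
                continue
            found.append(Equilibrium(x_star=np.where(np.abs(x) < dedup_tol, 0.0, x)))
        cands = found

    out = []
    for eq in cands:
        if eq.degenerate:
            out.append(eq)
            continue
        res = float(np.linalg.norm(
            np.asarray(model.rhs(eq.x_star, theta, model.input_at(0.0), 0.0))))
        if res > residual_tol * (1.0 + float(np.linalg.norm(eq.x_star))):
            eq.degenerate = True
            eq.residual_norm = res
            out.append(eq)
            continue
        if classify:
            eq2 = classify_equilibrium(model, theta, eq.x_star,
                                       residual_tol=max(residual_tol, 1e-8))
            eq2.support = eq.support
            out.append(eq2)
        else:
            eq.residual_norm = res
            out.append(eq)
    return out


def stability_screen(
    fit: FitResult,
    problem: EstimationProblem,
    horizon_factor: float = 3.0,
    eps_stab: float = EPS_STAB,
) -> dict:
    """Screen a converged fit for long-term dynamic plausibility.

    Combines an extended-horizon re-simulation from every experiment's
    initial state with equilibrium classification near the trajectory
    endpoints.  Verdict is ``"plausible"`` only when no trajectory diverges
    on the extended horizon; otherwise ``"locally_valid_but_unstable"``.
    """
    if not fit.converged:
        raise ValueError("stability screen requires a converged fit")
    theta, x0s = problem.split_free(fit.theta)
    model = problem.model
    evidence = {"experiments": {}, "equilibria": []}
    any_divergence = False
    for design in problem.designs:
        chk = long_horizon_check(
            model, theta, x0s[design.experiment_id], design.t_span[1],
            horizon_factor=horizon_factor, t0=design.t_span[0],
            rtol=problem.rtol, atol=problem.atol,
        )
        evidence["experiments"][design.experiment_id] = chk
        any_divergence |= not chk["stable_on_horizon"]

    if model.kind == "glv" and model.n_x <= 15:
        eqs = find_equilibria(model, theta)
        evidence["equilibria"] = [
            {"x_star": e.x_star.tolist(), "class": e.klass,
             "eigenvalues_re": np.real(e.eigenvalues).tolist()
             if e.eigenvalues is not None else None,
             "eigenvalues_im": np.imag(e.eigenvalues).tolist()
             if e.eigenvalues is not None else None}
            for e in eqs if not e.degenerate
        ]
    verdict = "plausible" if not any_divergence else "locally_valid_but_unstable"
    return {"verdict": verdict, "evidence": evidence}
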