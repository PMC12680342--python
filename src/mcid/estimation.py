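"""Parameter calibration: weighted least squares, multistart local
optimization, and enhanced scatter search (eSS).

The objective is the weighted least-squares cost

    J(theta) = sum_e sum_o sum_s [ (ym_{e,o,s} - y_{e,o}(theta, t_s)) / sigma_{e,o,s} ]^2,

the Gaussian maximum-likelihood objective when measurement standard
deviations are known.  Because large regions of parameter space produce
finite-time blow-up, every objective evaluation is guarded: a failed
integration returns a large *finite* penalty, ordered so that earlier
blow-up is worse, which keeps both local solvers and the metaheuristic
ranking well defined.

Two calibration strategies are provided:

* :func:`multistart_local` — repeated bound-constrained nonlinear
  least-squares refinement from randomized starts (the baseline that fails
  frequently on blow-up-prone models);
* :func:`ess_optimize` — enhanced scatter search, a population metaheuristic
  combining a diverse reference set, pairwise hyper-rectangle recombination,
  "go-beyond" intensification, and periodic local least-squares refinement.

Solutions are classified against the nominal-parameter objective J_nominal:
with r = log10(J / J_nominal), ``OF`` (overfit) when r < -delta, ``GF``
(good fit) when |r| <= delta, ``LO`` (local optimum / underfit) when
r > delta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model_core import ExperimentDesign, ModelSpec
from .simulator import simulate
from .synthetic_data import Dataset

__all__ = [
    "EstimationProblem", "FitResult", "FitEnsemble", "ESSSettings",
    "wls_cost", "multistart_local", "ess_optimize", "classify_fit",
    "PENALTY_BASE",
]

#: Base magnitude of the blow-up penalty; the final penalty is
#: PENALTY_BASE * (1 + fraction of sampling points not reached), so earlier
#: failure costs more and ranking among failed evaluations stays informative.
PENALTY_BASE = 1e10


# ---------------------------------------------------------------------------
# problem container
# ---------------------------------------------------------------------------

@dataclass
class EstimationProblem:
    """A calibration problem: model + designs + dataset (+ free x0 entries).

    The free-parameter vector is ``[theta, x0-entries marked "estimate"]``
    in design order; bounds are stacked accordingly.
    """

    model: ModelSpec
    designs: Sequence[ExperimentDesign]
    dataset: Dataset
    rtol: float = 1e-8
    atol: float = 1e-10
    guard_threshold: Optional[float] = 1e4

    def __post_init__(self) -> None:
        self._designs_by_id = {d.experiment_id: d for d in self.designs}
        for d in self.designs:
            d.validate_against(self.model)
        # each dataset (e, o) pair must map to a design observable
        for (e, o), _ in self.dataset.records.groupby(["experiment", "observable"]):
            if e not in self._designs_by_id:
                raise ValueError(f"dataset experiment {e!r} has no design")
            if o not in self._designs_by_id[e].observation_map.observable_names:
                raise ValueError(f"dataset observable {o!r} unknown in experiment {e!r}")
        names = list(self.model.param_names)
        lo = [self.model.bounds[:, 0]]
        hi = [self.model.bounds[:, 1]]
        self._x0_slices = {}
        pos = self.model.n_theta
        for d in self.designs:
            if d.x0_estimate:
                self._x0_slices[d.experiment_id] = (pos, pos + len(d.x0_estimate))
                pos += len(d.x0_estimate)
                names += [f"x0[{d.experiment_id}]:{self.model.state_names[i]}"
                          for i in d.x0_estimate]
                lo.append(d.x0_bounds[:, 0])
                hi.append(d.x0_bounds[:, 1])
        self.free_names = tuple(names)
        self.lower = np.concatenate(lo)
        self.upper = np.concatenate(hi)
        if not np.all(np.isfinite(self.lower)) or not np.all(np.isfinite(self.upper)):
            raise ValueError("free-parameter bounds must be finite")
        self._build_cache()

    def _build_cache(self) -> None:
        """Precompute per-design record arrays so objective evaluations are
        free of DataFrame operations."""
        self._cache = []
        for design in self.designs:
            sub = self.dataset.records[
                self.dataset.records["experiment"] == design.experiment_id
            ]
            if not len(sub):
                continue
            names = list(design.observation_map.observable_names)
            times = np.unique(sub["time"].to_numpy())
            t_idx = np.searchsorted(times, sub["time"].to_numpy())
            o_idx = np.array([names.index(o) for o in sub["observable"]])
            self._cache.append({
                "design": design,
                "times": times,
                "t_idx": t_idx,
                "o_idx": o_idx,
                "values": sub["value"].to_numpy(dtype=float),
                "sigmas": sub["sigma"].to_numpy(dtype=float),
                "rec_times": sub["time"].to_numpy(dtype=float),
            })

    @property
    def n_free(self) -> int:
        return self.lower.size

    @property
    def n_records(self) -> int:
        return len(self.dataset)

    def split_free(self, p: np.ndarray) -> tuple:
        """Split a free vector into (theta, {experiment_id: x0})."""
        p = np.asarray(p, dtype=float)
        theta = p[: self.model.n_theta]
        x0s = {}
        for d in self.designs:
            x0 = d.x0.copy()
            if d.experiment_id in self._x0_slices:
                a, b = self._x0_slices[d.experiment_id]
                x0[list(d.x0_estimate)] = p[a:b]
            x0s[d.experiment_id] = x0
        return theta, x0s

    def nominal_free(self, theta_nominal: np.ndarray) -> np.ndarray:
        """Embed nominal theta into a full free vector (x0 at design values)."""
        p = np.empty(self.n_free)
        p[: self.model.n_theta] = theta_nominal
        for d in self.designs:
            if d.experiment_id in self._x0_slices:
                a, b = self._x0_slices[d.experiment_id]
                p[a:b] = d.x0[list(d.x0_estimate)]
        return p


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _penalty_residuals(problem: EstimationProblem, frac_unreached: float) -> tuple:
    J = PENALTY_BASE * (1.0 + frac_unreached)
    n = max(problem.n_records, 1)
    return J, np.full(n, math.sqrt(J / n))


def wls_cost(problem: EstimationProblem, p: np.ndarray) -> dict:
    """Evaluate the weighted least-squares objective at a free vector.

    Returns ``{"J", "residuals", "status"}``.  Out-of-bounds points are
    clipped with a quadratic penalty added (soft bounds for line searches).
    Blow-up / solver failure yields a large finite penalty and
    ``status="blowup_abort"`` instead of raising.
    """
    p = np.asarray(p, dtype=float)
    if p.size != problem.n_free:
        raise ValueError(f"expected {problem.n_free} free parameters, got {p.size}")
    oob = np.maximum(problem.lower - p, 0) + np.maximum(p - problem.upper, 0)
    bound_pen = float(np.sum((oob / (problem.upper - problem.lower)) ** 2))
    p = np.clip(p, problem.lower, problem.upper)
    theta, x0s = problem.split_free(p)

    residuals = []
    total = reached = 0
    for entry in problem._cache:
        design = entry["design"]
        total += entry["values"].size
        traj = simulate(
            problem.model, theta, design, rtol=problem.rtol, atol=problem.atol,
            guard_threshold=problem.guard_threshold, x0=x0s[design.experiment_id],
            t_eval=entry["times"],
        )
        if not traj.ok or traj.times.size < entry["times"].size:
            reached += int((entry["rec_times"] <= traj.t_stop).sum())
            continue
        reached += entry["values"].size
        obs = design.observation_map
        Y = np.array([obs(traj.states[k], t) for k, t in enumerate(entry["times"])])
        y_rec = Y[entry["t_idx"], entry["o_idx"]]
        residuals.append((entry["values"] - y_rec) / entry["sigmas"])

    if reached < total:
        frac = 1.0 - reached / max(total, 1)
        J, res = _penalty_residuals(problem, frac)
        return {"J": J, "residuals": res, "status": "blowup_abort"}
    res = np.concatenate(residuals) if residuals else np.empty(0)
    if not np.all(np.isfinite(res)):
        J, res = _penalty_residuals(problem, 0.0)
        return {"J": J, "residuals": res, "status": "blowup_abort"}
    J = float(res @ res) * (1.0 + bound_pen)
    return {"J": J, "residuals": res, "status": "ok"}


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """One calibrated parameter vector and its bookkeeping."""

    theta: np.ndarray
    J: float
    status: str  # converged | blowup_abort | solver_failure | bound_stuck
    classification: str = "unclassified"  # OF | GF | LO | failed | unclassified
    n_obj_evals: int = 0
    seed: Optional[int] = None
    trace: list = field(default_factory=list)  # (n_evals, best J) milestones
    budget_exhausted: bool = False

    @property
    def converged(self) -> bool:
        return self.status in ("converged", "bound_stuck")


@dataclass
class FitEnsemble:
    """A collection of fits (e.g. one per multistart run) with summary fractions."""

    results: list
    delta: float = 0.25

    @property
    def summary(self) -> dict:
        n = max(len(self.results), 1)
        frac = lambda pred: sum(1 for r in self.results if pred(r)) / n
        s = {
            "n_runs": len(self.results),
            "converged": frac(lambda r: r.converged),
            "blowup": frac(lambda r: r.status == "blowup_abort"),
            "solver_failure": frac(lambda r: r.status == "solver_failure"),
        }
        for cls in ("OF", "GF", "LO"):
            s[cls] = frac(lambda r, c=cls: r.classification == c)
        s["delta"] = self.delta
        return s

    def best(self) -> FitResult:
        return min(self.results, key=lambda r: r.J)


def classify_fit(J: float, J_nominal: float, delta: float = 0.25) -> str:
    """Classify a fit by r = log10(J / J_nominal): OF / GF / LO."""
    if J_nominal <= 0:
        raise ValueError(
            "J_nominal must be positive; noise-free data has J_nominal = 0 "
            "and needs an absolute criterion instead"
        )
    r = math.log10(J / J_nominal) if J > 0 else -math.inf
    if r < -delta:
        return "OF"
    if r > delta:
        return "LO"
    return "GF"


# ---------------------------------------------------------------------------
# multistart local optimization
# ---------------------------------------------------------------------------

def _sample_starts(problem, n, rng, log_uniform=False):
    u = rng.uniform(size=(n, problem.n_free))
    lo, hi = problem.lower, problem.upper
    if not log_uniform:
        return lo + u * (hi - lo)
    # log-uniform magnitude sampling for boxes spanning decades; sign chosen
    # uniformly when the box straddles zero
    starts = np.empty_like(u)
    for k in range(problem.n_free):
        a, b = lo[k], hi[k]
        scale = max(abs(a), abs(b))
        mags = 10 ** rng.uniform(-6, 0, size=n) * scale
        signs = np.where(rng.uniform(size=n) < 0.5, -1.0, 1.0)
        starts[:, k] = np.clip(signs * mags, a, b)
    return starts


def _refine_local(problem, p0, max_nfev=None):
    """Bound-constrained least-squares refinement of the standardized
    residual vector; returns (p, J, status, n_evals)."""
    evals = [0]

    def fun(p):
        evals[0] += 1
        return wls_cost(problem, p)["residuals"]

    p0 = np.clip(p0, problem.lower, problem.upper)
    try:
        sol = least_squares(
            fun, p0, bounds=(problem.lower, problem.upper), method="trf",
            max_nfev=max_nfev, x_scale="jac",
        )
        p_hat = sol.x
    except Exception:
        return p0, wls_cost(problem, p0)["J"], "solver_failure", evals[0]
    out = wls_cost(problem, p_hat)
    if out["status"] != "ok":
        return p_hat, out["J"], "blowup_abort", evals[0]
    span = problem.upper - problem.lower
    at_bound = np.any(
        (p_hat - problem.lower < 1e-9 * span) | (problem.upper - p_hat < 1e-9 * span)
    )
    return p_hat, out["J"], ("bound_stuck" if at_bound else "converged"), evals[0]


def multistart_local(
    problem: EstimationProblem,
    n_starts: int,
    seed: int,
    J_nominal: Optional[float] = None,
    delta: float = 0.25,
    log_uniform: bool = False,
    max_nfev: Optional[int] = None,
    starts: Optional[np.ndarray] = None,
) -> FitEnsemble:
    """Multistart bound-constrained local least squares.

    Starts are drawn uniformly (optionally log-uniformly) within the bounds;
    each runs a trust-region-reflective least-squares refinement.  Failures
    (blow-up at or around the start, step collapse) are recorded in the
    ensemble, never raised.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    if starts is None:
        starts = _sample_starts(problem, n_starts, rng, log_uniform)
    results = []
    for i in range(n_starts):
        p_hat, J, status, n_ev = _refine_local(problem, starts[i], max_nfev=max_nfev)
        cls = "unclassified"
        if J_nominal is not None:
            cls = classify_fit(J, J_nominal, delta) if status in (
                "converged", "bound_stuck") else "failed"
        results.append(FitResult(theta=p_hat, J=J, status=status,
                                 classification=cls, n_obj_evals=n_ev, seed=seed))
    return FitEnsemble(results, delta=delta)


# ---------------------------------------------------------------------------
# enhanced scatter search
# ---------------------------------------------------------------------------

@dataclass
class ESSSettings:
    """eSS hyperparameters.  Defaults follow standard scatter-search practice;
    every value is surfaced in run configurations."""

    refset_size: Optional[int] = None      # b; default max(10, ceil(1+sqrt(n)))
    population: Optional[int] = None       # diverse initial population; default 10*b
    max_nfev: Optional[int] = None         # default 20000 * n_free
    local_every: int = 20                  # local refinement period (iterations)
    local_max_nfev: int = 400              # cap per local refinement
    n_stuck: int = 15                      # stale-member replacement threshold
    stall_tol: float = 1e-8                # relative improvement considered progress
    stall_iters: int = 50                  # stop after this many stalled iterations
    j_target: Optional[float] = None       # early stop when best J falls below


def ess_optimize(
    problem: EstimationProblem,
    seed: int,
    settings: Optional[ESSSettings] = None,
    J_nominal: Optional[float] = None,
    delta: float = 0.25,
) -> FitResult:
    """Enhanced scatter search with periodic local least-squares refinement.

    The reference set mixes a quality half (best objective) and a diversity
    half (maximin distance).  Pairs of reference members generate children
    uniformly inside a hyper-rectangle spanned around the better parent;
    children that improve their parent trigger "go-beyond" intensification
    along the improving direction.  Penalized (blow-up) evaluations are kept
    out of the reference set whenever finite-objective members exist.  The
    best-so-far objective is monotone non-increasing by construction.
    """
    st = settings or ESSSettings()
    n = problem.n_free
    b = st.refset_size or max(10, math.ceil(1 + math.sqrt(n)))
    b += b % 2  # even split between quality and diversity halves
    n_pop = st.population or 10 * b
    max_nfev = st.max_nfev or 20000 * n
    rng = np.random.default_rng(seed)
    lo, hi, span = problem.lower, problem.upper, problem.upper - problem.lower

    evals = [0]
    trace: list = []
    best = {"p": None, "J": math.inf}
    # Penalized (blow-up) evaluations rank strictly below every
    # finite-objective evaluation, whatever its magnitude; among penalized
    # ones the earlier blow-up still ranks worse.
    RANK_OFFSET = 1e30

    def cost(p):
        evals[0] += 1
        out = wls_cost(problem, p)
        J = out["J"] if out["status"] == "ok" else out["J"] + RANK_OFFSET
        if J < best["J"]:
            best["J"], best["p"] = J, p.copy()
            trace.append((evals[0], min(J, out["J"])))
        return J

    # --- diversification: space-filling initial population
    sampler = qmc.LatinHypercube(d=n, seed=rng)
    pop = lo + sampler.random(n_pop) * span
    pop_J = np.array([cost(p) for p in pop])
    initial_best_J = float(np.min(pop_J))

    # --- initial reference set: quality half + diversity half (maximin)
    order = np.argsort(pop_J)
    ref_idx = list(order[: b // 2])
    rest = [i for i in order[b // 2:]]
    norm = lambda p: (p - lo) / span
    while len(ref_idx) < b and rest:
        ref_pts = norm(pop[ref_idx])
        dists = [np.min(np.linalg.norm(norm(pop[i]) - ref_pts, axis=1)) for i in rest]
        pick = rest.pop(int(np.argmax(dists)))
        ref_idx.append(pick)
    ref = pop[ref_idx].copy()
    ref_J = pop_J[ref_idx].copy()
    stuck = np.zeros(b, dtype=int)
    refined = np.zeros(b, dtype=bool)

    is_penalty = lambda J: J >= RANK_OFFSET

    def try_replace(i, p_new, J_new):
        """Child replaces its parent only on improvement; penalty-valued
        children never displace finite members."""
        if J_new < ref_J[i] and not (is_penalty(J_new) and not is_penalty(ref_J[i])):
            ref[i], ref_J[i] = p_new, J_new
            stuck[i] = 0
            refined[i] = False
            return True
        return False

    iteration = 0
    stall = 0
    last_best = best["J"]
    while evals[0] < max_nfev:
        iteration += 1
        improved_any = False
        order = np.argsort(ref_J)
        for ii in range(b):
            for jj in range(ii + 1, b):
                if evals[0] >= max_nfev:
                    break
                i, j = order[ii], order[jj]  # i is the better parent
                d = (ref[j] - ref[i]) / 2.0
                c1 = np.clip(ref[i] - d, lo, hi)
                c2 = np.clip(ref[i] + d, lo, hi)
                child = c1 + rng.uniform(size=n) * (c2 - c1)
                J_child = cost(child)
                if J_child < ref_J[i]:
                    # go-beyond: keep stepping along the improving direction
                    step = child - ref[i]
                    parent, J_parent = child, J_child
                    for _ in range(3):
                        if evals[0] >= max_nfev:
                            break
                        nxt = np.clip(parent + step, lo, hi)
                        J_nxt = cost(nxt)
                        if J_nxt >= J_parent:
                            break
                        parent, J_parent = nxt, J_nxt
                        step *= 2.0
                    improved_any |= try_replace(i, parent, J_parent)
                else:
                    stuck[i] += 1
                    if try_replace(j, child, J_child):
                        improved_any = True
                    else:
                        stuck[j] += 1
            if evals[0] >= max_nfev:
                break

        # stale members are replaced from a fresh diverse pool
        for i in range(b):
            if stuck[i] >= st.n_stuck and evals[0] < max_nfev:
                p_new = lo + rng.uniform(size=n) * span
                ref[i], ref_J[i] = p_new, cost(p_new)
                stuck[i] = 0
                refined[i] = False

        # periodic local refinement of the best unrefined member
        if iteration % st.local_every == 0 and evals[0] < max_nfev:
            cands = [i for i in range(b) if not refined[i] and not is_penalty(ref_J[i])]
            if cands:
                i = min(cands, key=lambda k: ref_J[k])
                budget = min(st.local_max_nfev, max_nfev - evals[0])
                p_loc, _, _, _ = _refine_local(problem, ref[i], max_nfev=max(budget, 2))
                J_loc = cost(p_loc)
                refined[i] = True
                try_replace(i, p_loc, J_loc)

        if st.j_target is not None and best["J"] <= st.j_target:
            break
        rel = (last_best - best["J"]) / max(abs(last_best), 1e-300)
        stall = 0 if rel > st.stall_tol else stall + 1
        last_best = best["J"]
        if stall >= st.stall_iters:
            break

    # final polish of the incumbent
    if best["p"] is not None and not is_penalty(best["J"]):
        budget = min(max(max_nfev - evals[0], 50 * (n + 1)), 10 * st.local_max_nfev)
        p_loc, _, _, _ = _refine_local(problem, best["p"], max_nfev=budget)
        cost(p_loc)

    p_hat = best["p"]
    out = wls_cost(problem, p_hat)
    J_hat = out["J"]
    if out["status"] != "ok":
        status = "blowup_abort"
    else:
        at_bound = np.any((p_hat - lo < 1e-9 * span) | (hi - p_hat < 1e-9 * span))
        status = "bound_stuck" if at_bound else "converged"
    cls = "unclassified"
    if J_nominal is not None:
        cls = (classify_fit(J_hat, J_nominal, delta)
               if status in ("converged", "bound_stuck") else "failed")
    assert J_hat <= initial_best_J + 1e-12  # never worse than diversification
    return FitResult(
        theta=p_hat, J=J_hat, status=status, classification=cls,
        n_obj_evals=evals[0], seed=seed, trace=trace,
        budget_exhausted=evals[0] >= max_nfev,
    )
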