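"""Identifiability analysis: parametric sensitivities, Fisher information,
Cramér-Rao intervals, a local structural-identifiability rank test, and
sign-agreement diagnostics.

Practical identifiability (can the parameters be estimated with useful
precision from *this* dataset?) is assessed through the Fisher Information
Matrix.  For the weighted least-squares objective with known Gaussian noise,

    F = sum_records  s_rec s_rec^T / sigma_rec^2,       s_rec = dy_rec/dtheta,

whose inverse lower-bounds the covariance of unbiased estimators
(Cramér-Rao); the square roots of its diagonal give per-parameter standard
errors, and its normalized off-diagonals give the parameter correlation
matrix.  A singular or ill-conditioned FIM, wide confidence intervals, or
near-unit correlations all flag practical non-identifiability.

Structural identifiability (is estimation possible even from perfect data?)
is screened with a *local* numeric surrogate: noise-free sensitivities on a
dense sampling grid are stacked into an identifiability matrix whose
SVD rank, evaluated at several random parameter probes, decides the verdict.
Full rank is a necessary condition for global identifiability; the verdict
is explicitly local and never claims global uniqueness (differential-algebra
tools are needed for that).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import norm, t as t_dist

from .estimation import EstimationProblem
from .model_core import ExperimentDesign, ModelSpec, ObservationMap
from .simulator import simulate
from .synthetic_data import COLUMNS, Dataset

__all__ = [
    "SensitivityTensor", "FIMReport", "SIAReport",
    "compute_sensitivities", "compute_fim", "cramer_rao_intervals",
    "local_sia_rank", "sign_agreement",
]

#: SVD tolerance for numeric rank: singular values below RANK_TOL * s_max
#: count as zero.
RANK_TOL = 1e-8


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SensitivityTensor:
    """Record-aligned output sensitivities dy/dp.

    ``S[r, k]`` is the sensitivity of record ``r`` (a row of the problem's
    dataset, in its canonical sort order) with respect to free parameter
    ``k``.  Columns follow ``problem.free_names`` (model parameters first,
    then any estimated initial conditions).
    """

    S: np.ndarray
    records: pd.DataFrame
    theta_eval: np.ndarray
    method: str
    free_names: tuple

    def __post_init__(self) -> None:
        if self.S.shape[0] != len(self.records):
            raise ValueError("sensitivity rows must match dataset records")


@dataclass
class FIMReport:
    """Fisher information and derived practical-identifiability quantities."""

    fim: np.ndarray
    eval_point: np.ndarray
    eigenvalues: np.ndarray
    condition_number: float
    singular_flag: bool
    free_names: tuple = ()
    covariance: Optional[np.ndarray] = None
    correlation: Optional[np.ndarray] = None
    ci: Optional[pd.DataFrame] = None
    confidence: Optional[float] = None
    non_identifiable: list = field(default_factory=list)
    correlated_pairs: list = field(default_factory=list)


@dataclass
class SIAReport:
    """Local structural-identifiability screen for one observation scheme."""

    scheme: str
    rank: int
    n_free: int
    implicated: list                      # null-space directions (unit vectors)
    verdict: str                          # locally_identifiable | locally_non_identifiable
    probe_ranks: list = field(default_factory=list)
    free_names: tuple = ()
    singular_values: Optional[np.ndarray] = None

    @property
    def deficiency(self) -> int:
        return self.n_free - self.rank


# ---------------------------------------------------------------------------
# sensitivities
# ---------------------------------------------------------------------------

def _obs_jacobian_x(obs: ObservationMap, n_x: int, x: np.ndarray, t: float) -> np.ndarray:
    """dg/dx, analytic for linear FO/PO schemes, central FD otherwise."""
    if obs.scheme in ("FO", "PO_subset", "PO_sum"):
        return obs.matrix(n_x)
    J = np.empty((obs.n_o, n_x))
    for j in range(n_x):
        h = 1e-6 * max(abs(x[j]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (obs(xp, t) - obs(xm, t)) / (2 * h)
    return J


def _rhs_theta_jacobian(model: ModelSpec, x, theta, u, t) -> np.ndarray:
    if model.jacobian_theta is not None:
        return model.jacobian_theta(x, theta, u, t)
    J = np.empty((model.n_x, model.n_theta))
    for k in range(model.n_theta):
        h = 1e-6 * max(abs(theta[k]), 1.0)
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        J[:, k] = (np.asarray(model.rhs(x, tp, u, t)) -
                   np.asarray(model.rhs(x, tm, u, t))) / (2 * h)
    return J


def _forward_design_sens(problem: EstimationProblem, design, theta, x0,
                         x0_cols, times) -> tuple:
    """Integrate the augmented state+sensitivity system for one design.

    Returns (states at times, dstates/dp at times with p the full free
    vector).  Sensitivity dynamics: dS/dt = J_x S + dF/dtheta, with
    S(t0) = dx0/dp (identity rows on estimated initial conditions).
    """
    model = problem.model
    n_x, n_p = model.n_x, problem.n_free
    n_th = model.n_theta

    S0 = np.zeros((n_x, n_p))
    for col, state_i in x0_cols:
        S0[state_i, col] = 1.0

    def aug_rhs(t, z):
        x = z[:n_x]
        S = z[n_x:].reshape(n_x, n_p)
        u = model.input_at(t)
        Jx = (model.jacobian_x(x, theta, u, t) if model.jacobian_x is not None
              else _fd_state_jac(model, x, theta, u, t))
        Ft = np.zeros((n_x, n_p))
        Ft[:, :n_th] = _rhs_theta_jacobian(model, x, theta, u, t)
        dS = Jx @ S + Ft
        return np.concatenate([np.asarray(model.rhs(x, theta, u, t)), dS.ravel()])

    # guard against blow-up first: the augmented system inherits divergence
    # from the states and would otherwise stall the integrator
    probe = simulate(problem.model, theta, design, rtol=problem.rtol,
                     atol=problem.atol, x0=x0,
                     guard_threshold=problem.guard_threshold, t_eval=times)
    if not probe.ok:
        raise RuntimeError(
            f"simulation failed (status={probe.status}) at the sensitivity "
            f"evaluation point for experiment {design.experiment_id!r}; "
            "run stability/fit diagnostics first"
        )

    guard = probe.guard_threshold

    def guard_event(t, z):
        return guard - np.max(np.abs(z[:n_x]))

    guard_event.terminal = True
    guard_event.direction = -1

    z0 = np.concatenate([x0, S0.ravel()])
    sol = solve_ivp(aug_rhs, design.t_span, z0, method="LSODA", t_eval=times,
                    rtol=problem.rtol, atol=problem.atol, events=guard_event)
    if sol.status != 0 or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(
            f"sensitivity integration failed for experiment "
            f"{design.experiment_id!r}; check stability of the evaluation point"
        )
    X = sol.y[:n_x].T
    S = sol.y[n_x:].T.reshape(len(times), n_x, n_p)
    return X, S


def _fd_state_jac(model, x, theta, u, t):
    J = np.empty((model.n_x, model.n_x))
    for j in range(model.n_x):
        h = 1e-6 * max(abs(x[j]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (np.asarray(model.rhs(xp, theta, u, t)) -
                   np.asarray(model.rhs(xm, theta, u, t))) / (2 * h)
    return J


def _records_output(problem: EstimationProblem, p: np.ndarray) -> np.ndarray:
    """Model outputs aligned with the dataset records; raises on blow-up."""
    theta, x0s = problem.split_free(p)
    chunks = []
    for entry in problem._cache:
        design = entry["design"]
        traj = simulate(problem.model, theta, design, rtol=problem.rtol,
                        atol=problem.atol, x0=x0s[design.experiment_id],
                        t_eval=entry["times"],
                        guard_threshold=problem.guard_threshold)
        if not traj.ok:
            raise RuntimeError(
                f"simulation failed (status={traj.status}) at the sensitivity "
                f"evaluation point for experiment {design.experiment_id!r}; "
                "run stability/fit diagnostics first"
            )
        obs = design.observation_map
        Y = np.array([obs(traj.states[k], t) for k, t in enumerate(entry["times"])])
        chunks.append(Y[entry["t_idx"], entry["o_idx"]])
    return np.concatenate(chunks) if chunks else np.empty(0)


def compute_sensitivities(
    problem: EstimationProblem,
    theta_eval: np.ndarray,
    method: str = "forward_ode",
) -> SensitivityTensor:
    """Output sensitivities dy/dp at every dataset record.

    ``forward_ode`` integrates the augmented state + sensitivity ODE system
    (exact to integration tolerance); ``finite_difference`` uses central
    differences with per-parameter relative steps.  ``theta_eval`` is a free
    vector (theta plus any estimated initial conditions).
    """
    p = np.asarray(theta_eval, dtype=float)
    if p.size == problem.model.n_theta and problem.n_free != p.size:
        p = problem.nominal_free(p)
    if p.size != problem.n_free:
        raise ValueError(f"expected {problem.n_free} free parameters, got {p.size}")

    if method == "finite_difference":
        S = np.empty((problem.n_records, problem.n_free))
        for k in range(problem.n_free):
            h = 1e-5 * max(abs(p[k]), 1e-3)
            pp, pm = p.copy(), p.copy()
            pp[k] += h
            pm[k] -= h
            S[:, k] = (_records_output(problem, pp) -
                       _records_output(problem, pm)) / (2 * h)
    elif method == "forward_ode":
        theta, x0s = problem.split_free(p)
        rows = []
        for entry in problem._cache:
            design = entry["design"]
            x0_cols = []
            if design.experiment_id in problem._x0_slices:
                a, _ = problem._x0_slices[design.experiment_id]
                x0_cols = [(a + j, i) for j, i in enumerate(design.x0_estimate)]
            X, Sx = _forward_design_sens(
                problem, design, theta, x0s[design.experiment_id], x0_cols,
                entry["times"])
            obs = design.observation_map
            for r in range(entry["values"].size):
                ti, oi = entry["t_idx"][r], entry["o_idx"][r]
                G = _obs_jacobian_x(obs, problem.model.n_x, X[ti], entry["times"][ti])
                rows.append(G[oi] @ Sx[ti])
        S = np.vstack(rows) if rows else np.empty((0, problem.n_free))
    else:
        raise ValueError(f"unknown sensitivity method {method!r}")

    return SensitivityTensor(S=S, records=problem.dataset.records, theta_eval=p,
                             method=method, free_names=problem.free_names)


# ---------------------------------------------------------------------------
# Fisher information and Cramér-Rao
# ---------------------------------------------------------------------------

def compute_fim(
    S: SensitivityTensor,
    sigma: Optional[np.ndarray] = None,
    singular_tol: float = 1e-10,
) -> FIMReport:
    """Assemble the Gaussian-likelihood FIM from record sensitivities.

    ``sigma`` defaults to the dataset's recorded standard deviations.
    """
    if S.S.size == 0:
        raise ValueError("empty sensitivity tensor")
    if sigma is None:
        sigma = S.records["sigma"].to_numpy(dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape[0] != S.S.shape[0]:
        raise ValueError("sigma must have one entry per record")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    W = S.S / sigma[:, None]
    F = W.T @ W
    F = 0.5 * (F + F.T)  # enforce exact symmetry
    eig = np.sort(np.linalg.eigvalsh(F))
    lam_max = float(eig[-1]) if eig.size else 0.0
    lam_min = float(eig[0]) if eig.size else 0.0
    singular = bool(lam_max <= 0 or lam_min < singular_tol * lam_max)
    cond = math.inf if lam_min <= 0 else lam_max / lam_min
    return FIMReport(fim=F, eval_point=S.theta_eval, eigenvalues=eig,
                     condition_number=cond, singular_flag=singular,
                     free_names=S.free_names)


def cramer_rao_intervals(
    report: FIMReport,
    theta_hat: np.ndarray,
    confidence: float = 0.95,
    use_t: bool = False,
    dof: Optional[int] = None,
    rel_width_threshold: float = 1.0,
    corr_threshold: float = 0.95,
) -> FIMReport:
    """Fill Cramér-Rao confidence intervals and the correlation matrix.

    Covariance is ``inv(F)`` (Moore-Penrose pseudo-inverse with
    ``singular_flag`` set when rank-deficient).  ``half_width_k =
    q * sqrt(C_kk)`` with the Gaussian (default) or Student-t quantile.
    Parameters whose relative CI width exceeds ``rel_width_threshold``
    (100% by default) or that participate in a correlation above
    ``corr_threshold`` are reported as practically non-identifiable.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    F = report.fim
    if report.singular_flag:
        C = np.linalg.pinv(F, hermitian=True)
    else:
        C = np.linalg.inv(F)
    C = 0.5 * (C + C.T)
    if use_t:
        if dof is None or dof <= 0:
            raise ValueError("use_t requires positive dof (n_records - n_params)")
        q = float(t_dist.ppf(0.5 + confidence / 2.0, dof))
    else:
        q = float(norm.ppf(0.5 + confidence / 2.0))
    var = np.clip(np.diag(C), 0.0, None)
    half = q * np.sqrt(var)
    denom = np.where(np.abs(theta_hat) > 0, np.abs(theta_hat), np.nan)
    rel = half / denom
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = C / np.outer(sd, sd)
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)

    names = report.free_names or tuple(f"p{i}" for i in range(theta_hat.size))
    ci = pd.DataFrame({
        "parameter": names,
        "estimate": theta_hat,
        "half_width": half,
        "relative_width": rel,
    })
    non_ident = [names[k] for k in range(len(names))
                 if not np.isfinite(rel[k]) or rel[k] > rel_width_threshold]
    pairs = [(names[i], names[j], float(R[i, j]))
             for i in range(len(names)) for j in range(i + 1, len(names))
             if abs(R[i, j]) > corr_threshold]
    for a, b_, _ in pairs:
        for nm in (a, b_):
            if nm not in non_ident:
                non_ident.append(nm)

    report.covariance = C
    report.correlation = R
    report.ci = ci
    report.confidence = confidence
    report.non_identifiable = non_ident
    report.correlated_pairs = pairs
    return report


# ---------------------------------------------------------------------------
# local structural-identifiability screen
# ---------------------------------------------------------------------------

def _dense_problem(model, obs_map, design, x0_estimate) -> EstimationProblem:
    """Wrap a dense noise-free design into a unit-sigma estimation problem."""
    rows = []
    for name in obs_map.observable_names:
        for t in design.sampling_times[name]:
            rows.append((design.experiment_id, name, float(t), 0.0, 1.0))
    ds = Dataset(pd.DataFrame(rows, columns=COLUMNS))
    return EstimationProblem(model, [design], ds, guard_threshold=None)


def local_sia_rank(
    model: ModelSpec,
    obs_map: ObservationMap,
    theta_probe: np.ndarray,
    design: Optional[ExperimentDesign] = None,
    x0: Optional[np.ndarray] = None,
    t_span: tuple = (0.0, 10.0),
    estimate_x0: bool = False,
    n_probes: int = 3,
    rank_tol: float = RANK_TOL,
    seed: int = 0,
    max_retries: int = 10,
) -> SIAReport:
    """Local structural-identifiability screen via sensitivity rank.

    Noise-free output sensitivities on a dense grid (at least ``3 * n_free``
    records) are stacked into an identifiability matrix; its SVD rank at
    ``rank_tol * s_max`` decides local identifiability at that point.  The
    test is repeated at ``n_probes`` random parameter probes (resampled
    within bounds when a probe's trajectory blows up) and the verdict taken
    by majority, guarding against atypically symmetric points.  Full rank is
    necessary — not sufficient — for *global* identifiability.
    """
    theta_probe = np.asarray(theta_probe, dtype=float)
    rng = np.random.default_rng(seed)

    if design is None:
        if x0 is None:
            raise ValueError("provide either a design or an initial state x0")
        n_free_est = model.n_theta + (model.n_x if estimate_x0 else 0)
        n_times = max(int(math.ceil(3.0 * n_free_est / obs_map.n_o)) + 2, 10)
        times = np.linspace(t_span[0], t_span[1], n_times + 1)[1:]
        design = ExperimentDesign(
            experiment_id="__sia__", x0=np.asarray(x0, dtype=float),
            t_span=t_span, sampling_times=times, observation_map=obs_map,
            x0_estimate=tuple(range(model.n_x)) if estimate_x0 else (),
            x0_bounds=np.tile([0.0, 10.0], (model.n_x, 1)) if estimate_x0 else None,
        )
    problem = _dense_problem(model, obs_map, design, estimate_x0)
    n_free = problem.n_free
    n_records = problem.n_records
    if n_records < 3 * n_free:
        raise ValueError(
            f"dense design has {n_records} records; need at least {3 * n_free}"
        )

    probes = [problem.nominal_free(theta_probe)]
    lo, hi = problem.lower, problem.upper
    while len(probes) < n_probes:
        cand = None
        for _ in range(max_retries):
            trial = probes[0] * rng.uniform(0.7, 1.3, size=n_free) \
                + 0.05 * rng.standard_normal(n_free) * np.maximum(np.abs(probes[0]), 0.1)
            trial = np.clip(trial, lo, hi)
            try:
                _records_output(problem, trial)
            except RuntimeError:
                continue
            cand = trial
            break
        if cand is None:
            cand = probes[0]  # fall back to the nominal probe
        probes.append(cand)

    ranks, sv_first, null_dirs = [], None, []
    for pi, p in enumerate(probes):
        S = compute_sensitivities(problem, p, method="forward_ode").S
        # scale columns by the probe magnitude so rank is invariant to
        # parameter (and time) units; zero parameters keep unit scale
        scale = np.where(np.abs(p) > 1e-12, np.abs(p), 1.0)
        M = S * scale[None, :]
        sv = np.linalg.svd(M, compute_uv=False)
        r = int(np.sum(sv > rank_tol * sv[0])) if sv.size and sv[0] > 0 else 0
        ranks.append(r)
        if pi == 0:
            sv_first = sv
            if r < n_free:
                _, _, Vt = np.linalg.svd(M)
                null_dirs = [Vt[k] for k in range(r, n_free)]

    votes_ident = sum(1 for r in ranks if r == n_free)
    verdict = ("locally_identifiable" if votes_ident > len(ranks) / 2
               else "locally_non_identifiable")
    rank_major = max(set(ranks), key=ranks.count)
    return SIAReport(scheme=obs_map.scheme, rank=rank_major, n_free=n_free,
                     implicated=null_dirs, verdict=verdict, probe_ranks=ranks,
                     free_names=problem.free_names, singular_values=sv_first)


# ---------------------------------------------------------------------------
# sign agreement
# ---------------------------------------------------------------------------

def sign_agreement(
    theta_hat: np.ndarray,
    theta_nominal: np.ndarray,
    mask: Optional[Sequence[bool]] = None,
    zero_band: float = 1e-8,
    names: Optional[Sequence[str]] = None,
) -> tuple:
    """Fraction of parameters whose estimated sign matches the nominal sign.

    Interaction-coefficient sign errors misrepresent the underlying ecology
    (e.g. competition reported as facilitation), so this is the headline
    mechanistic-recovery diagnostic on synthetic benchmarks.  Nominal zeros
    count as agreeing when the estimate lies within ``zero_band``.

    Returns ``(fraction, table)`` with a per-parameter DataFrame.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    theta_nominal = np.asarray(theta_nominal, dtype=float)
    if theta_hat.shape != theta_nominal.shape:
        raise ValueError("estimate and nominal vectors must have equal length")
    if mask is None:
        mask = np.ones(theta_hat.size, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != theta_hat.shape:
        raise ValueError("mask must match the parameter vector length")
    agree = np.where(
        np.abs(theta_nominal) <= zero_band,
        np.abs(theta_hat) <= zero_band,
        np.sign(theta_hat) == np.sign(theta_nominal),
    )
    idx = np.flatnonzero(mask)
    frac = float(np.mean(agree[idx])) if idx.size else float("nan")
    table = pd.DataFrame({
        "parameter": [
            (names[i] if names is not None else f"p{i}") for i in idx
        ],
        "nominal": theta_nominal[idx],
        "estimate": theta_hat[idx],
        "agree": agree[idx],
    })
    return frac, table
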