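"""Core model representations for microbial-community ODE systems.

A community model is an autonomous (or input-driven) ODE system

    dx/dt = f(x, theta, u, t),        y = g(x, t),

where ``x`` holds species abundances (or other states), ``theta`` the model
parameters constrained to a box ``theta_min <= theta <= theta_max``, ``u`` an
optional exogenous input, and ``g`` the observation map connecting states to
what an experiment actually measures.

The workhorse is the dense generalized Lotka-Volterra (gLV) system

    dx_i/dt = x_i * (mu_i + sum_j beta_ij x_j),

with per-species intrinsic growth rates ``mu_i`` and a full N x N interaction
matrix ``beta``, giving ``n_theta = N + N**2`` parameters.  The parameter
vector layout is fixed throughout the package:

    [mu_1, ..., mu_N, beta_11, beta_12, ..., beta_1N, beta_21, ..., beta_NN]

i.e. growth rates first, then the interaction matrix in row-major order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "ModelSpec",
    "ObservationMap",
    "ExperimentDesign",
    "build_glv",
    "make_observation_map",
    "evaluate_rhs",
    "glv_unpack",
    "glv_pack",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """An ODE community model with parameter box and optional analytics.

    Parameters
    ----------
    n_x
        Number of state variables.
    state_names
        Unique labels, length ``n_x``.
    rhs
        Deterministic map ``(x, theta, u, t) -> dx/dt`` of dimension ``n_x``.
    param_names
        Unique labels, length ``n_theta``.
    bounds
        Array of shape ``(n_theta, 2)`` with finite ``theta_min < theta_max``.
    jacobian_x
        Optional analytic state Jacobian ``(x, theta, u, t) -> (n_x, n_x)``.
    jacobian_theta
        Optional analytic parameter Jacobian ``(x, theta, u, t) ->
        (n_x, n_theta)``; used by forward sensitivity integration.
    input_profile
        Optional map ``t -> u``; ``None`` means autonomous dynamics.
    kind
        ``"glv"`` for dense generalized Lotka-Volterra, else ``"general"``.
    """

    n_x: int
    state_names: Sequence[str]
    rhs: Callable[[np.ndarray, np.ndarray, Optional[np.ndarray], float], np.ndarray]
    param_names: Sequence[str]
    bounds: np.ndarray
    jacobian_x: Optional[Callable] = None
    jacobian_theta: Optional[Callable] = None
    input_profile: Optional[Callable[[float], np.ndarray]] = None
    kind: str = "general"

    def __post_init__(self) -> None:
        if self.n_x < 1:
            raise ValueError("n_x must be a positive integer")
        if len(self.state_names) != self.n_x:
            raise ValueError("state_names length must equal n_x")
        if len(set(self.state_names)) != self.n_x:
            raise ValueError("state_names must be unique")
        if len(set(self.param_names)) != len(self.param_names):
            raise ValueError("param_names must be unique")
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.bounds.shape != (self.n_theta, 2):
            raise ValueError(
                f"bounds must have shape ({self.n_theta}, 2), got {self.bounds.shape}"
            )
        if not np.all(np.isfinite(self.bounds)):
            raise ValueError("bounds must be finite")
        if not np.all(self.bounds[:, 0] < self.bounds[:, 1]):
            raise ValueError("each lower bound must be strictly below its upper bound")
        if self.kind == "glv":
            n = self.n_x
            if self.n_theta != n + n * n:
                raise ValueError("gLV models require n_theta = N + N**2")

    @property
    def n_theta(self) -> int:
        return len(self.param_names)

    def input_at(self, t: float) -> Optional[np.ndarray]:
        return None if self.input_profile is None else self.input_profile(t)


@dataclass
class ObservationMap:
    """Map from model states to experimental observables, ``y = g(x, t)``.

    Schemes: ``FO`` (fully observed, identity), ``PO_subset`` (a subset of
    states is measured individually), ``PO_sum`` (a single aggregate such as
    total biomass), or ``custom`` (arbitrary ``g``).
    """

    n_o: int
    g: Callable[[np.ndarray, float], np.ndarray]
    scheme: str = "custom"
    indices: Optional[tuple] = None
    observable_names: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_o < 1:
            raise ValueError("n_o must be a positive integer")
        if not self.observable_names:
            self.observable_names = tuple(f"y{i + 1}" for i in range(self.n_o))
        if len(self.observable_names) != self.n_o:
            raise ValueError("observable_names length must equal n_o")

    def __call__(self, x: np.ndarray, t: float = 0.0) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.g(x, t), dtype=float))

    def matrix(self, n_x: int) -> np.ndarray:
        """Linear observation matrix C with y = C x (FO/PO schemes only)."""
        if self.scheme == "FO":
            return np.eye(n_x)
        if self.scheme == "PO_subset":
            C = np.zeros((self.n_o, n_x))
            for row, idx in enumerate(self.indices):
                C[row, idx] = 1.0
            return C
        if self.scheme == "PO_sum":
            C = np.zeros((1, n_x))
            C[0, list(self.indices)] = 1.0
            return C
        raise ValueError(f"scheme {self.scheme!r} has no linear matrix form")


@dataclass
class ExperimentDesign:
    """One experiment: initial condition, time window and sampling schedule.

    ``x0`` entries are fixed numbers; states listed in ``x0_estimate`` are
    instead treated as unknowns to be estimated, within ``x0_bounds``.
    ``sampling_times`` maps each observable name to its (sorted) sampling
    grid; passing a single array applies the same grid to every observable.
    """

    experiment_id: str
    x0: np.ndarray
    t_span: tuple
    sampling_times: dict
    observation_map: ObservationMap
    x0_estimate: tuple = ()
    x0_bounds: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=float)
        t0, tf = float(self.t_span[0]), float(self.t_span[1])
        if not t0 < tf:
            raise ValueError("t_span must satisfy t0 < tf")
        self.t_span = (t0, tf)
        if isinstance(self.sampling_times, (list, np.ndarray)):
            grid = np.asarray(self.sampling_times, dtype=float)
            self.sampling_times = {
                name: grid.copy() for name in self.observation_map.observable_names
            }
        clean = {}
        for name, times in self.sampling_times.items():
            if name not in self.observation_map.observable_names:
                raise ValueError(f"unknown observable {name!r} in sampling_times")
            times = np.asarray(times, dtype=float)
            if np.any(np.diff(times) <= 0):
                raise ValueError(f"sampling times for {name!r} must be strictly sorted")
            if times.size and (times[0] < t0 or times[-1] > tf):
                raise ValueError(f"sampling times for {name!r} must lie within t_span")
            clean[name] = times
        self.sampling_times = clean
        if self.x0_estimate:
            bad = [i for i in self.x0_estimate if not 0 <= i < self.x0.size]
            if bad:
                raise ValueError(f"x0_estimate indices out of range: {bad}")
            if self.x0_bounds is None:
                raise ValueError("x0_bounds required when x0 entries are estimated")
            self.x0_bounds = np.asarray(self.x0_bounds, dtype=float)
            if self.x0_bounds.shape != (len(self.x0_estimate), 2):
                raise ValueError("x0_bounds must have one (lo, hi) row per estimated state")

    @property
    def all_times(self) -> np.ndarray:
        """Union of all sampling grids, sorted."""
        if not self.sampling_times:
            return np.empty(0)
        return np.unique(np.concatenate(list(self.sampling_times.values())))

    def validate_against(self, model: ModelSpec) -> None:
        if self.x0.size != model.n_x:
            raise ValueError(
                f"x0 has length {self.x0.size} but model has {model.n_x} states"
            )


# ---------------------------------------------------------------------------
# gLV construction
# ---------------------------------------------------------------------------

def glv_pack(mu: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Pack (mu, beta) into the canonical flat parameter vector."""
    mu = np.asarray(mu, dtype=float)
    beta = np.asarray(beta, dtype=float)
    return np.concatenate([mu, beta.ravel(order="C")])


def glv_unpack(theta: np.ndarray, n: int) -> tuple:
    """Split a flat gLV parameter vector into (mu, beta)."""
    theta = np.asarray(theta, dtype=float)
    if theta.size != n + n * n:
        raise ValueError(f"expected {n + n * n} parameters for N={n}, got {theta.size}")
    return theta[:n], theta[n:].reshape(n, n)


def _default_glv_bounds(mu: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Default parameter box: growth rates in [0, max(3, 2|mu|)], interactions
    in a symmetric box at max(5, 2|beta|)."""
    n = mu.size
    mu_hi = max(3.0, 2.0 * float(np.max(np.abs(mu))) if mu.size else 3.0)
    b_hi = max(5.0, 2.0 * float(np.max(np.abs(beta))) if beta.size else 5.0)
    lo = np.concatenate([np.zeros(n), -b_hi * np.ones(n * n)])
    hi = np.concatenate([mu_hi * np.ones(n), b_hi * np.ones(n * n)])
    return np.column_stack([lo, hi])


def build_glv(
    growth_rates: np.ndarray,
    interaction_matrix: np.ndarray,
    bounds_policy=None,
    state_names: Optional[Sequence[str]] = None,
) -> ModelSpec:
    """Construct a dense gLV :class:`ModelSpec` with analytic Jacobians.

    Parameters
    ----------
    growth_rates
        Nominal intrinsic growth rates ``mu``, length N (used only to size
        the default bounds; the model itself is parametric).
    interaction_matrix
        Nominal N x N interaction matrix ``beta``.
    bounds_policy
        ``None`` for the default box, an ``(n_theta, 2)`` array, or a callable
        ``(mu, beta) -> (n_theta, 2)``.
    """
    mu = np.asarray(growth_rates, dtype=float)
    beta = np.asarray(interaction_matrix, dtype=float)
    if mu.ndim != 1:
        raise ValueError("growth_rates must be a vector")
    n = mu.size
    if n < 1:
        raise ValueError("at least one species is required")
    if beta.shape != (n, n):
        raise ValueError(f"interaction_matrix must be {n}x{n}, got {beta.shape}")
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(beta))):
        raise ValueError("growth rates and interactions must be finite")

    if bounds_policy is None:
        bounds = _default_glv_bounds(mu, beta)
    elif callable(bounds_policy):
        bounds = np.asarray(bounds_policy(mu, beta), dtype=float)
    else:
        bounds = np.asarray(bounds_policy, dtype=float)

    state_names = tuple(state_names) if state_names else tuple(f"x{i + 1}" for i in range(n))
    param_names = tuple(f"mu_{i + 1}" for i in range(n)) + tuple(
        f"beta_{i + 1}_{j + 1}" for i in range(n) for j in range(n)
    )

    def rhs(x, theta, u, t):
        m, b = theta[:n], theta[n:].reshape(n, n)
        return x * (m + b @ x)

    def jac_x(x, theta, u, t):
        m, b = theta[:n], theta[n:].reshape(n, n)
        # d/dx_j [x_i (mu_i + sum_k b_ik x_k)] = delta_ij (mu_i + b_i.x) + x_i b_ij
        return np.diag(m + b @ x) + x[:, None] * b

    def jac_theta(x, theta, u, t):
        b = theta[n:].reshape(n, n)
        J = np.zeros((n, n + n * n))
        J[np.arange(n), np.arange(n)] = x  # d f_i / d mu_i = x_i
        for i in range(n):
            # d f_i / d beta_ij = x_i * x_j
            J[i, n + i * n : n + (i + 1) * n] = x[i] * x
        return J

    return ModelSpec(
        n_x=n,
        state_names=state_names,
        rhs=rhs,
        param_names=param_names,
        bounds=bounds,
        jacobian_x=jac_x,
        jacobian_theta=jac_theta,
        kind="glv",
    )


# ---------------------------------------------------------------------------
# observation maps
# ---------------------------------------------------------------------------

def make_observation_map(
    scheme: str,
    n_x: int,
    indices: Optional[Sequence[int]] = None,
    state_names: Optional[Sequence[str]] = None,
) -> ObservationMap:
    """Build a standard observation map.

    ``FO``: identity (every state measured); ``PO_subset``: the listed state
    indices measured individually; ``PO_sum``: a single aggregate observable
    equal to the sum of the listed states (e.g. total biomass).
    """
    names = tuple(state_names) if state_names else tuple(f"x{i + 1}" for i in range(n_x))
    if scheme == "FO":
        return ObservationMap(
            n_o=n_x, g=lambda x, t: np.asarray(x, dtype=float), scheme="FO",
            observable_names=names,
        )
    if scheme in ("PO_subset", "PO_sum"):
        if not indices:
            raise ValueError(f"{scheme} requires a non-empty index list")
        idx = tuple(int(i) for i in indices)
        bad = [i for i in idx if not 0 <= i < n_x]
        if bad:
            raise IndexError(f"observation indices out of range for n_x={n_x}: {bad}")
        if scheme == "PO_subset":
            return ObservationMap(
                n_o=len(idx), g=lambda x, t: np.asarray(x, dtype=float)[list(idx)],
                scheme="PO_subset", indices=idx,
                observable_names=tuple(names[i] for i in idx),
            )
        return ObservationMap(
            n_o=1, g=lambda x, t: np.atleast_1d(np.sum(np.asarray(x, dtype=float)[list(idx)])),
            scheme="PO_sum", indices=idx, observable_names=("total",),
        )
    raise ValueError(f"unknown observation scheme {scheme!r}")


def evaluate_rhs(
    model: ModelSpec,
    x: np.ndarray,
    theta: np.ndarray,
    u: Optional[np.ndarray] = None,
    t: float = 0.0,
) -> np.ndarray:
    """Evaluate dx/dt with dimension and finiteness checks."""
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if x.size != model.n_x:
        raise ValueError(f"state has length {x.size}, model expects {model.n_x}")
    if theta.size != model.n_theta:
        raise ValueError(
            f"parameter vector has length {theta.size}, model expects {model.n_theta}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("state vector contains non-finite entries")
    if not np.all(np.isfinite(theta)):
        raise ValueError("parameter vector contains non-finite entries")
    dx = np.asarray(model.rhs(x, theta, u, t), dtype=float)
    if dx.shape != (model.n_x,):
        raise ValueError("rhs returned a vector of the wrong dimension")
    return dx
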