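# Methods

`mcid` implements a three-phase identification workflow for nonlinear ODE
models of microbial communities: identifiability screening before
estimation, robust calibration with post-fit practical-identifiability and
stability analysis, and predictive-power assessment. This note documents
the models, algorithms, defaults, and the design choices made where more
than one reasonable option existed.

## Models and observation

A community model is an autonomous ODE system `dx/dt = f(x, θ, u, t)` with
observation map `y = g(x, t)` and parameters constrained to a finite box
`θmin ≤ θ ≤ θmax`. All quantities are dimensionless with time in arbitrary
units; the plausibility checker is the only place unit-aware ranges appear
(e.g. growth rates quoted per hour).

The central instance is the dense generalized Lotka–Volterra (gLV) system

```
dx_i/dt = x_i (μ_i + Σ_j β_ij x_j),       i = 1..N,
```

with per-species intrinsic growth rates `μ_i` and a full interaction matrix
`β` (β_ij > 0: facilitation of species i by j; β_ij < 0: competition or
inhibition; β_ii < 0: self-limitation). The parameter count is
`nθ = N + N²` — 6, 12 and 156 for N = 2, 3, 12 — which is what makes dense
community models data-hungry and identifiability-fragile. The parameter
vector layout is fixed package-wide: `[μ_1..μ_N, β_11, β_12, …, β_NN]`
(interaction matrix row-major). Initial conditions can optionally be
declared estimable per experiment; they are appended to the free-parameter
vector after θ.

Observation schemes: `FO` (every state measured), `PO_subset` (a subset of
states), `PO_sum` (a single aggregate such as total biomass), or custom
maps. FO/PO maps are linear, which the sensitivity machinery exploits.

## Simulation under blow-up

gLV systems exhibit finite-time blow-up on large parts of any symmetric
interaction box (any positive feedback loop `x_i β_ii x_i` grows
super-exponentially). The simulator therefore never lets the integrator
fail: a terminal event on `max_i |x_i| − G` stops integration at a defined
time `t_stop` that upper-bounds the true blow-up time, and step-size
collapse is mapped to a `solver_failure` status. Defaults: LSODA with
`rtol = 1e-8`, `atol = 1e-10` (tight, because Fisher-information
sensitivities and the weighted objective inherit integration error), guard
`G = 1e6` in units of the largest initial-state magnitude. The analytic
state Jacobian of gLV models is supplied to the integrator. Event-based
detection makes the detected stopping time converge to the analytic blow-up
time as the guard grows (verified against `x' = x²`, whose solution
`x(t) = x0/(1 − x0 t)` diverges at `t = 1/x0`).

## Calibration objective

With known measurement standard deviations the maximum-likelihood objective
is the weighted least-squares cost

```
J(θ) = Σ_e Σ_o Σ_s [ (ym_{e,o,s} − y_{e,o}(θ, t_s)) / σ_{e,o,s} ]²
```

summed over experiments, observables and sampling times. At the generating
parameters J is a χ² variable with one unit-variance term per record, so
`E[J(θ_true)] ≈ n_records` — the calibration target scale.

Failed integrations receive the finite penalty
`J_pen = 1e10 · (1 + fraction of sampling points not reached)`: earlier
blow-up costs more, so ranking among infeasible points remains informative.
Because a legitimate finite objective can exceed `1e10` when σ floors are
tiny (noise-free data), the scatter-search ranking additionally orders any
penalized evaluation strictly below any finite-objective evaluation;
penalized candidates never displace finite ones in the reference set.

## Optimizers

**Multistart local least squares** (the baseline): starts drawn uniformly
(optionally log-uniformly) in the box, each refined by bound-constrained
trust-region-reflective least squares on the standardized residual vector.
A start inside a blow-up region sees a locally flat penalty and terminates
immediately; the run is recorded with status `blowup_abort`. `bound_stuck`
flags solutions pinned to the box. Benchmark runs cap each start at 200
objective evaluations.

**Enhanced scatter search (eSS)**: a population metaheuristic
combining

* a Latin-hypercube diversification population (default `10·b` points);
* a reference set of size `b = max(10, ⌈1 + √nθ⌉)` (rounded even), half
  selected by objective quality, half by maximin distance in the unit box;
* pairwise hyper-rectangle recombination: for parents `x_i` (better) and
  `x_j`, a child is drawn uniformly in the box spanned by
  `x_i ± (x_j − x_i)/2`, clipped to bounds;
* "go-beyond" intensification: a child improving its parent keeps stepping
  along the improving direction with doubling step length while improvement
  continues;
* stale-member replacement after 15 non-improving combinations;
* periodic local least-squares refinement (default every 20 iterations;
  benchmark configurations use 3–8) of the best unrefined member, plus a
  final polish of the incumbent;
* stopping on an objective-evaluation budget (default `2·10⁴·nθ`;
  benchmarks use 1.5k–6k), a stagnation rule (relative improvement below
  `1e-8` for 50 iterations), or an optional objective target.

The best-so-far objective is monotone non-increasing by construction and
never worse than the best diversification point.

**Fit classification.** Given the objective `J_nom` at the nominal
(generating) parameters, `r = log10(J/J_nom)` classifies a converged fit as
overfit (`OF`, r < −δ), good fit (`GF`, |r| ≤ δ) or local optimum /
underfit (`LO`, r > δ), with δ = 0.25 by default (reported with every
ensemble summary). The ratio rule needs `J_nom > 0`; noise-free studies
use absolute criteria instead (`J < 1e-6 · n_records`).

## Practical identifiability

Output sensitivities `S = ∂y/∂θ` at every record are computed either by
integrating the forward sensitivity system
`dS/dt = J_x S + ∂f/∂θ, S(t0) = ∂x0/∂θ` (identity rows on estimated
initial conditions) together with the states, or by central finite
differences with per-parameter relative steps; the two agree to ~1e-6
relative on the gLV fixtures. The Gaussian-likelihood Fisher Information
Matrix is `F = Σ_rec s_rec s_recᵀ / σ_rec²`. Eigenvalues, condition
number, and a singularity flag (`λmin < 1e-10 · λmax`) summarize the
information geometry. The Cramér–Rao bound `C ≥ F⁻¹` (Moore–Penrose
pseudo-inverse when flagged singular) yields per-parameter half-widths
`q·√C_kk` with a Gaussian quantile by default (Student-t with
`dof = n_records − nθ` on request) and the correlation matrix
`R_ij = C_ij/√(C_ii C_jj)`. Reporting conventions (configurable, not
statistics): a parameter is listed practically non-identifiable when its
relative CI width exceeds 100% or it participates in a correlation with
|R| > 0.95. The FIM is evaluated at the estimate by default (the usual
observed-information practice); synthetic studies may evaluate at the
nominal parameters instead.

## Local structural-identifiability screen

Full structural identifiability analysis requires differential-algebra
machinery; this package provides the standard numeric surrogate: noise-free
sensitivities on a dense grid (≥ 3 records per free parameter) are stacked
into an identifiability matrix, columns scaled by the probe magnitude so
the rank is invariant to parameter and time units, and the SVD rank taken
with tolerance `1e-8 · s_max`. The test is repeated at 3 random probes
(resampled within bounds when a probe's trajectory blows up) with a
majority verdict, guarding against atypically symmetric points. Null-space
directions are reported with the parameters they implicate.

The verdict is strictly *local*: full rank is necessary but not sufficient
for global identifiability. The distinction is real in practice — on the
two-species gLV with only total biomass measured, the output is invariant
under the species permutation (a discrete symmetry), so the model is
globally non-identifiable while every generic point is locally
identifiable; the screen correctly passes locally and the gap is
documented in its report. Genuine continuous deficiencies (exact zero
singular values) appear for single-species observation with unknown
initial conditions and for aggregate observation of two or more species in
a larger community, and the screen flags those as rank deficient.

## Stability analysis

For gLV models equilibria are enumerated exactly: each support (subset of
surviving species) contributes at most one equilibrium, the solution of
`β_ss x_s = −μ_s` on the support (supports with singular or
ill-conditioned submatrices are recorded as degenerate); the interior
equilibrium, when it exists, is `−β⁻¹μ`. Only non-negative equilibria are
reported by default (abundances), with a flag for the full set.
Enumeration is limited to N ≤ 15; general models use multistart Newton
root-finding inside a user-supplied box with distance-based deduplication.

Classification follows the eigenvalues of the Jacobian at the equilibrium:
all real parts negative → asymptotically stable (node or spiral by
imaginary parts); at least one positive → unstable (saddle when signs mix);
all non-positive with some zero (|Re λ| < ε_stab = 1e-8) → neutrally
stable, flagged for simulation-based follow-up since linearization is
inconclusive there (e.g. the classic predator–prey center).

The **stability screen** re-simulates every experiment from its initial
state on an extended horizon (default 3× the data window) and classifies
equilibria near trajectory endpoints. A fit is `plausible` only when no
trajectory diverges on the extended horizon; otherwise it is
`locally_valid_but_unstable` — the failure mode where a parameter set fits
the data window yet diverges shortly beyond it.

## Predictive power

Standardized in-sample residuals of a well-specified fit should be white
noise. Diagnostics (each a pass/fail flag with documented thresholds):
mean test `|r̄·√n| < 2` (known unit variance under the model), per-series
lag-1 autocorrelation `|ρ₁| < 2/√n`, first/second-half variance ratio in
[0.5, 2], and the Q-Q correlation between sorted residuals and standard
normal quantiles (> 0.95). The Q-Q overfitting indicator is an explicit
stand-in convention: residual variance materially below one (< 0.5) with
high normality suggests the fit has absorbed measurement noise. Groups
with fewer than 8 residuals are reported not-computed, never guessed.

Cross-validation refits on training experiments (scatter search) and
scores held-out experiments by RMSE and NRMSE = RMSE / (max − min) of the
observed validation series per observable (range normalization; a
mean-normalized variant is available; zero-range series are flagged
undefined). Overall metrics are record-count-weighted means. Default fold
plan: leave-one-experiment-out. Diverged predictions are scored against
the guard magnitude, which yields large finite errors rather than NaNs.

Mechanistic plausibility rules (range, sign, and comparative rules such as
mortality < growth) screen named estimates; the stock example is that
bacterial maximum specific growth rates should be positive and of order
0.1–2 per hour.

## Synthetic data generator

The generator emulates pseudo-experimental benchmark datasets: trajectories
of a fixture model at nominal parameters, sampled on the design grids and
corrupted with Gaussian noise — absolute, proportional to the *noise-free*
signal (keeping the stored σ consistent with the generating process), or
mixed — at levels such as 0/5/10%. σ is floored at `1e-6 · max|y|` so
extinction points never get infinite weight. Negative noisy abundances are
kept by default (truncation at zero would bias the Gaussian error model; a
config switch enables it). Standardized residuals of generated data are
exact Gaussians by construction, so the generator calibrates the residual
diagnostics. What it does not emulate: non-Gaussian or autocorrelated
measurement error, dropout/missingness, relative-abundance
(compositional) measurements, and model misspecification — passing tests
on synthetic data bound what can be claimed about real communities.

## Case-study fixtures

Nominal parameter values are synthetic stand-ins chosen once to be
ecologically plausible, not transcriptions of published communities:

* `glv2` — two species, μ = (1.0, 0.9); coexistence subcase (intraspecific
  competition dominant, stable interior equilibrium at −β⁻¹μ) and
  competition subcase (interspecific dominant, bistable exclusion). Two
  experiments with different initial conditions, 15 samples on [0, 10].
* `glv3` — three species with mixed competition/facilitation and rates
  2–3, sampled 12 times on the short window [0, 2]; bounded at the
  nominal point but blow-up-prone over most of its symmetric box
  (μ ∈ [0, 6], β ∈ [−6, 6]) — the robustness benchmark.
* `mglv` — N species (default 12, `nθ = 156`) generated from a fixed seed:
  μ ~ U(0.3, 1.0), β_ii ~ −U(0.8, 1.6), β_ij ~ N(0, 0.15); diagonal
  dominance keeps the nominal community bounded. `mglv(5)` is the
  reduced-scale variant (30 parameters) used in benchmarks.

## Benchmark study conditions and problem sizes

The reproduction benchmarks fix these conditions (chosen a priori, stated
here as the package's own design):

* Multistart robustness: `glv3`, one training experiment with the three
  initial conditions estimated alongside the 12 parameters (unknown-x0
  scenario; bounds [0.01, 3]), 10% proportional noise, 200 uniform starts,
  200-evaluation budget per start. Typical
  outcome: ~20–25% of starts converge, ~6% reach the good-fit band, and
  ~75–80% terminate in blow-up — local optimization is structurally
  inadequate here.
* Scatter-search good-fit rate: both experiments per fixture at 10% noise;
  3 runs each on `glv2`/`glv3` (2.5k/3.5k evaluation budgets) and 2 runs
  on `mglv(5)` (6k budget).
* Noise-free recovery: `glv2`, 10 optimizer seeds, 1.5k evaluations each;
  success = every parameter within 1% relative (in practice recovery is
  exact to machine precision once the global basin is found).
* Cramér–Rao coverage: `glv2` at 5% noise, 50 replicate datasets; each
  replicate refit locally from a mildly perturbed nominal start (the
  estimator's own basin), FIM at the estimate, pooled per-parameter 95%
  coverage compared with the nominal rate.
* Predictive-power ordering: `glv3`, 10 repetitions; per repetition a
  25-start multistart plus one scatter search on fresh single-experiment
  training data (unknown-x0 scenario, which provides the overfit capacity
  that makes noise-chasing solutions possible), validated by simulating
  fitted parameters at the held-out experiment (different initial
  conditions) against its own noisy data. Class representatives per
  repetition: the best-objective OF solution (overfits are
  characteristically unstable, so they are taken unscreened) versus the
  best-objective GF solution that passes a stability screen covering every
  study-design initial condition.

These sizes keep a full benchmark sweep in the tens of minutes on one CPU;
they are scaled-down but condition-faithful versions of a full 200-run
sweep at every cell.

## Numerical choices

* Integration: LSODA; `rtol 1e-8 / atol 1e-10` for oracles, data
  generation and default estimation (generator and objective must share
  tolerances for noise-free objectives to vanish exactly); `1e-7 / 1e-9`
  (gLV2/3 benchmarks) and `1e-6 / 1e-8` (mglv benchmarks) for repeated
  fitting, where measurement noise dominates integration error.
* Blow-up guard during estimation: `1e4` (abundances are O(1); a tighter
  guard aborts hopeless integrations sooner without affecting feasible
  ones).
* Equilibrium residual tolerance `1e-9·(1 + |x*|)`; support submatrices
  with condition number above 1e12 are treated as degenerate.
* SVD rank tolerance `1e-8 · s_max`; ε_stab `1e-8`; FIM singularity
  tolerance `1e-10 · λmax`.
* Ties and degenerate inputs: zero nominal parameters compare signs within
  a dead band of `1e-8`; zero-range validation series leave NRMSE
  undefined and flagged; datasets sort canonically by (experiment,
  observable, time) so every result is invariant to input record order.
* Determinism: a single master seed fans out via `SeedSequence.spawn` to
  every stochastic component; identical configuration + seed reproduces
  byte-identical result files.

## Known limitations

* The structural-identifiability screen is local; globally-ambiguous but
  locally-identifiable schemes (discrete symmetries) pass it by design and
  are only visible through its conditioning report.
* The Cramér–Rao intervals are asymptotic and local; they are reliable
  near an interior, well-conditioned optimum and degrade under strong
  nonlinearity or active bounds (bootstrap alternatives are out of scope).
* Blow-up detection bounds the blow-up time from below by the guard
  crossing; it does not estimate the true divergence time beyond that.
* The Q-Q overfitting indicator is a documented convention, not a testable
  statistic with known size/power.
* Equilibrium enumeration covers gLV with N ≤ 15; general models rely on
  multistart root-finding, which offers no completeness guarantee.
* Cross-validation refits with the scatter search at benchmark budgets;
  with very tight budgets the per-fold fits may be undertrained, which
  inflates validation error uniformly rather than biasing the OF/GF
  comparison.
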