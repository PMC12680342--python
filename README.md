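# mcid — identification of microbial-community ODE models

Dynamic models of microbial communities — above all the generalized
Lotka–Volterra (gLV) family

    dx_i/dt = x_i (mu_i + sum_j beta_ij x_j)

with growth rates `mu_i` and a dense interaction matrix `beta_ij` — are
popular and treacherous. Their parameter count grows as `N + N²` with the
number of species; their calibration landscape is non-convex and riddled
with finite-time blow-up (trajectories reaching infinity in finite time);
estimated interaction signs routinely misrepresent the underlying ecology;
and a model that fits its training window can be useless one window later.

`mcid` is a library and CLI for modelers who want to calibrate such models
*and know whether the result means anything*. It implements a three-phase
workflow:

1. **Pre-estimation screening** — a local structural-identifiability test:
   noise-free output sensitivities on a dense grid, stacked and ranked by
   SVD at several random parameter probes. Catches observation schemes
   (total biomass, single species, unknown initial conditions) from which
   parameters cannot be estimated even in principle, before any fitting.
2. **Robust calibration** — weighted least squares
   `J(θ) = Σ [(ym − y(θ))/σ]²` minimized by either multistart local least
   squares (the baseline, which fails on most starts for blow-up-prone
   models) or an enhanced scatter search (eSS) metaheuristic that treats
   failed integrations as ordered finite penalties. Followed by practical
   identifiability (Fisher information, Cramér–Rao intervals
   `C ≥ F⁻¹`, parameter correlations) and a stability screen that flags
   fits that are locally valid but globally unstable (equilibria via
   support enumeration, Jacobian eigenvalue classification, extended-
   horizon re-simulation).
3. **Predictive power** — residual white-noise diagnostics with a Q-Q
   based overfitting indicator, leave-experiment-out cross-validation
   scored by range-normalized RMSE, and mechanistic plausibility rules
   (signs, ranges, comparative constraints).

Fits are classified against the objective at the generating parameters:
overfit (OF), good fit (GF), or local optimum/underfit (LO) by
`log10(J/J_nominal)` with a ±0.25 band.

See `docs/methods.md` for the model, algorithms, defaults and limitations.

## Worked example

Calibrate the built-in two-species coexistence fixture from synthetic 5%
noise data, end to end:

```python
from mcid.workflow import RunConfig, run_workflow

config = RunConfig(model="glv2", seed=7, output_dir="out",
                   synthesis={"noise_level": 0.05},
                   optimizer={"method": "ess", "max_nfev": 2500,
                              "local_every": 4})
bundle = run_workflow(config)
print(open("out/report.md").read())
```

which prints (numbers from this exact configuration and seed):

```
# Model identification report

- model: `glv2`
- master seed: 7

## Phase 1 — structural identifiability (local screen)

- FO: **locally_identifiable** (rank 6/6)

## Phase 2 — calibration and practical identifiability

- best objective J = 59.728 (status converged, class GF)
- nominal objective J = 68.8063
- FIM condition number = 1.02e+03
- stability verdict: **plausible**

## Phase 3 — predictive power

- residuals: mean z = 0.135, Q-Q corr = 0.9920, variance = 0.995
- cross-validation: mean validation NRMSE = 0.359 over 2 folds
```

Reading it: the fully-observed scheme is locally identifiable (rank 6/6 of
the sensitivity matrix), so estimation is worth attempting. The scatter
search reached J = 59.7 against J = 68.8 at the true parameters — with 60
records this is the expected χ² scale, and `log10(59.7/68.8) = −0.06` puts
the fit in the good-fit band rather than overfitting. The
Fisher-information condition number (~10³) says the data constrain all six
parameters, the extended-horizon screen finds no hidden divergence, the
standardized residuals look like unit-variance white noise (Q-Q
correlation 0.992, variance 0.995), and the model predicts a held-out
experiment to ~36% of its observed range per fold — honest but not
perfect, reflecting the residual parameter uncertainty at 5% noise. The same pipeline is available from the shell:

```bash
mcid run --config run.json --seed 7 --out outdir
```

with `run.json` holding the same fields as `RunConfig`; subcommands
`simulate | generate | sia | fit | pia | stability | validate | run | bench`
expose the individual phases. Exit codes: 0 success, 2 invalid
configuration, 3 phase failure.

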