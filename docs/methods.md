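# Methods

This note documents the model, the estimation procedure, the numerical
choices, and what the synthetic benchmarks do and do not establish.

## Model class

The state is a vector of `m` metabolite concentrations obeying the mole
balance `dX/dt = S v(X, p)` with an `m × n` stoichiometric matrix `S` and
`n` flux functions.  Two kinetic laws are implemented:

* **Power law (GMA):** `v_j = γ_j Π_i X_i^{f_ji}`, with rate constant
  `γ_j > 0` (units flux/concentration^Σf) and kinetic orders `f_ji`
  (dimensionless; positive = substrate/activation, negative = inhibition).
  Each flux stores only its own sparse dependency set; no dense order
  matrix exists anywhere.
* **Michaelis–Menten:** `v = s · vmax · X/(km + X)` with `vmax > 0`
  (concentration/time), `km > 0` (concentration) and a dimensionless scale
  `s` (default 1) available for compartment volume ratios.

Simulation uses `scipy.integrate.solve_ivp` with LSODA (GMA systems are
frequently stiff); reference runs use `rtol=1e-8, atol=1e-10`, pipeline
runs `1e-6/1e-8`.  States are clipped at zero inside the right-hand side
and concentrations are floored at `1e-12` before exponentiation so a
smoothed value at zero cannot produce `0^negative`.

## Incremental identification

Estimation is decomposed into smoothing → slopes → dynamic fluxes →
per-flux regression rather than one global ODE fit.

**Smoothing.** Candidate smoothers are least-squares polynomials
(default degrees 3–6) and a cubic smoothing spline whose penalty is chosen
by generalized cross-validation.  Selection is by AIC,
`K ln(RSS/K) + 2(c+1)` with complexity `c` = number of coefficients
(effective degrees of freedom for the spline) and an RSS floor of `1e-15`;
adjusted R² is reported alongside but does not decide.  Two guards matter
in practice:

* GCV penalties with effective dof above `max(8, K/4)` are excluded — GCV
  occasionally undersmooths a noisy realization catastrophically, and a
  wiggly fit ruins every downstream slope;
* slopes are central finite differences of the smoothed values (one-sided
  at the ends), and the incremental stage works on *interior* time points
  only: by default 1 leading and `1 + K/12` trailing rows are dropped.
  Edge slopes carry one-sided-difference error and maximal smoother
  leverage; empirically they were the dominant source of spurious
  flux-positivity violations and out-of-bound regressed parameters, while
  the flat trajectory tail they cover carries little information.  The
  full-grid profiles remain available (`interior_profiles` is an explicit,
  reversible step).

**Flux decomposition.** With `m*` measured metabolites, `n_DOF = n − m*`
independent fluxes are selected by enumerating subsets: a subset is
admissible when its dependent submatrix `S_D` (measured rows) has
condition number below `1e8` and every independent flux depends only on
measured metabolites (otherwise `v_I(X_M, p_I)` is not computable);
among admissible subsets the total independent-parameter count is
minimized, ties broken toward lowest flux indices.  On the two benchmark
pathways this reproduces the canonical choices `{v1, v6}` and
`{v4, v7, v8}`.

**Unmeasured metabolites.** Unmeasured species appearing in no flux
dependency are sinks and their balance rows are dropped.  Every remaining
unmeasured row `S_u` is eliminated when it can be written exactly as
`c · S_M + d`, with `d` supported on fluxes whose dependencies are fully
measured; the minimum-norm exact solution of this linear system is the
slope recipe `Ẋ_u = c · Ẋ_M + Σ d_j v_j`.  The recipe is an algebraic
identity, not an approximation.  Hidden concentration profiles needed by
dependent-flux regressions are reconstructed by trapezoidal integration of
the recipe slope from a user-supplied initial value.  Non-eliminable
unmeasured metabolites are flagged; the simulation-based fallback is not
enabled by default.

**Per-flux regression.** Power laws are fitted by unweighted least squares
in log space; a rank check (relative SV cutoff `1e-10`) rejects collinear
log-profiles, and the `K > d+1` uniqueness condition is enforced.
Michaelis–Menten fluxes are fitted by the linearization
`[X·v] = vmax·X − km·v`; the solve is unconstrained and bound violations
are reported, never clipped.  When a usable curve is required even though
the linearization left the positive domain (saturated, noisy profiles can
linearize to negative `km`), a bounded nonlinear least-squares refit is
available and is used by the Monte Carlo bound replicates.

## Error functions and viability

All error functions are **means of squared relative errors** (denominator
guarded at `1e-8`), so values are comparable across model sizes:
`Φ_R` compares each regressed dependent flux function against its
mass-balance target; `Φ_S` compares `S_M v(X_M, p)` against the estimated
slopes; `Φ_C` compares the simulated trajectory against the measured data
(`+inf` on simulation failure).  Because this normalization is a package
choice, printed error values are comparable only within this package.

A candidate `p_I` is viable when, in order: `p_I` is inside its bounds;
all dependent flux values are positive and all fluxes below the cap
(default `5e5` mM/min); the regressed `p_D` is inside its bounds; and
`Φ_R` is below the confidence bound.  Verification short-circuits and
records the first failure.

**Confidence bound.**  The noise variance per metabolite is estimated from
the smoothing residuals, `RSS/(K − c)`.  `n_mc` replicate datasets are
drawn around the measured data; each is re-smoothed and re-sloped.  Two
readings of "re-estimate and collect Φ" exist, and they bracket the truth
from opposite sides:

* *re-minimize* Φ_R over `p_I` per replicate — these minima sit
  systematically below the Φ of any fixed parameter point (the optimizer
  absorbs part of the replicate's noise), so the bound can exclude a true
  model when noise is small;
* *re-evaluate* Φ_R at the base-data minimizer (only the per-flux least
  squares are redone per replicate) — cheap and anchored at a fixed point,
  but that point is in tune with the base noise realization and can sit
  below a generic true point when noise is large.

The default bound is the larger of the two (both at the
`ceil((1−level)·n_mc)`-th-largest order statistic, e.g. the 5th largest of
100 at 95%).  In benchmark experiments this conservative combination
covers the true parameters in ≈9/10 seeded runs at both 1% and 10% noise,
where each single reading fails in one regime.  Replicate minimization
drops the dependent-parameter bound constraints and uses masked flux
positivity (fluxes fitted on their positive-target time points, requiring
≥80% positive): a replicate whose noise flips a few slope signs should
contribute a large Φ, not abort the procedure.

**Initial point.** `Φ_R` is minimized by multistart Nelder–Mead (default
20 Latin-hypercube starts plus the box center; warm starts get jittered
copies) on a penalized objective: out-of-box `p_I`, nonviable regressions
and out-of-bound `p_D` map to graded penalties so the direct search can
descend back into feasibility.

## Viable-space exploration

**OEAMC.** An adaptive random walk: proposals from a diagonal normal
kernel (scale initialized at 5% of each bound range), accepted into the
coarse set iff viable.  With probability 0.1 the proposal scale is
inflated tenfold — these out-of-equilibrium jumps let the chain cross
between poorly connected viable pockets.  The scale adapts toward 25%
acceptance, shrinking hard (×0.3) on empty batches so thin regions are
found quickly.  After every batch the viable points are clustered
(single linkage in box-normalized coordinates, cutoff 10% of the
normalized diagonal) and per-cluster minimum-volume enclosing ellipsoids
are fitted; sampling stops when the summed ellipsoid volume changes by
less than 5% over two consecutive checks (convergence is not tested until
at least 20 points exist, so a never-accepting run terminates at the
iteration cap with a warning flag).

**MVEE.** Khachiyan's barycentric-coordinate ascent with tolerance `1e-3`;
the returned ellipsoid is rescaled so the farthest input point sits
exactly on the boundary — containment of all inputs is asserted on every
call.  Degenerate inputs (fewer than `d+1` points, or points on a flat)
fall back to a principal-axes ellipsoid with a floor semi-axis.

**MEBS.** Every coarse point not already covered seeds a local loop: a
cloud of nearby viable points is gathered by perturbation (walking a
scale ladder downward until perturbations land, which handles very thin
regions), an MVEE is fitted, inflated by the multiplier `g`, sampled
uniformly (exact affine-image-of-ball sampling, no rejection), viable
samples are kept and the ellipsoid refitted; the multiplier follows
`g_{i+1} = 1 + 0.7 (g_i − 1)` from `g_1 = 2` until `g < 1.05` or 20
iterations.

**Volume.** The union volume of the cover is estimated by sampling from
the ellipsoids proportionally to their volumes and weighting each sample
by 1/(number of covering ellipsoids), zero if outside the parameter box
(the viable region cannot leave it); the estimate carries a standard
error.  `V_ci`, the initial volume, is the product of the independent
parameter ranges only.

## Pipeline and determinism

`build_ensemble` chains the stages (reduce → align → smooth → decompose →
initial point → bound → OEAMC → MEBS → volume → per-member error ranges),
with one master seed fanned out via `SeedSequence` to per-stage seeds; two
runs with the same seed and configuration produce identical ensembles.
Members are stored as independent-parameter vectors only; dependent
parameters are regenerated on demand by the per-flux regression.  Φ_S/Φ_C
ranges are computed over a seeded member subsample (default 50) because
Φ_C requires one ODE integration per member.

## Synthetic benchmarks

The generators emulate the statistical structure of the two case studies;
the original true parameter values are not published, so the defaults are
documented package choices and every test is parameter-*recovery*, never
value-matching.

* **Branched pathway:** 4 metabolites, 6 power-law fluxes, 13 parameters
  (dependency pattern `f13, f21, f33, f43, f44, f51, f64`), all measured;
  i.i.d. Gaussian noise with 10% CV by default (sd proportional to the
  trajectory value, absolute floor `1e-4` at zeros, negative draws floored
  at `1e-6`).  X4 is consumed by two parallel routes (v4, activated by X3,
  and v6), giving those fluxes proportional stoichiometric columns — the
  structural feature that makes `{v1, v6}` the unique admissible
  minimal-parameter independent set.  The default truth places the steady
  state at order-one concentrations with mid-range kinetic orders
  (1.0–1.5) and a displaced initial state, sampled at 101 points over 6
  time units: concentrations stay of order one (fluxes bounded away from
  zero, so strict positivity of noisy flux targets is achievable) and the
  log-concentration ranges are wide enough that order estimates at 10%
  noise scatter by ~±0.5 — inside the `[0, 5]` search box.
* **Trehalose pathway:** 8 metabolites, 8 fluxes; Michaelis–Menten glucose
  transport with the extracellular balance scaled by `−V_in/V_ex`
  (`V_ex = 5.00e-2 L`, `V_in = 7.17e-3 L`; the MM `scale` field exists for
  the same purpose and is tested, the fixture carries the ratio in the
  stoichiometric coefficient); PPP and leakage as pure sinks; unmeasured
  intracellular glucose eliminable by the overall mass balance.  The
  transport truth (`vmax=3, km=0.8`) makes the glucose pulse traverse both
  kinetic regimes — near-constant decrease while saturated, exponential
  tail below `km` — so both MM parameters are identifiable.  Default
  noise 5% CV, emulating moderately noisy in vivo NMR time courses.
* **Random GMA models:** chain backbone plus sparse random columns (full
  row rank by construction), substrate-consistent dependencies, used by
  property tests.

What passing these benchmarks shows: the algebra (decomposition,
elimination, regression) is exact on exact data; the statistical pipeline
covers the true parameters at the advertised confidence under i.i.d.
relative Gaussian noise.  What it does not show: robustness to model
mismatch (wrong flux laws), correlated or non-Gaussian measurement error,
missing time points, or real instrument artifacts — none of which the
generators emulate.

## Problem sizes and limitations

Default test and example budgets are deliberately small (e.g. `n_mc=20`
replicates, a few thousand exploration iterations, volume estimates from
`5e3–3e4` samples); they characterize the viable region coarsely.
Production runs should raise `n_mc` to 100 and the exploration budgets by
an order of magnitude.  Known limitations: the ellipsoid cover
over-estimates sharply non-convex regions; the conservative combined
error bound widens with sloppy replicate optimization; per-flux
regression requires every dependent flux's (possibly reconstructed)
regressor profiles to be positive and non-collinear; and rank-deficient
`S_D` (pseudo-inverse handling) is detected but not supported.
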