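# Methods

## Model

`agingnet` implements a weighted network model of aging over `N` binary
health attributes ("deficits") d_i ∈ {0, 1}.  Damage is irreversible
(0 → 1 only) and mortality is a separate competing event channel.  With
φ(x) = max(x, 0) the hinge/rectifier:

- local frailty of node i:  f_i(t, {d_j}) = φ( Σ_j w_ij d_j + μ_i(t) ),
  μ_i(t) = Σ_{n=1..n_f} μ_{i,n} t^n;
- damage rate:  Γ⁺_i = φ( Σ_{n=0..n_+} γ⁺_{i,n} f_i^n );
- mortality load:  x(t, {d_j}) = φ( Σ_j β_j d_j + Σ_{n=0..n_D2} η_n t^n );
- mortality rate:  Γ_D = φ( Σ_{n=0..n_D1} α_n x^n ).

The directed weights w_ij capture how existing damage at node j promotes
damage at node i; μ_i(t) absorbs the age-dependent influence of everything
not represented as a node.  All series coefficients of order ≥ 1 are
constrained non-negative so that f_i, Γ⁺_i, x and Γ_D are monotone
non-decreasing in age at fixed deficits; intercepts and weights may be
negative (the hinge keeps rates non-negative, and a negative intercept lets
a rate switch on at a finite age).

Two conventions fix coordinates that the data cannot identify: diag(W) = 0
(node i's damage rate is only ever evaluated while d_i = 0, so w_ii never
enters) and μ_{i,0} = 0 (an additive constant inside f_i is redundant with
the γ⁺ intercept).  With these, the free-parameter count is
N(N + n_f + n_+ + 1) + n_D1 + n_D2 + 2 — e.g. 188 for N = 10 with
(n_+, n_f, n_D1, n_D2) = (4, 3, 3, 3), the configuration used with the
observational studies this family targets.

## Stochastic simulation

Between events the deficit vector is frozen, so every component hazard is a
monotone, piecewise-polynomial function of age (pieces separated by hinge
zero-crossings, at most two per component).  `agingnet._ssa` draws waiting
times exactly by hazard inversion: hinge breakpoints are bracketed and
bisected (tolerance 1e-8 y), the cumulative hazard is integrated with
Gauss–Legendre quadrature between breakpoints (order chosen from the
composite polynomial degree, hence exact), and ∫Γ_tot = Exp(1) is solved by
safeguarded Newton iteration to 1e-10 y.  Event identity is then drawn
proportional to the instantaneous rates, nodes in index order with
mortality last (exact floating-point ties are measure-zero).  A thinning
(rejection) sampler over one-year windows — valid because every hazard is
monotone, so the window-end value is an upper bound — serves as an
independent cross-check; the two samplers agree distributionally
(two-sample KS in the test suite).

Randomness is a splitmix64 counter stream keyed by (seed, stream id), one
stream per simulated individual, so any individual's trajectory is
reproducible in isolation and independent of batch order.  The default
horizon is 120 years; individuals alive there are flagged, not killed.

## Likelihood for censored cross-sectional data

A record is {t, {d_i}, a, c}: baseline age, deficits (missing allowed),
last known-alive age, censoring flag.  The log-likelihood is

L = Σ_{c=0} log p̂(a | {d}, t) + Σ_m log p̂({d_i} | t) + Σ_{c=1} log Ŝ(a | {d}, t),

with every term estimated from simulations:

- **Health term.**  A birth-cohort pool (default 10⁴ individuals, all
  healthy at t = 0) is tallied into an age-binned joint state distribution
  (1-year bins, states among survivors at the bin midpoint) with additive
  smoothing of 0.5 per state per bin.
- **Censored survival.**  Simulated event ages are exact, so Ŝ(a | {d}, t)
  conditions on pool individuals alive at exactly t whose state matches the
  record's observed deficits at t, smoothed as (k + ½)/(n + 1); records
  whose state has no alive match fall back to the marginal pool.
- **Uncensored density.**  For fully observed records, forward simulations
  from (t, {d}) (default 500 per record) and the central finite difference
  [Ŝ(a−Δ/2) − Ŝ(a+Δ/2)]/Δ with Δ = 1 y, smoothed with an add-half
  correction (k + ½)/(R + 1)/Δ so a zero-death window costs log(½/R) rather
  than an unbounded floor — without this the optimizer inflates mortality
  solely to avoid floor penalties.  Records with missing deficits use the
  pool estimator (deaths within a ± Δ/2 among state-matched survivors),
  which marginalizes the missing coordinates implicitly; the health term
  sums the smoothed table over all completions.
- **Validity guard.**  All terms condition on survival to the baseline age,
  so the likelihood says nothing about pre-entry mortality; with small
  pools, smoothing would additionally let parameters that kill almost the
  whole pool saturate the health term.  A parameter vector whose pool
  leaves fewer than `min_bin_count` survivors (default 10) in any age bin
  occupied by the data is therefore treated as invalid (−∞): the
  conditional estimators are undefined there.

For a given random stream the likelihood is a deterministic function of the
parameters (common random numbers); forward streams are keyed to record
content, making L exactly invariant to record order.

## Fitting

Maximum likelihood by global-best particle swarm optimization: inertia
0.72, cognitive = social = 1.49, velocity clamp at 20% of the bound span,
reflecting bound handling, coordinates with equal bounds held fixed;
defaults swarm 50 × 200 iterations.  The stochastic objective is handled
with *per-iteration* common random numbers: all particles in an iteration
share one simulation stream (so their ranking is fair), and the stream is
reseeded each iteration.  With a single fixed stream a swarm of this size
reliably climbs the realized noise of the evaluation pool instead of the
likelihood — selected "optima" scored tens of nats above the generating
parameters on the fitting stream and tens of nats below them on fresh
streams; reseeding bounds that selection bias by the luck of ~10² iteration
draws rather than ~10³–10⁴ position-adapted ones.  Because the per-position
noise at practical budgets (σ ≈ 10 nats at pool 3000) still exceeds the
behavioural signal separating near-optimal modes, a final selection phase
re-scores the personal-best positions of all particles once on an
independent stream with simulation budgets scaled up (default 5×, σ well
below 1 nat) and returns the winner — a standard clean-up step for
simulation-based optimization that costs ~1% extra evaluations.  Bounds
encode
the monotonicity constraints (lower bound 0 for every series coefficient of
order ≥ 1); weights and intercepts default to [−10, 10], but analyses
should narrow these to the per-year scales of their data.  An optional L1
penalty λ(‖W‖₁ + ‖β‖₁) regularizes the network.  The fitted network is
*not* expected to be identified — repeated fits reach equal likelihood with
different weights — so recovery is asserted on model behaviour (prevalence
and survival curves), not on W entrywise; the L1 penalty selects a sparse
representative of the likelihood-flat set.

## Synthetic studies

`synthetic.make_ground_truth` draws a sparse, mostly synergistic network
(default edge density 0.4, weights ~ N(0.6, 0.3)), damage intercepts
γ⁺_{i,0} ~ U(0.001, 0.006)/y, damage slopes γ⁺_{i,1} ~ U(0.03, 0.12),
background age slopes μ_{i,1} ~ U(0.0005, 0.002)/y², and mortality weights
β_j ~ U(0.2, 1.0); the mortality scale is calibrated by pilot simulation so
the birth-cohort median death age is ≈ 80 y.  These scales produce deficit
prevalences rising from ≈ 0.3–0.5 at 65 to ≈ 0.6–0.8 at 95 and ≈ 90%
censoring under a 6-year window — the structure (not the values) of the
ADL/IADL-based studies this model family is fitted to.

`sample_cross_sectional` simulates individuals from birth, accepts a drawn
baseline age only if the individual is alive then (the left truncation a
cross-sectional study of the living implies), records the state at
baseline, right-censors at baseline + window, and masks deficits MCAR.
Presets encode the two study shapes: entry ages 65–99 (truncated normal
76 ± 7) with a 6-year window, and 20–85 (51 ± 20) with a 10-year window,
N = 10 deficits, study-sized cohorts.

What the generator does *not* emulate: Gompertz-steep old-age mortality
(with first-order series the population hazard grows linearly, so the
survival tail beyond ~95 is heavier than in human cohorts), informative
missingness, stratified sampling weights, and measurement error.  Passing
tests therefore demonstrate correctness of the machinery and recoverability
under the stated conditions, not fidelity to any particular human cohort.

## Validation battery

Prevalence and pairwise-prevalence trajectories among survivors (with
binomial standard errors and Fréchet-bound checks), frailty-index
distributions, left-out-deficit imputation AUC (scores from birth-pool
individuals matched on the observed sub-state at the record's exact age;
records with no match are dropped and counted), Kaplan–Meier curves
(lifelines, with left-truncation entries), mean predicted survival ⟨Ŝ⟩,
the age-dependent concordance index C^td = Pr(Ŝ₁(a₁) < Ŝ₂(a₁) | a₁ < a₂,
c₁ = 0) with ties at 0.5, an IPCW Brier-score R² against the population KM
reference, windowed dead/alive AUC, and conditional damage-propagation
rates Γ_{i←j}(t).  Confidence intervals are percentile bootstrap over
individuals (1000 resamples); age stratification defaults to 5-year bins.

## Parameter-recovery experiment (test suite)

The end-to-end check fits a cohort of M = 2000 records (entry 65–99,
6-year window) generated from a known N = 3 model (first-order series,
22 free parameters) with a reduced budget: swarm 30 × 100 iterations,
search likelihood with a 6000-individual pool and all mortality terms
estimated from the pool (lowest-noise configuration, σ ≈ 6 nats), validity
guard 150 (2.5% of the pool), L1 strength λ = 1, scale-informed bounds,
method-of-moments warm start, and a forward-simulation final-selection
re-score.  Because every likelihood term conditions on survival to entry,
pre-entry mortality is structurally unidentifiable, and near-optimal
parameter sets differ behaviourally; recovery is therefore asserted on
identifiable functionals at the resolution M = 2000 supports: survivor
prevalences in 5-year age bins over [65, 90) (where >95% of baseline ages
fall) and the age-conditional cohort Kaplan–Meier curve S(t | alive at 68)
(entries clamped to a common left edge — the raw left-truncated KM is
unstable while the earliest entrants trickle in), compared where risk sets
are adequate and with the fitted model's KM estimated from a 10⁴-individual
synthetic cohort so the comparison is not dominated by fitted-side
sampling noise; each functional must agree with the generating model
within ±0.05.  Problem sizes
throughout the suite (simulation pools of 10³–10⁵, bootstrap 1000) were
chosen so the full battery completes on a single CPU in well under half an
hour.

## Numerical choices

Horner evaluation for all power series; ages up to 120 are used directly
(t³ ≈ 1.7·10⁶ is well within double precision; an internal t/100 rescale
for optimizer conditioning was considered and found unnecessary at the
bound scales recommended).  Bisection tolerances: 1e-8 y (breakpoints),
1e-10 y (event times).  Ŝ is defined as 1 below the baseline age; an event
at exactly age t is included in the state at t (right-continuity);
simultaneous events are resolved node-index-first, mortality last.
Degenerate inputs are signalled, not silently absorbed: empty age bins
raise, damage rates of already-damaged nodes raise, all-identical labels
make windowed AUC raise, and infeasible cohort designs abort after a
bounded number of rejections.
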