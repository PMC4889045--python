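# Methods

## Scope and model class

The package simulates Markov jump processes (chemical master equation
dynamics) whose propensities $a_j[X, I(t)]$ depend on an exogenous input
$I(t)$: a process that influences the network but is not influenced by it
(negligible retroactivity), and can therefore be pre-simulated on $[0, T]$.
Time is in hours everywhere; all rates are h⁻¹.  The master-equation setting
implicitly assumes a dilute, well-mixed reaction volume; molecular crowding
and spatial effects are out of scope, as are networks that feed back onto
their inputs.

## Input trajectories

An input is a gridded path with a declared interpolation rule.  The default
rule is **left-constant** (a right-continuous step function): the trajectory
then only ever takes grid values, so the window-supremum query used for the
propensity bound is an *exact* supremum and the thinning bound is rigorously
valid.  Linear interpolation is also supported; its supremum over a window is
attained at window endpoints or interior grid points and remains exact.

Generators (all reproducible bit-for-bit given (spec, dt, T, seed)):

* **Ornstein–Uhlenbeck**: $dX=-\gamma(X-\mu)dt+\sqrt{2\gamma\sigma^2}\,dW$;
  stationary variance $\sigma^2$, autocovariance $\sigma^2 e^{-\gamma|\Delta|}$,
  lifetime $1/\gamma$.  Default scheme is Euler–Maruyama (an AR(1) recursion
  run through `scipy.signal.lfilter`); an exact-discretization scheme is kept
  for validation, and the scheme is recorded in the trajectory metadata.  The
  initial value is drawn from the stationary law unless overridden.  A
  warning is raised when $\gamma\,dt > 0.1$.
* **Circadian**: $k(t) = 4k_{dp}(1+\sin 2\pi f t)$, default period
  $1/f = 24$ h; the time-average of $k/k_{dp}$ over a period is exactly 4.
* **Normalized lognormal**: $k(t) = \bar k\,\langle e^{\xi}\rangle^{-1}e^{\xi(t)}$
  for zero-mean OU noise $\xi$; the lognormal identity
  $\langle e^{\xi}\rangle = e^{\sigma^2/2}$ makes the stationary mean exactly
  $\bar k$.
* **Modulated circadian**: $k(t) = A\,e^{\xi(t)}(1+\sin 2\pi f t)$, default
  amplitude $A=20$; the variance of $\xi$ is an explicit parameter of the
  supplied OU path (we use 1/8 in the reduced-scale population checks —
  variances of order 10 would swing $e^{\xi}$ over many orders of magnitude,
  which is not a plausible model of amplitude fluctuation).
* **Sum of independent OU paths** for two-exponential autocovariances.

Gaussian OU paths used as molecular-count inputs (the quorum-sensing
transcription factor) can dip below zero; `clip_nonnegative()` clips them at
evaluation time and records the clipped fraction (≈0.2% at CV 0.35).

## The thinning simulator

The core loop follows the extra-reaction construction exactly: bound
determination, $\tau\sim\mathrm{Exp}(B)$, reject if $\tau > L$ (clock
advances by $L$), otherwise refresh propensities at $t+\tau$ and use a
*single* uniform $u$ for both the acceptance test $a_0 \ge Bu$ and the
channel selection (smallest $j$ with $\sum_{i\le j} a_i \ge Bu$).  Reusing
the one uniform is a deliberate fidelity choice; two independent uniforms
would be equally correct.

Bound strategies:

* `window-max` (default): $B$ = safety × max of $a_0(X, I(s), s)$ over the
  input-grid evaluation points in $[t, t+L)$.  Generic, one
  propensity-vector evaluation per grid point in the window.
* `monotone-sup`: $B$ = safety × $a_0(X, I^*)$ with $I^*$ the exact window
  supremum of the input.  Requires the network to declare every propensity
  nondecreasing in the input; one propensity evaluation per bound.  This is
  the cheap bound used for ensemble runs.
* `global`: `monotone-sup` over the whole remaining horizon ($L = T-t$).
  (A state-independent global constant is not well defined when propensities
  depend on the state, so "global" here means a globally valid input
  supremum combined with the current state.)

$L$ is clipped to $T-t$.  The runtime check $a_0(t) \le B$ at every
acceptance evaluation is a hard failure (`BoundViolationError`), not a
warning — a violated bound means the sampled law is no longer exact.  When
$B=0$ (nothing can fire while the state is unchanged) the window is
traversed and counted as an automatic rejection, keeping the invariant
`exponentials drawn = accepted + thinned + rejected`.

The look-ahead $L$ can be fixed, chosen by a short pilot scan (log-spaced
candidates; minimises propensity evaluations + exponentials drawn), or
adapted online by a heuristic (double after 32 reject-free draws, halve on a
reject, clamped to a factor 64 around the initial value).  The adaptive rule
is our own labelled heuristic — the base algorithm leaves it open — and is
flagged experimental.  Output distributions are invariant to $L$; only the
reject/thin bookkeeping trades off (verified by rank tests in the suite).

### Engines

Two implementations of the same algorithm: a general pure-Python path
(arbitrary propensity callables, full event recording including thin/reject
pseudo-events) and a numba-compiled fast path for the ensemble-scale common
case (mass-action network, uniform step-function input, monotone-sup bound,
grid-only recording).  Engine selection never changes the sampled law, only
the RNG stream; determinism holds per engine, and the suite checks the two
agree distributionally.  Event statistics count individual per-channel
propensity evaluations — the hardware-independent surrogate for the CPU time
that dominates integral methods.

## Reference methods

**SIA** (slow input approximation): a classic SSA loop whose input value is
frozen at the last firing time; both the waiting time and the channel
selection use the stale value.  Faithfully reproduced including the trapping
failure: if the total (stale) propensity reaches zero, no reaction can ever
fire again and the run continues silently to $T$ (a warning is logged and
the trajectory is flagged `trapped`).  This trapping — and more generally the
sluggish update of the input when copy numbers are near zero — is the
mechanism behind the method's large errors; the package exposes the
time-fraction-at-zero diagnostic that explains them.

**Modified-next integral method**: per channel, a unit-exponential target
$P_j$ and an internal clock $T_j=\int a_j\,ds$ accumulated by the
trapezoidal rule, stepping on the union of the input grid and a configured
integration step.  The within-step firing time solves the trapezoid's linear
interpolant (closed-form quadratic; a bisection rule is available).  After a
firing, the fired channel draws a fresh increment to its target and all
clocks resume from the firing time.  The published description of this
method family does not pin down every detail; our dialect (linear-in-step
propensity, union-grid stepping) is stated here and is consistent with
trapezoidal accumulation.  Accuracy is governed by the coarser of the
integration step and the input grid (warned).  A **direct-integral** variant
(single integral of $a_0$ to one target; channel chosen $\propto a_j$ at the
firing time) sits behind a config switch; no quantitative performance claim
is attached to it.

## Oracles and metrics

* **Conditional-moment ODEs** (two-stage model): $d\langle m\rangle/dt =
  k(t)-k_{dm}\langle m\rangle$, $d\langle n\rangle/dt = k_s\langle m\rangle -
  k_{dp}\langle n\rangle$ — exact for this linear network conditional on the
  input.  Integrated with a piecewise-exact propagator on the input grid
  (matrix exponential per unique step, forced response by 24-node
  Gauss–Legendre quadrature of $e^{Au}$), so the only error is round-off;
  both step-function and piecewise-linear forcing are handled exactly.
* **Finite-state master equation**: truncated box per species, per-reaction
  sparse flow matrices (probability leaving the box is removed and reported
  as leakage, which must stay below tolerance or a larger box is demanded);
  time-varying channels are gated by the input value at the integrator's
  time.  LSODA with rtol 1e-8.  Leakage is monotone nonincreasing in the box
  size.
* **Metrics**: proportional RMSE
  $[\frac{1}{T\bar n_{ex}^2}\int_0^T(\langle n\rangle-n_{ex})^2 dt]^{1/2}$
  (trapezoid quadrature on the exact solution's grid, scale-free);
  stationary proportional error $|est-exact|/exact$; exact time-weighted
  zero-occupancy fraction from the piecewise-constant path.

## Ensembles and cell fate

Ensemble runs spawn one RNG stream per cell from a master seed (numpy
`SeedSequence`), with either an independent input realization per cell or a
single shared pre-generated realization; the population mean is accumulated
on a fixed output grid by sampling each cell's right-continuous path.
Failures abort with the cell id and seed, so runs are resumable.

Fate mechanics: progress to competence is
$\mathrm{Progress}(t)=k\int_0^t \mathrm{ComK}(s)\,ds$ with entry at
Progress = 1; since the simulated regulator path is piecewise constant the
crossing is solved exactly within its segment.  Per-cell outcomes carry the
entry time, the time-averaged (clipped) input over the experiment window and
the final progress.  The competent fraction comes with its binomial standard
error; the probability-of-competence curve versus mean input is a
maximum-likelihood logistic regression (statsmodels), with an L2-regularised
Newton fallback (flagged) under complete separation.  Entry times scale as
$1/k$ pointwise, so the competent fraction is monotone in the
differentiation rate for a fixed trajectory set.

The wild-type and rewired quorum-sensing competence networks themselves are
user-supplied through the declarative network config (their full reaction
tables are not part of this package); a small bistable-expression toy —
an input-activated telegraph promoter driving bursty expression of a
master-regulator species — makes the fate pipeline testable end to end and
is explicitly labelled a synthetic illustration.

## Benchmark parameterisations

* **Circadian alga** (picoalga at circadian timescales): the organism's
  relative timescales — 0.008 oscillation cycles per protein lifetime, 0.002
  per mRNA lifetime — fix $k_{dp}=f/0.008\approx5.21$ h⁻¹ and
  $k_{dm}=f/0.002\approx20.8$ h⁻¹ at $f=1/24$ h⁻¹; $k_s=100\,k_{dp}$ sets
  the mean protein to ~100 (stationary mean mRNA is $4k_{dp}/k_{dm}=1$).
  Study window 240 h (the 10-day design of the population panels), 200 SIA
  cells; the exact comparator is the conditional-moment ODE on the same
  gridded input (dt $10^{-3}$ h at desk scale; the much finer production
  grids change nothing measurable here because the input varies on a 24 h
  scale).
* **Bacterial stationary regime**: normalized lognormal-OU transcription
  with log-variance 5 and $\gamma=k_{dp}$ (stable proteins removed mainly by
  dilution), $k_{dm}=10\,k_{dp}$.  The transcription/translation split is
  chosen in the canonical low-copy bacterial regime — mean mRNA 0.2
  ($\bar k = 2$ h⁻¹) and burst size $k_s/k_{dm}=50$ — giving the analytic
  stationary mean $\bar k k_s/(k_{dm}k_{dp}) = 100$.  200 cells × 150 h with
  a 30 h burn-in.  In this regime the rare, large excursions of the
  lognormal rate dominate the mean; the stale-input method misses them
  whenever copy numbers are low, which is exactly its failure mode.
* **Quorum-sensing input baseline**: single OU with mean 1000 molecules,
  lifetime 5 h, CV 0.35 (the upstream-signalling surrogate); measured over
  ≥2000 correlation times at dt = lifetime/1000.

## What the synthetic benchmarks do and do not show

The generators emulate the *study conditions* (deterministic circadian
drive, stationary lognormal transcription noise, OU signalling input), not
real data: real transcription inputs are neither exactly lognormal nor
exactly OU, cell ensembles are not perfectly exchangeable, and measurement
noise is absent.  Passing the suite therefore demonstrates algorithmic
correctness (conditional exactness against master-equation and moment-ODE
oracles, thinning identities, cross-method agreement) and the *relative*
behaviour of the methods under controlled conditions — not predictive
accuracy for any particular organism.  Wall-clock speed-ups are deliberately
replaced by propensity-evaluation counts, which are hardware-independent;
the measured count ratios (>10× at matched fine steps on the noisy-circadian
benchmark) understate what production-scale grids would show, because the
integral method's cost grows linearly as its step shrinks while the thinning
cost does not.

## Numerical choices and degenerate inputs

Tolerances: bound-violation slack $10^{-9}$ relative (pure round-off);
moment-ODE and master-equation rtol $10^{-8}$; quadratic crossing solve
falls back to the linear branch when the slope is negligible.  Ties in
channel selection resolve to the smallest index by construction.  A uniform
draw of exactly 0 selects the first channel with positive propensity.
Zero-propensity states under a zero bound advance the clock by whole
windows.  Mass-action propensities use falling factorials (no $1/r!$), so
consumed-species-absent states have exactly zero propensity and negative
populations are impossible by construction; a negative count after any
update is a hard consistency error pointing at a broken user propensity.
Networks are dense small-state-vector objects (intended for ≲30 species).

## Known limitations

Single scalar input per trajectory object (multivariate inputs can be
expressed as separate input-scaled channels but share no joint supremum
machinery); the compiled fast path covers only the mass-action/uniform-grid
case; the master-equation oracle assumes input dependence enters
multiplicatively through declared input-scaled channels (general
input-dependent propensities fall back to an input-independent evaluation
and should not be used with that oracle); no tau-leaping or hybrid
approximations — the package's purpose is exact conditional sampling.
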