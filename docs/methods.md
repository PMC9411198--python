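# Methods

This note records the models, the algorithmic and numerical choices behind
them, and what the synthetic tests do and do not establish.

## Arrays and geometry

A `PlatformArray` is a labelled set of 2-D points with a derived Euclidean
distance matrix. Distances are unitless: the physical arrays were scaled to
each species' body size, so only relative geometry is meaningful, and all
shape-dependent results in this package use scale-invariant quantities
(slopes, DET) or are checked under explicit rescaling.

The three built-in fixtures reconstruct the experimental shapes from their
descriptions rather than from published coordinates (none are printed):

- **Double Trapezoid** — two congruent trapezoids sharing a long base, six
  platforms, labels following the perimeter with platforms 1–2 the closest
  pair. The fixture is scaled so that `log(2·L_min) = 4.78`, the intercept
  prior centre used for this array, which pins it to the coordinate scale
  of the original analysis. Its optimal open path is the perimeter walk
  `1-2-3-4-5-6` with `L_min = 59.55`.
- **Z array** — six platforms along a Z stroke (bar ends, two diagonal
  platforms, bar ends), overall scale 4 units per base coordinate
  (`L_min = 44.0`).
- **Pentagon** — a regular pentagon (circumradius 25, `L_min = 117.6`);
  the optimal open path is the perimeter minus one edge, which is also the
  nearest-neighbour walk from any start.

`optimal_open_path` is an exhaustive scan of all `n!` open paths with
lexicographic tie-breaking, refused above `n = 9` (no heuristic fallback:
its output is used as ground truth). Route distance sums consecutive
pairwise distances, revisits included; the start platform contributes no
distance.

## Reinforcement agents

An agent is a directed random walker. Trial structure is open-TSP: the
start is drawn from a start distribution (uniform by default, or a species'
observed start frequencies), counts as visited, and the trial ends the
moment all platforms have been visited. Transition probabilities are
proportional to a positive weight matrix `W` restricted to admissible moves
(not the current platform; not the just-left platform, which excludes
two-platform loops). `W` is initialised as `1/dist`, so initial transition
probabilities are inversely proportional to distance.

Learning is iterative improvement with factor `F ≥ 1`: after a trial whose
distance **ties or beats** the running best, every distinct directed
transition used in that trial has its weight multiplied by `F` (once per
ordered pair, however often traversed); `F = 1` is the no-learning control.
Three variants of the improvement rule are implemented:

- `reinforce_ties=True` (default): `d ≤ best`. Repeating the best-so-far
  route keeps strengthening it, so strongly-reinforced agents lock into a
  route (Pentagon `F=2` agents lock into an optimal-length route around
  trial 40 in the median). This is the only variant that reproduces both
  route lock-in and the strong negative learning-rate slopes of the `F=2`
  cohorts, so it is the default.
- `reinforce_ties=False`: strictly `d < best`. Reinforcement stops once the
  best route is found; agents rarely lock in (16/100 Pentagon agents in
  120 trials) and late-trial behaviour stays noisy.
- `compare="previous"`: beat only the immediately preceding trial. This
  reinforces regressions — mediocre routes get reinforced after a bad
  trial — and can drive small loop weights to extremes, producing
  pathologically long trials. Kept only as an explicit option; not
  recommended.

Weights are never renormalised globally; normalisation happens per step
over admissible moves, so unreinforced pairs keep their absolute weights.
Each agent has its own RNG stream derived from the cohort seed and agent
index; cohort output is byte-reproducible.

`convergence_trial` defines lock-in conservatively as the first trial from
which *every* remaining trial has optimal length (within relative 1e-9);
agents that never settle report infinity.

## Determinism (DET)

For a visit sequence, every index pair `i < j` with the same platform is a
recurrence; `DET = repeats / recurrences` where a repeat is a recurrence
lying on a diagonal line of the self-comparison (recurrence) plot of length
at least `minL = 3`. Forward repeats live on main-diagonal lines (repeated
sub-sequences in the same order), reverse repeats on anti-diagonal lines
(reversed order). Implementation is a line scan over diagonals;
anti-diagonal line length is measured over the whole symmetric matrix — a
run may pass through the main diagonal, so a palindrome's centre extends
the line — but only strict upper-triangle pairs are counted. The tests pin
this convention to a brute-force window-enumeration oracle over all pair
positions.

Decisions with no single canonical answer, and how they were fixed:

- DET's numerator uses **forward repeats only** by default; reverse repeats
  are always computed and reported, and `direction="both"` adds them
  (capped at the recurrence count).
- The unit of analysis is limited to each individual's **first ten
  trials** (sequence length affects DET); individuals with fewer completed
  trials are excluded and logged. Two units are first-class: `per_trial`
  (one observation per trial; recurrences arise only from within-trial
  revisits) and `concatenated` (one observation per individual from the
  concatenated first ten trials; repeated routes in different trials form
  cross-trial lines). Cross-trial repetition *is* the traplining
  signature, and at moderate cohort sizes only the concatenated unit
  separates mild from no reinforcement reliably, so the model-comparison
  workflows in this package use `concatenated`; `per_trial` remains the
  recurrence-table default for descriptive use.
- Consecutive duplicate visits (zero-distance self-transitions, a recording
  artifact) are collapsed on ingest.
- Trials with zero recurrences are retained as `n = 0` binomial
  observations: they contribute nothing to the likelihood but keep sample
  accounting consistent with the loader.

DET is undefined (NaN, flagged), not zero, when a sequence has no
recurrence.

## Learning-curve model

Log distance is linear in log trial number; intercept = expected log
distance on trial 1, slope = learning-rate exponent. Intercept and slope
each decompose into grand mean + group deviation + individual deviation;
the per-observation error s.d. is `σ_ε,group / √(1 + t)` with `t` the raw
trial number (the log-trial alternative is available via
`error_weight="log_trial"`). Priors: intercept grand mean
`N(log 2·L_min, 1)` computed per array; `N(0,1)` on the slope grand mean
and all group deviations; half-Cauchy(0,1) on all standard deviations. One
model is fit per array. For simulated cohorts the reinforcement factor
plays the group ("species") role. No sum-to-zero constraints are imposed;
the `N(0,1)` priors make the redundant decomposition proper.

**Sampling.** Individual deviations are jointly Gaussian given the
hyperparameters, so they are integrated out of the likelihood analytically
(Woodbury identities on the per-individual 2×2 random-effect blocks;
individuals sharing a group and trial pattern are vectorised). Because the
likelihood depends on the grand means and group deviations only through
their per-group sums, sampling runs on those identified sums with their
exact induced Gaussian priors; the redundant decomposition (`μ0`, `μ_sp`,
…) and the individual effects are recovered afterwards by exact conditional
Gaussian draws. MCMC is an emcee ensemble (80% differential-evolution, 20%
snooker moves; ≥ 32 walkers), initialised in a small ball around an L-BFGS
MAP estimate, with an equal-length discarded burn-in. Convergence is
summarised by split-R̂ and ESS across walkers treated as chains — a
conservative convention — with 1.01 as the acceptance-grade R̂ threshold;
there is no divergence diagnostic in this sampler family. Defaults (1500
kept steps) suit exploratory fits; headline fits use 2000–3000.

Credible intervals are equal-tailed posterior quantiles (80%/95%).

## Binomial DET model

`repeats ~ Binomial(recurrences, DET)` per unit, `DET = logit⁻¹(α)`,
`α = a0 + Sp + Src + Int + ID` with `N(0,1)` priors on the fixed
coefficients and half-Cauchy(0,1) on the individual-effect scale. With
four species and four sources (empirical, F1, F1.2, F2) the interaction has
16 cells. The individual effect is integrated out by 21-node Gauss–Hermite
quadrature (exact for practical purposes at these counts); sampling again
runs on the identified per-cell sums `α` with the exact induced Gaussian
prior (`Cov(α_sk, α_s'k') = 1 + [s=s'] + [k=k'] + [s=s'][k=k']`), and the
redundant coefficients are recovered by conditional draws. Reported
cell-level quantities marginalise the individual effect out of the linear
predictor; approximate individual-effect draws are available by sampling
the quadrature grid.

## Synthetic data

The generator emulates the structure of the empirical dataset — per-trial
rows of (array, species, individual, trial, visit sequence) — from known
strategies: nearest-neighbour heuristics (flat, near-optimal distance
profiles), distance-weighted random walks (the F=1 null), and
reinforcement learners (decreasing profiles). `revisit_noise` (default
0.1, roughly one detour per trial on a six-platform array) inserts random
admissible detours to create the revisits that give nonzero recurrence
counts. Default cohort sizes follow the study conditions (100 agents × 120
trials per factor; DET analyses use the first 10 trials).

What the synthetic tests show: the pipeline recovers known parameters from
data generated by its own models (simulate-then-fit coverage), and the
simulation reproduces the qualitative and quantitative contrasts between
reinforcement factors. What they do not show: anything about real animals —
the generator has no satiation, motivation, provisioning or perceptual
structure, its noise is i.i.d. per step, and heuristic agents other than
nearest-neighbour (e.g. convex-hull orderings, which are underdetermined
for interior platforms in these arrays) are not modelled.

## Numerical details and limitations

- Log-scale sampling for all standard deviations (Jacobian included),
  bounded to |log σ| ≤ 12; walker initialisation retries until finite
  log-probability.
- Optimal-path ties broken lexicographically; route-distance and DET
  computations are exact integer/float arithmetic, no tolerances beyond
  the 1e-12 tie guard.
- The learning model assumes every individual belongs to exactly one
  group and rejects duplicate (individual, trial) keys and non-positive
  distances; incomplete trials (not all platforms visited) are excluded
  from distance fits but kept, flagged, in the raw table.
- Problem sizes in the test-suite checks are deliberately moderate (e.g.
  30–60 agents per factor, 500–1200 kept steps); the headline simulation
  script uses the full 100-agent grid. Posterior summaries at these sizes
  carry Monte-Carlo error of a few thousandths on slope quantiles.
- Ensemble MCMC on walker-chains makes split-R̂ conservative; values
  around 1.02–1.05 at moderate chain lengths reflect slow walker mixing
  rather than biased location, as the recovery tests verify. Longer runs
  push R̂ below 1.01.
- With very small groups (one or two individuals), group-level deviations
  are prior-dominated; this matches the model definition, but group
  credible intervals should then be read as partially pooled, not as
  stand-alone estimates.
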