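# trapline

Analysis toolkit for **trapline foraging** experiments on multi-platform
arrays: do animals (or simulated agents) converge on repeated, efficient
routes through a set of feeding platforms, and by what mechanism —
trial-and-error **reinforcement learning** or pre-existing **heuristics**
like the nearest-neighbour rule?

The package is written for behavioural ecologists analysing platform-visit
sequences from small-scale foraging arrays (the kind used with primates,
bees, or rodents). It provides, as a plain Python library:

- **Geometry** — labelled platform arrays, Euclidean distance matrices,
  route distances, and brute-force optimal open (Hamiltonian) paths; the
  shortest open route length `L_min` anchors everything downstream.
- **Agent simulation** — Reynolds-style iterative-reinforcement agents:
  random walkers whose transition weights start inversely proportional to
  distance, never immediately backtrack, and are multiplied by a
  reinforcement factor `F ∈ {1, 1.2, 2}` for every directed transition used
  in a trial that ties or beats the best distance so far.
- **Determinism (DET)** — a recurrence-based statistic of route repetition
  for categorical visit sequences. Every pair of positions holding the same
  platform is a *recurrence*; a recurrence inside a repeated (or reversed)
  sub-sequence of at least `minL = 3` visits is a *repeat*;
  `DET = repeats / recurrences` (undefined without recurrences).
- **Learning-curve model** — a hierarchical Bayesian power-law fit,
  linear in log-log space:

  `log d ~ (μ0 + μ_sp + μ_id) + (b0 + b_sp + b_id)·log t + ε`,
  `ε ~ N(0, σ_ε,sp / √(1+t))`

  with priors `μ0 ~ N(log 2·L_min, 1)`, `μ_sp, b0, b_sp ~ N(0,1)`,
  `μ_id ~ N(0, σ_µID)`, `b_id ~ N(0, σ_bID)` and half-Cauchy(0,1) priors on
  all standard deviations. The intercept is the expected log distance on
  the first trial; the slope is the learning-rate exponent.
- **Binomial DET model** — `repeats ~ Binom(recurrences, DET)` with
  `DET = logit⁻¹(a0 + Sp + Src + Int + ID)`: species, data-source
  (empirical vs. reinforcement factor), their interaction, and a Gaussian
  individual effect.
- **Synthetic data & pipeline I/O** — empirical-format CSV generation from
  known strategies, a validating loader, and one-call simulation/empirical
  study drivers.

Both models are sampled with an affine-invariant/differential-evolution
ensemble MCMC (`emcee`), after integrating the individual-level random
effects out of the likelihood (analytically for the Gaussian model,
Gauss–Hermite quadrature for the binomial one); convergence is summarised
by split-R̂ and effective sample size (`arviz`). See `docs/methods.md`.

## Worked example

```python
import trapline as tl
from trapline import McmcSettings

dt = tl.double_trapezoid()               # six platforms, 720 possible routes
opt = tl.optimal_open_path(dt)
print(opt.length)                        # 59.55 — minimum open-path distance

trials = tl.run_cohort(dt, factors=[1.0, 2.0], n_agents=15, n_trials=60, seed=5)
data = tl.prepare_learning_data(trials, array=dt, group_col="source")
post = tl.fit_learning_model(data, McmcSettings(n_steps=800, seed=1))
print(post.group_ci("F1", "slope", 0.95))   # (-0.070, +0.032): no learning
print(post.group_ci("F2", "slope", 0.95))   # (-0.164, -0.044): distances shrink
```

The F=1 cohort's slope interval straddles zero — without reinforcement the
walk never improves — while the F=2 interval lies entirely below zero: its
trial distances decay as a power of trial number. Route repetition shows
the same contrast through the DET model:

```python
rec = tl.det_table(trials, mode="concatenated")   # first 10 trials per agent
dpost = tl.fit_det_model(tl.prepare_det_data(rec), McmcSettings(n_steps=600, seed=9))
print(dpost.cell_summary()[["species", "source", "det_mean"]])
#   agent  F1  0.144
#   agent  F2  0.252    — stronger reinforcement, more repetitive routes
```

The `examples/` directory holds one short narrative script per capability
(geometry, agents, DET, both models, and the end-to-end synthetic
pipeline); each prints the numbers it computes and a line on what they
mean.

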