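"""Shared MCMC machinery: ensemble sampling, initialisation, diagnostics.

Both hierarchical models in this package have low-dimensional posteriors
once individual-level random effects are marginalized out, which suits an
affine-invariant / differential-evolution ensemble sampler well.  Sampling
is done with :mod:`emcee`; walkers are initialised in a small Gaussian ball
around a MAP estimate found with L-BFGS, and convergence is summarised with
split-R-hat and effective sample size computed by :mod:`arviz` over walkers
treated as chains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["McmcSettings", "SampleResult", "sample_posterior", "half_cauchy_logpdf"]

#: split-R-hat threshold for an acceptance-grade fit
RHAT_THRESHOLD = 1.01


@dataclass(frozen=True)
class McmcSettings:
    """Ensemble-sampler settings.

    ``n_steps`` counts post-burn-in steps per walker; a burn-in of
    ``burn_steps`` (default: equal to ``n_steps``) is run and discarded.
    """

    n_walkers: int | None = None  # default: max(2*ndim + 2, 32)
    n_steps: int = 1500
    burn_steps: int | None = None
    thin: int = 1
    seed: int = 0

    def walkers(self, ndim: int) -> int:
        return self.n_walkers or max(2 * ndim + 2, 32)

    @property
    def burn(self) -> int:
        return self.burn_steps if self.burn_steps is not None else self.n_steps


@dataclass
class SampleResult:
    """Posterior draws plus convergence diagnostics.

    ``chain`` has shape ``(n_walkers, n_draws, ndim)``; ``draws`` is the
    flattened ``(n_walkers * n_draws, ndim)`` view.  R-hat and ESS are
    per-parameter, computed across walkers.
    """

    chain: np.ndarray
    param_names: list[str]
    rhat: np.ndarray
    ess: np.ndarray
    map_estimate: np.ndarray

    @property
    def draws(self) -> np.ndarray:
        nw, nd, k = self.chain.shape
        return self.chain.reshape(nw * nd, k)

    @property
    def n_draws(self) -> int:
        return self.chain.shape[0] * self.chain.shape[1]

    @property
    def max_rhat(self) -> float:
        return float(np.nanmax(self.rhat))

    @property
    def min_ess(self) -> float:
        return float(np.nanmin(self.ess))

    @property
    def converged(self) -> bool:
        return bool(self.max_rhat <= RHAT_THRESHOLD)

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]


def half_cauchy_logpdf(x: float | np.ndarray, scale: float = 1.0):
    """log density of a half-Cauchy(0, scale) variable (x > 0)."""
    return math.log(2.0 / (math.pi * scale)) - np.log1p((x / scale) ** 2)


def _find_map(
    log_prob: Callable[[np.ndarray], float],
    x0: np.ndarray,
    maxiter: int = 500,
) -> np.ndarray:
    from scipy.optimize import minimize

    def neg(x: np.ndarray) -> float:
        lp = log_prob(x)
        return -lp if np.isfinite(lp) else 1e12

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(neg, x0, method="L-BFGS-B", options={"maxiter": maxiter})
    return res.x if np.all(np.isfinite(res.x)) else x0


def sample_posterior(
    log_prob: Callable[[np.ndarray], float],
    x0: np.ndarray,
    param_names: Sequence[str],
    settings: McmcSettings,
    init_scale: float = 0.05,
) -> SampleResult:
    """MAP-initialised ensemble MCMC with split-R-hat/ESS diagnostics.

    Parameters are sampled on an unconstrained scale (the caller is
    responsible for transforming, e.g. log-standard-deviations, and for
    including Jacobian terms in ``log_prob``).
    """
    import arviz as az
    import emcee

    ndim = len(x0)
    assert len(param_names) == ndim
    nw = settings.walkers(ndim)
    rng = np.random.RandomState(settings.seed)

    center = _find_map(log_prob, np.asarray(x0, dtype=float))
    p0 = center[None, :] + init_scale * rng.standard_normal((nw, ndim))
    # walkers must all start at finite log-probability
    for i in range(nw):
        tries = 0
        while not np.isfinite(log_prob(p0[i])) and tries < 100:
            p0[i] = center + init_scale * rng.standard_normal(ndim)
            tries += 1

    sampler = emcee.EnsembleSampler(
        nw,
        ndim,
        log_prob,
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    state = emcee.State(p0, random_state=np.random.RandomState(settings.seed).get_state())
    state = sampler.run_mcmc(state, settings.burn, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, settings.n_steps, progress=False)
    chain = sampler.get_chain(thin=settings.thin)  # (steps, walkers, ndim)
    chain = np.moveaxis(chain, 0, 1)  # (walkers, steps, ndim)

    posterior = {
        name: chain[:, :, k] for k, name in enumerate(param_names)
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=posterior)
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
    rhat = np.array([float(rhat_ds[name].values) for name in param_names])
    ess = np.array([float(ess_ds[name].values) for name in param_names])
    return SampleResult(
        chain=chain,
        param_names=list(param_names),
        rhat=rhat,
        ess=ess,
        map_estimate=center,
    )
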