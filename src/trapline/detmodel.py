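"""Binomial model of determinism: repeats out of recurrences, on a logit scale.

Each observation is a count pair from the recurrence analysis: the number of
recurrences in a unit (a trial, or an individual's concatenated first
trials) and how many of them were repeats.  Repeats are modelled as

    repeats ~ Binomial(recurrences, DET)
    DET     = logit^-1(alpha)
    alpha   = a0 + Sp + Src + Int + ID

where ``Sp`` is a species coefficient, ``Src`` a data-source coefficient
(empirical data, or each reinforcement-factor level of the simulations),
``Int`` one coefficient per species-by-source cell, and ``ID`` a Gaussian
individual effect with scale ``sigma_ID``.  Priors are N(0, 1) on all fixed
coefficients and half-Cauchy(0, 1) on ``sigma_ID``.

The parameterisation is deliberately redundant (a cell mean is spread over
four coefficients); the N(0, 1) priors keep the posterior proper, and all
reported quantities are per-cell sums ``a0 + Sp + Src + Int``, which are
identified.  Individual effects are integrated out of the likelihood by
Gauss-Hermite quadrature, so MCMC runs on the fixed effects plus
``sigma_ID`` only.

Observations with zero recurrences carry no information about DET (the
binomial has no draws) and contribute nothing to the likelihood, but they
remain in the data so sample accounting matches the loader.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logsumexp

from ._mcmc import McmcSettings, SampleResult, half_cauchy_logpdf, sample_posterior

__all__ = [
    "DetData",
    "DetPosterior",
    "prepare_det_data",
    "fit_det_model",
    "alpha_draws",
    "simulate_det_data",
]

logger = logging.getLogger(__name__)

_LOG_SIGMA_BOUND = 12.0
_GH_NODES = 21


@dataclass
class DetData:
    """Indexed repeat/recurrence observations for the binomial DET model."""

    repeats: np.ndarray
    recurrences: np.ndarray
    obs_individual: np.ndarray
    species_names: list[str]
    source_names: list[str]
    individual_names: list[str]
    individual_species: np.ndarray
    individual_source: np.ndarray

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_sources(self) -> int:
        return len(self.source_names)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_names)

    def cell_index(self, species: str, source: str) -> tuple[int, int]:
        try:
            s = self.species_names.index(species)
        except ValueError:
            raise KeyError(f"unknown species {species!r}") from None
        try:
            k = self.source_names.index(source)
        except ValueError:
            raise KeyError(f"unknown source {source!r}") from None
        return s, k


def prepare_det_data(table: pd.DataFrame, min_trials: int = 10) -> DetData:
    """Index a recurrence table for model fitting.

    Expects columns ``individual, species, source, recurrences, repeats``
    (the output of the recurrence analysis).  In per-trial mode an
    individual must contribute at least ``min_trials`` rows — i.e. have
    completed that many trials — otherwise it is excluded and logged.
    """
    required = {"individual", "species", "source", "recurrences", "repeats"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"recurrence table missing columns {sorted(missing)}")
    if (table["repeats"] > table["recurrences"]).any():
        bad = table.index[table["repeats"] > table["recurrences"]][:5]
        raise ValueError(f"repeats exceed recurrences at rows {list(bad)}")
    per_trial = "mode" not in table.columns or (table["mode"] == "per_trial").all()
    if per_trial:
        counts = table.groupby("individual")["repeats"].size()
        ok = counts.index[counts >= min_trials]
        dropped = sorted(set(counts.index) - set(ok))
        if dropped:
            logger.warning(
                "excluding %d individuals with < %d trials: %s",
                len(dropped),
                min_trials,
                dropped,
            )
        table = table[table["individual"].isin(ok)]
    if table.empty:
        raise ValueError("no observations left after exclusions")

    species_names = sorted(table["species"].astype(str).unique())
    source_names = sorted(table["source"].astype(str).unique())
    ind_names = sorted(table["individual"].astype(str).unique())
    i_of = {v: k for k, v in enumerate(ind_names)}
    obs_ind = table["individual"].astype(str).map(i_of).to_numpy()

    ind_sp = np.zeros(len(ind_names), dtype=np.intp)
    ind_src = np.zeros(len(ind_names), dtype=np.intp)
    for ii, sp, src in zip(
        obs_ind, table["species"].astype(str), table["source"].astype(str)
    ):
        ind_sp[ii] = species_names.index(sp)
        ind_src[ii] = source_names.index(src)
    return DetData(
        repeats=table["repeats"].to_numpy(dtype=float),
        recurrences=table["recurrences"].to_numpy(dtype=float),
        obs_individual=obs_ind,
        species_names=species_names,
        source_names=source_names,
        individual_names=ind_names,
        individual_species=ind_sp,
        individual_source=ind_src,
    )


class _DetLogPosterior:
    """Marginal log-posterior with the individual effect integrated out.

    The fixed-effect structure ``a0 + Sp + Src + Int`` is redundant: the
    likelihood depends only on the per-cell sums ``alpha``.  Sampling
    therefore runs on the identified cell sums with their exact induced
    Gaussian prior (``alpha = B u`` with ``u ~ N(0, I)`` implies ``alpha ~
    N(0, B B')`` where ``Cov(alpha_{sk}, alpha_{s'k'}) = 1 + [s=s'] +
    [k=k'] + [s=s'][k=k']``); the redundant coefficients are recovered
    afterwards by exact conditional draws (:meth:`decompose`).

    Parameter vector: ``[alpha (S*K), log sigma_ID]``.
    """

    def __init__(self, data: DetData, n_nodes: int = _GH_NODES):
        self.data = data
        S, K = data.n_species, data.n_sources
        self.S, self.K = S, K
        self.ndim = S * K + 1
        self.param_names = [
            f"alpha[{s}:{k}]"
            for s in data.species_names
            for k in data.source_names
        ] + ["log_sigma_id"]
        # induced prior on cell sums
        sp_i, src_i = np.divmod(np.arange(S * K), K)
        cov = (
            1.0
            + (sp_i[:, None] == sp_i[None, :]).astype(float)
            + (src_i[:, None] == src_i[None, :]).astype(float)
            + (
                (sp_i[:, None] == sp_i[None, :])
                & (src_i[:, None] == src_i[None, :])
            ).astype(float)
        )
        self._prior_prec = np.linalg.inv(cov)
        # design matrix alpha = B u for the redundant decomposition
        B = np.zeros((S * K, 1 + S + K + S * K))
        B[:, 0] = 1.0
        B[np.arange(S * K), 1 + sp_i] = 1.0
        B[np.arange(S * K), 1 + S + src_i] = 1.0
        B[np.arange(S * K), 1 + S + K + np.arange(S * K)] = 1.0
        self._B = B
        # informative observations only, sorted by individual for reduceat
        keep = data.recurrences > 0
        r = data.repeats[keep]
        n = data.recurrences[keep]
        obs_ind = data.obs_individual[keep]
        order = np.argsort(obs_ind, kind="stable")
        self.r = r[order]
        self.n = n[order]
        self.obs_ind = obs_ind[order]
        self._uniq_ind, self._starts = np.unique(self.obs_ind, return_index=True)
        # Gauss-Hermite nodes for N(0,1): int f(z) phi(z) dz
        gz, gw = np.polynomial.hermite.hermgauss(n_nodes)
        self.z = gz * math.sqrt(2.0)
        self.logw = np.log(gw) - 0.5 * math.log(math.pi)

    def unpack(self, theta: np.ndarray) -> dict:
        return {
            "alpha": theta[: self.S * self.K],
            "log_sigma_id": theta[-1],
        }

    def cell_alpha(self, p: dict) -> np.ndarray:
        """(S, K) matrix of per-cell linear predictors."""
        return p["alpha"].reshape(self.S, self.K)

    def decompose(self, draws: np.ndarray, seed: int = 0) -> dict[str, np.ndarray]:
        """Exact conditional draws of (a0, Sp, Src, Int) given cell alphas.

        ``u | alpha`` is Gaussian with mean ``B' (BB')^{-1} alpha`` and
        covariance ``I - B' (BB')^{-1} B``.
        """
        rng = np.random.default_rng(seed)
        S, K = self.S, self.K
        alpha = draws[:, : S * K]
        Bt_prec = self._B.T @ self._prior_prec
        mean = alpha @ Bt_prec.T
        cov = np.eye(self._B.shape[1]) - Bt_prec @ self._B
        # symmetrize and factor (cov is rank-deficient: u is constrained)
        evals, evecs = np.linalg.eigh((cov + cov.T) / 2)
        L = evecs * np.sqrt(np.clip(evals, 0, None))
        u = mean + rng.standard_normal(mean.shape) @ L.T
        return {
            "a0": u[:, 0],
            "sp": u[:, 1 : 1 + S],
            "src": u[:, 1 + S : 1 + S + K],
            "int": u[:, 1 + S + K :].reshape(-1, S, K),
        }

    def _individual_node_loglik(self, p: dict) -> np.ndarray:
        """(n_individuals, n_nodes) conditional log-likelihoods.

        Individuals whose observations all have zero recurrences get a
        zero row (no likelihood contribution).
        """
        d = self.data
        alpha = self.cell_alpha(p)
        eta_ind = alpha[d.individual_species, d.individual_source]
        sigma = math.exp(p["log_sigma_id"])
        eta = eta_ind[self.obs_ind, None] + sigma * self.z[None, :]
        ll = self.r[:, None] * log_expit(eta) + (self.n - self.r)[
            :, None
        ] * log_expit(-eta)
        acc = np.zeros((d.n_individuals, len(self.z)))
        acc[self._uniq_ind] = np.add.reduceat(ll, self._starts, axis=0)
        return acc

    def __call__(self, theta: np.ndarray) -> float:
        p = self.unpack(theta)
        if abs(p["log_sigma_id"]) > _LOG_SIGMA_BOUND:
            return -math.inf
        lp = -0.5 * float(p["alpha"] @ self._prior_prec @ p["alpha"])
        sigma = math.exp(p["log_sigma_id"])
        lp += float(half_cauchy_logpdf(sigma)) + p["log_sigma_id"]
        acc = self._individual_node_loglik(p)
        lp += float(np.sum(logsumexp(acc + self.logw[None, :], axis=1)))
        if not np.isfinite(lp):
            return -math.inf
        return lp

    def initial_point(self) -> np.ndarray:
        x0 = np.zeros(self.ndim)
        d = self.data
        # per-cell smoothed empirical logits
        for c in range(self.S * self.K):
            s, k = divmod(c, self.K)
            mask = (d.individual_species[self.obs_ind] == s) & (
                d.individual_source[self.obs_ind] == k
            )
            pooled = (self.r[mask].sum() + 0.5) / (self.n[mask].sum() + 1.0)
            x0[c] = math.log(pooled / (1 - pooled))
        x0[-1] = math.log(0.3)
        return x0


@dataclass
class DetPosterior:
    """Posterior draws and diagnostics for one binomial DET fit."""

    data: DetData
    result: SampleResult

    @property
    def converged(self) -> bool:
        return self.result.converged

    @property
    def max_rhat(self) -> float:
        return self.result.max_rhat

    def sigma_id_draws(self) -> np.ndarray:
        return np.exp(self.result.column("log_sigma_id"))

    def alpha_draws(self, species: str, source: str) -> np.ndarray:
        """Per-draw cell linear predictor a0 + Sp + Src + Int.

        The individual effect is marginalized out of the reported linear
        predictor (it enters only the likelihood).
        """
        self.data.cell_index(species, source)  # validate
        return self.result.column(f"alpha[{species}:{source}]")

    def coefficient_draws(self, seed: int = 0) -> dict[str, np.ndarray]:
        """Draws of the redundant (a0, Sp, Src, Int) decomposition."""
        post = _DetLogPosterior(self.data)
        return post.decompose(self.result.draws, seed=seed)

    def det_draws(self, species: str, source: str) -> np.ndarray:
        """Posterior draws of cell-level DET (inverse-logit of alpha)."""
        return expit(self.alpha_draws(species, source))

    def id_effect_draws(self, n_draws: int = 200, seed: int = 0) -> np.ndarray:
        """Approximate draws of individual effects (quadrature-grid sampling).

        For each retained hyperparameter draw, each individual's effect is
        sampled from the Gauss-Hermite discretisation of its conditional
        posterior.  Shape ``(n_draws, n_individuals)``.
        """
        rng = np.random.default_rng(seed)
        post = _DetLogPosterior(self.data)
        all_draws = self.result.draws
        pick = rng.choice(len(all_draws), size=n_draws, replace=True)
        out = np.zeros((n_draws, self.data.n_individuals))
        for k, row in enumerate(all_draws[pick]):
            p = post.unpack(row)
            sigma = math.exp(p["log_sigma_id"])
            acc = post._individual_node_loglik(p) + post.logw[None, :]
            w = np.exp(acc - acc.max(axis=1, keepdims=True))
            w /= w.sum(axis=1, keepdims=True)
            cum = np.cumsum(w, axis=1)
            u = rng.random((self.data.n_individuals, 1))
            idx = (cum < u).sum(axis=1)
            out[k] = sigma * post.z[idx]
        return out

    def cell_summary(self) -> pd.DataFrame:
        """Per-cell alpha and DET posterior summaries."""
        rows = []
        for s in self.data.species_names:
            for k in self.data.source_names:
                a = self.alpha_draws(s, k)
                d = expit(a)
                rows.append(
                    {
                        "species": s,
                        "source": k,
                        "alpha_mean": float(a.mean()),
                        "alpha_q2.5": float(np.quantile(a, 0.025)),
                        "alpha_q97.5": float(np.quantile(a, 0.975)),
                        "det_mean": float(d.mean()),
                        "det_q2.5": float(np.quantile(d, 0.025)),
                        "det_q97.5": float(np.quantile(d, 0.975)),
                    }
                )
        return pd.DataFrame(rows)


def fit_det_model(
    data: DetData,
    mcmc: McmcSettings | None = None,
    seed: int | None = None,
) -> DetPosterior:
    """Fit the binomial DET model by quadrature-marginalized MCMC."""
    if not np.any(data.recurrences > 0):
        raise ValueError("need at least one observation with recurrences > 0")
    mcmc = mcmc or McmcSettings()
    if seed is not None:
        mcmc = McmcSettings(
            n_walkers=mcmc.n_walkers,
            n_steps=mcmc.n_steps,
            burn_steps=mcmc.burn_steps,
            thin=mcmc.thin,
            seed=seed,
        )
    post = _DetLogPosterior(data)
    result = sample_posterior(post, post.initial_point(), post.param_names, mcmc)
    return DetPosterior(data=data, result=result)


def alpha_draws(post: DetPosterior, species: str, source: str) -> np.ndarray:
    """Cell-level alpha draws (see :meth:`DetPosterior.alpha_draws`)."""
    return post.alpha_draws(species, source)


def simulate_det_data(
    det_by_cell: dict[tuple[str, str], float],
    n_individuals_per_cell: int = 20,
    n_obs_per_individual: int = 10,
    recurrences_per_obs: int = 20,
    sigma_id: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a synthetic recurrence table with known cell-level DET values.

    Serves as the recovery oracle for :func:`fit_det_model`: repeats are
    binomial draws at logit(DET) plus an optional Gaussian individual
    effect.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (species, source), p in det_by_cell.items():
        base = math.log(p / (1 - p))
        for i in range(n_individuals_per_cell):
            eta = base + rng.normal(0, sigma_id) if sigma_id > 0 else base
            prob = expit(eta)
            for t in range(n_obs_per_individual):
                n = recurrences_per_obs
                rows.append(
                    {
                        "individual": f"{species}_{source}_{i:03d}",
                        "species": species,
                        "source": source,
                        "unit_id": f"trial{t + 1}",
                        "recurrences": n,
                        "repeats": int(rng.binomial(n, prob)),
                        "mode": "per_trial",
                    }
                )
    return pd.DataFrame(rows)
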