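"""Iterative-reinforcement foraging agents on platform arrays.

The agent is a directed random walker over the platforms of an array.  Each
trial starts at a platform drawn from a start distribution and ends as soon
as every platform has been visited at least once (an open-TSP trial: no
return to the start is required).  Transition probabilities are proportional
to a positive weight matrix ``W``, initialised inversely proportional to
distance, and the agent never returns to the platform it has just left
("avoid the last location"), which rules out two-platform loops.

Learning is iterative improvement: when a trial beats the best (shortest)
distance seen so far, every distinct directed transition used in that trial
has its weight multiplied by the reinforcement factor ``F``.  ``F = 1``
means no reinforcement; the study's other levels are 1.2 (mild) and 2
(strong).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import PlatformArray, route_distance
from .records import TRIALS_COLUMNS, TrialRecord, factor_label

__all__ = [
    "AgentState",
    "init_agent",
    "run_trial",
    "reinforce",
    "run_agent",
    "run_cohort",
    "convergence_trial",
]

CompareMode = Literal["best", "previous"]


@dataclass
class AgentState:
    """Mutable state of one reinforcement-learning agent."""

    array: PlatformArray
    W: np.ndarray  # directed transition weights; diagonal unused
    F: float
    start_probs: np.ndarray
    best_distance: float = math.inf
    last_distance: float = math.inf
    #: improvement rule: beat the running minimum ("best", default) or only
    #: the immediately preceding trial ("previous")
    compare: CompareMode = "best"
    #: reinforce trials that tie the reference distance as well as beat it;
    #: with ties on, repeating the best-so-far route keeps strengthening it,
    #: which is what lets strongly-reinforced agents lock into a route
    reinforce_ties: bool = True


def _as_start_probs(
    array: PlatformArray, start_probs: Sequence[float] | Mapping[str, float] | str
) -> np.ndarray:
    n = array.n
    if isinstance(start_probs, str):
        if start_probs != "uniform":
            raise ValueError(f"unknown start_probs spec {start_probs!r}")
        return np.full(n, 1.0 / n)
    if isinstance(start_probs, Mapping):
        p = np.zeros(n)
        for lab, v in start_probs.items():
            p[array.index_of(str(lab))] = v
    else:
        p = np.asarray(start_probs, dtype=float)
        if p.shape != (n,):
            raise ValueError("start_probs length must match platform count")
    if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("start_probs must be non-negative and sum to 1")
    return p / p.sum()


def init_agent(
    array: PlatformArray,
    F: float,
    start_probs: Sequence[float] | Mapping[str, float] | str = "uniform",
    compare: CompareMode = "best",
    reinforce_ties: bool = True,
) -> AgentState:
    """Create an agent with distance-weighted initial transition weights.

    ``W[i, j] = 1 / dist[i, j]`` for ``i != j``, so initial transition
    probabilities are inversely proportional to distance.
    """
    if F < 1:
        raise ValueError("reinforcement factor must be >= 1")
    with np.errstate(divide="ignore"):
        W = 1.0 / array.dist
    np.fill_diagonal(W, 0.0)
    return AgentState(
        array=array,
        W=W,
        F=float(F),
        start_probs=_as_start_probs(array, start_probs),
        compare=compare,
        reinforce_ties=reinforce_ties,
    )


def run_trial(agent: AgentState, rng: np.random.Generator) -> tuple[str, ...]:
    """Sample one trial: walk until every platform has been visited.

    The start platform is drawn from the agent's start distribution and
    counts as visited.  Each subsequent platform is drawn with probability
    proportional to ``W[current, j]`` over platforms other than the current
    one and the one just left; revisits to already-visited platforms are
    allowed and contribute distance.
    """
    array = agent.array
    n = array.n
    cur = int(rng.choice(n, p=agent.start_probs))
    seq = [cur]
    visited = np.zeros(n, dtype=bool)
    visited[cur] = True
    n_seen = 1
    prev = -1
    while n_seen < n:
        w = agent.W[cur].copy()
        w[cur] = 0.0
        if prev >= 0 and n > 2:
            w[prev] = 0.0
        nxt = int(rng.choice(n, p=w / w.sum()))
        seq.append(nxt)
        if not visited[nxt]:
            visited[nxt] = True
            n_seen += 1
        prev, cur = cur, nxt
    return tuple(array.labels[i] for i in seq)


def reinforce(
    agent: AgentState, seq: Sequence[str], trial_distance: float | None = None
) -> AgentState:
    """Apply the iterative-improvement update for one completed trial.

    If the trial strictly beat the reference distance (the running best, or
    the previous trial under ``compare="previous"``), the weight of every
    distinct directed transition used in the trial is multiplied by ``F``
    (once per ordered pair, however often it was traversed).  Updates
    mutate the agent in place and also return it.
    """
    if trial_distance is None:
        trial_distance = route_distance(agent.array, seq)
    reference = (
        agent.best_distance if agent.compare == "best" else agent.last_distance
    )
    improved = (
        trial_distance <= reference if agent.reinforce_ties
        else trial_distance < reference
    )
    if improved and agent.F != 1.0:
        idx = agent.array.indices(seq)
        pairs = set(zip(idx[:-1].tolist(), idx[1:].tolist()))
        for i, j in pairs:
            agent.W[i, j] *= agent.F
    if trial_distance < agent.best_distance:
        agent.best_distance = trial_distance
    agent.last_distance = trial_distance
    return agent


def run_agent(
    array: PlatformArray,
    F: float,
    n_trials: int,
    start_probs: Sequence[float] | Mapping[str, float] | str = "uniform",
    seed: int | Sequence[int] = 0,
    *,
    species: str = "agent",
    individual: str | None = None,
    source: str | None = None,
    compare: CompareMode = "best",
    reinforce_ties: bool = True,
) -> list[TrialRecord]:
    """Run one agent for ``n_trials`` trials and record each sequence.

    Reproducible: the same seed yields a bit-identical trial list.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    agent = init_agent(
        array, F, start_probs, compare=compare, reinforce_ties=reinforce_ties
    )
    source = source or factor_label(F)
    individual = individual or f"{source}_agent"
    out = []
    for t in range(1, n_trials + 1):
        seq = run_trial(agent, rng)
        d = route_distance(array, seq)
        reinforce(agent, seq, d)
        out.append(
            TrialRecord(
                experiment=array.name,
                species=species,
                individual=individual,
                trial=t,
                sequence=seq,
                source=source,
                distance=d,
            )
        )
    return out


def run_cohort(
    array: PlatformArray,
    factors: Iterable[float],
    n_agents: int,
    n_trials: int,
    start_mode: str = "uniform",
    species_start_probs: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    compare: CompareMode = "best",
    reinforce_ties: bool = True,
) -> pd.DataFrame:
    """Simulate a full cohort grid and return a trials table.

    For each reinforcement factor, ``n_agents`` independent agents each
    complete ``n_trials`` trials.  With ``start_mode="uniform"`` every
    platform is an equally likely trial start and the species tag is
    ``"agent"``; with ``start_mode="empirical"`` one cohort is run per
    species in ``species_start_probs`` using that species' observed
    start-location distribution.

    Each agent has its own RNG stream derived from ``(seed, factor index,
    species index, agent index)``, so cohorts are reproducible and agents
    independent.
    """
    if start_mode == "uniform":
        groups: list[tuple[str, object]] = [("agent", "uniform")]
    elif start_mode == "empirical":
        if not species_start_probs:
            raise ValueError(
                "start_mode='empirical' requires a species start-probability table"
            )
        groups = sorted(species_start_probs.items())
    else:
        raise ValueError(f"unknown start_mode {start_mode!r}")
    rows: list[TrialRecord] = []
    for fi, F in enumerate(factors):
        src = factor_label(F)
        for si, (species, sp) in enumerate(groups):
            for a in range(n_agents):
                rows.extend(
                    run_agent(
                        array,
                        F,
                        n_trials,
                        start_probs=sp,
                        seed=(seed, fi, si, a),
                        species=species,
                        individual=f"{src}_{species}_{a:03d}",
                        source=src,
                        compare=compare,
                        reinforce_ties=reinforce_ties,
                    )
                )
    return _records_to_frame(rows)


def _records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    from .records import SEQ_DELIMITER

    return pd.DataFrame(
        {
            "experiment": [r.experiment for r in records],
            "species": [r.species for r in records],
            "individual": [r.individual for r in records],
            "trial": [r.trial for r in records],
            "sequence": [SEQ_DELIMITER.join(r.sequence) for r in records],
            "source": [r.source for r in records],
            "distance": [r.distance for r in records],
        },
        columns=list(TRIALS_COLUMNS),
    )


def convergence_trial(
    records: Sequence[TrialRecord], optimal_length: float, rel_tol: float = 1e-9
) -> float:
    """First trial from which every remaining trial is of optimal length.

    Returns ``math.inf`` when the agent never locks into an optimal route.
    Used to summarise how quickly strongly-reinforced agents settle on a
    shortest path.
    """
    distances = [r.distance for r in sorted(records, key=lambda r: r.trial)]
    lock = math.inf
    for t, d in zip(range(len(distances), 0, -1), reversed(distances)):
        if d <= optimal_length * (1 + rel_tol):
            lock = t
        else:
            break
    return lock
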