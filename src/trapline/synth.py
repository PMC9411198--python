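"""Synthetic trial datasets with known generating strategies.

Generates empirical-format trial tables from agents whose behaviour is known
by construction, so every pipeline stage can be exercised and checked
without animal data:

* ``nearest_neighbour`` — the classic heuristic: always move to the nearest
  not-yet-visited platform.  Produces flat log-log distance profiles with
  near-optimal intercepts (the pattern expected of heuristic users).
* ``distance_weighted_random`` — random transitions with probability
  inversely proportional to distance (a reinforcement-factor-1 agent); the
  null model of random movement.
* ``reinforcement(F)`` — the iterative-reinforcement learner; decreasing
  distance profiles for F > 1.

``revisit_noise`` inserts random admissible detours, creating the revisits
to already-emptied platforms that give trials nonzero recurrence counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import PlatformArray, route_distance
from .records import TRIALS_COLUMNS, SEQ_DELIMITER, factor_label
from .simulator import init_agent, reinforce, run_trial
from . import arrays as _arrays

__all__ = [
    "SyntheticConfig",
    "nearest_neighbour_sequence",
    "generate_dataset",
    "empirical_start_probs",
]


def nearest_neighbour_sequence(
    array: PlatformArray,
    start: str,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[str, ...]:
    """Greedy nearest-unvisited walk from ``start``.

    Ties are broken by the lexicographically lowest label.  With
    probability ``noise`` per step a uniformly random unvisited platform is
    chosen instead of the nearest; with ``noise=0`` the sequence (and hence
    its distance) is a deterministic function of the start platform.
    """
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must be a probability")
    rng = rng or np.random.default_rng()
    cur = array.index_of(start)
    unvisited = set(range(array.n)) - {cur}
    seq = [cur]
    while unvisited:
        if noise > 0 and rng.random() < noise:
            nxt = int(rng.choice(sorted(unvisited)))
        else:
            nxt = min(
                unvisited,
                key=lambda j: (array.dist[cur, j], array.labels[j]),
            )
        seq.append(nxt)
        unvisited.discard(nxt)
        cur = nxt
    return tuple(array.labels[i] for i in seq)


def _inject_revisits(
    array: PlatformArray,
    seq: tuple[str, ...],
    p: float,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    """Insert random admissible detours (revisits) with probability p per step."""
    if p <= 0 or len(seq) < 2:
        return seq
    idx = list(array.indices(seq))
    out = [idx[0]]
    for nxt in idx[1:]:
        while rng.random() < p:
            cur = out[-1]
            prev = out[-2] if len(out) > 1 else -1
            choices = [
                j for j in range(array.n) if j != cur and j != prev and j != nxt
            ]
            if not choices:
                break
            out.append(int(rng.choice(choices)))
        if out[-1] != nxt:
            out.append(nxt)
    return tuple(array.labels[i] for i in out)


_REINF_RE = re.compile(r"^reinforcement\(([\d.]+)\)$")


def _parse_strategy(spec: str) -> tuple[str, float | None]:
    m = _REINF_RE.match(spec)
    if m:
        return "reinforcement", float(m.group(1))
    if spec in ("nearest_neighbour", "distance_weighted_random"):
        return spec, None
    raise ValueError(
        f"unknown strategy {spec!r}; expected 'nearest_neighbour', "
        "'distance_weighted_random' or 'reinforcement(F)'"
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for one synthetic dataset.

    ``groups`` maps a group (pseudo-species) name to a strategy spec:
    ``"nearest_neighbour"``, ``"distance_weighted_random"`` or
    ``"reinforcement(F)"`` with a numeric factor, e.g.
    ``"reinforcement(2)"``.
    """

    array: str = "double_trapezoid"
    groups: Mapping[str, str] = field(
        default_factory=lambda: {
            "heuristic": "nearest_neighbour",
            "learner": "reinforcement(2)",
        }
    )
    n_individuals: int = 10
    n_trials: int = 12
    revisit_noise: float = 0.1
    start_mode: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_trials < 1:
            raise ValueError("n_individuals and n_trials must be >= 1")
        if not 0.0 <= self.revisit_noise <= 1.0:
            raise ValueError("revisit_noise must be a probability")
        for spec in self.groups.values():
            _parse_strategy(spec)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        return cls(**dict(d))


def generate_dataset(
    cfg: SyntheticConfig, array: PlatformArray | None = None
) -> pd.DataFrame:
    """Generate a trials table in the empirical CSV schema.

    Byte-identical output for a fixed config (each individual has its own
    seeded RNG stream).  The group name goes in the ``species`` column and
    the strategy tag in ``source``, mirroring how simulated cohorts are
    labelled.
    """
    arr = array if array is not None else _arrays.get_array(cfg.array)
    rows = []
    for gi, (gname, spec) in enumerate(sorted(cfg.groups.items())):
        kind, F = _parse_strategy(spec)
        source = {
            "nearest_neighbour": "NNR",
            "distance_weighted_random": "F1",
        }.get(kind, factor_label(F) if F is not None else kind)
        for i in range(cfg.n_individuals):
            rng = np.random.default_rng((cfg.seed, gi, i))
            agent = None
            if kind in ("reinforcement", "distance_weighted_random"):
                agent = init_agent(arr, F if F is not None else 1.0, "uniform")
            for t in range(1, cfg.n_trials + 1):
                if agent is not None:
                    clean = run_trial(agent, rng)
                    # learning operates on the intended trajectory; detour
                    # noise below is observational
                    reinforce(agent, clean, route_distance(arr, clean))
                else:
                    start = arr.labels[int(rng.choice(arr.n))]
                    clean = nearest_neighbour_sequence(arr, start, 0.0, rng)
                seq = _inject_revisits(arr, clean, cfg.revisit_noise, rng)
                d = route_distance(arr, seq)
                rows.append(
                    {
                        "experiment": arr.name,
                        "species": gname,
                        "individual": f"{gname}_{i:03d}",
                        "trial": t,
                        "sequence": SEQ_DELIMITER.join(seq),
                        "source": source,
                        "distance": d,
                    }
                )
    return pd.DataFrame(rows, columns=list(TRIALS_COLUMNS))


def empirical_start_probs(
    trials: pd.DataFrame,
) -> dict[str, dict[str, float]]:
    """Observed start-platform distribution per species.

    The relative frequency of each trial's first-visited platform, per
    species; feeds the empirical start mode of cohort simulations.
    """
    if trials.empty:
        raise ValueError("empty trials table")
    out: dict[str, dict[str, float]] = {}
    for species, grp in trials.groupby("species", sort=True):
        starts = grp["sequence"].astype(str).str.split(SEQ_DELIMITER).str[0]
        freq = starts.value_counts(normalize=True)
        out[str(species)] = {str(k): float(v) for k, v in freq.items()}
    return out
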