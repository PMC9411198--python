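"""Platform arrays, distance matrices, route lengths and optimal open paths.

A foraging experiment presents an animal (or a simulated agent) with a small
set of labelled feeding platforms at fixed 2-D positions.  Everything
downstream — trial distances, learning-curve intercept priors, agent
transition weights — is derived from the pairwise Euclidean distance matrix
of such an array.  Distances are unitless; the physical arrays were scaled to
the body size of each species, so only relative geometry matters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlatformArray",
    "OptimalRoute",
    "build_array",
    "load_array_csv",
    "route_distance",
    "count_routes",
    "optimal_open_path",
]

#: largest array size for which exhaustive open-path search is attempted
DEFAULT_BRUTE_FORCE_CAP = 9


@dataclass(frozen=True)
class PlatformArray:
    """A named set of platforms with coordinates and derived distances.

    Attributes
    ----------
    name : str
        Array identifier (e.g. ``"double_trapezoid"``).
    labels : tuple of str
        Platform labels in a fixed order; unique.
    coords : ndarray, shape (n, 2)
        Cartesian coordinates, one row per label.
    dist : ndarray, shape (n, n)
        Pairwise Euclidean distances (symmetric, zero diagonal).
    """

    name: str
    labels: tuple[str, ...]
    coords: np.ndarray
    dist: np.ndarray
    _index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(
                f"unknown platform {label!r} for array {self.name!r}"
            ) from None

    def indices(self, seq: Sequence[str]) -> np.ndarray:
        return np.array([self.index_of(s) for s in seq], dtype=np.intp)

    def scaled(self, c: float, name: str | None = None) -> "PlatformArray":
        """Return a copy with all coordinates multiplied by ``c > 0``."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return build_array(
            name or self.name,
            {lab: tuple(self.coords[i] * c) for i, lab in enumerate(self.labels)},
        )


@dataclass(frozen=True)
class OptimalRoute:
    """A shortest open (Hamiltonian) path through an array.

    ``length`` is the minimum possible distance required to visit every
    platform exactly once, without returning to the start.
    """

    sequence: tuple[str, ...]
    length: float


def build_array(
    name: str, coords: Mapping[str, Sequence[float]]
) -> PlatformArray:
    """Construct a :class:`PlatformArray` from labelled 2-D points.

    Raises
    ------
    ValueError
        If fewer than two platforms are given, labels repeat, coordinates
        are non-finite, or two platforms coincide.
    """
    labels = tuple(str(k) for k in coords)
    if len(labels) < 2:
        raise ValueError("an array needs at least two platforms")
    if len(set(labels)) != len(labels):
        raise ValueError("platform labels must be unique")
    xy = np.asarray([coords[k] for k in coords], dtype=float)
    if xy.shape != (len(labels), 2):
        raise ValueError("each platform needs exactly two coordinates")
    if not np.all(np.isfinite(xy)):
        raise ValueError("coordinates must be finite")
    diff = xy[:, None, :] - xy[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    off = dist[~np.eye(len(labels), dtype=bool)]
    if np.any(off == 0):
        raise ValueError(f"array {name!r} has coincident platforms")
    return PlatformArray(name=name, labels=labels, coords=xy, dist=dist)


def load_array_csv(path: str | Path, name: str | None = None) -> PlatformArray:
    """Read an array from a CSV file with columns ``label,x,y``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"label": str})
    missing = {"label", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return build_array(
        name or path.stem,
        {row.label: (row.x, row.y) for row in df.itertuples()},
    )


def route_distance(array: PlatformArray, seq: Sequence[str]) -> float:
    """Total straight-line distance of a visit sequence.

    Sums the pairwise distances over consecutive transitions, including
    revisit transitions.  A single-platform sequence has distance 0.
    """
    if len(seq) < 1:
        raise ValueError("sequence must contain at least one platform")
    idx = array.indices(seq)
    if len(idx) == 1:
        return 0.0
    return float(array.dist[idx[:-1], idx[1:]].sum())


def count_routes(n_platforms: int) -> int:
    """Number of distinct visit orders of ``n`` platforms (``n!``)."""
    if n_platforms < 1:
        raise ValueError("need at least one platform")
    return math.factorial(n_platforms)


def optimal_open_path(
    array: PlatformArray, brute_force_cap: int = DEFAULT_BRUTE_FORCE_CAP
) -> OptimalRoute:
    """Exhaustive search for the shortest open path visiting all platforms.

    All ``n!`` permutations are scored; ties are broken by lexicographic
    order of the label sequence.  Arrays larger than ``brute_force_cap``
    are rejected outright — there is no heuristic fallback, because the
    result is used as a ground-truth optimum.
    """
    n = array.n
    if n > brute_force_cap:
        raise ValueError(
            f"array {array.name!r} has {n} platforms, above the exhaustive "
            f"search cap of {brute_force_cap}; refusing to approximate an "
            "optimum"
        )
    best_len = math.inf
    best_seq: tuple[str, ...] | None = None
    # iterate label permutations in lexicographic order so the first
    # minimiser found is the lexicographic tie-break winner
    for perm in itertools.permutations(sorted(array.labels)):
        idx = array.indices(perm)
        length = float(array.dist[idx[:-1], idx[1:]].sum())
        if length < best_len - 1e-12:
            best_len = length
            best_seq = perm
    assert best_seq is not None
    return OptimalRoute(sequence=best_seq, length=best_len)
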