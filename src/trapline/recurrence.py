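"""Determinism (DET) of categorical visit sequences.

A visit sequence is compared against itself: every pair of positions
``i < j`` holding the same platform is a *recurrence*.  A recurrence is a
*repeat* when it lies on a diagonal line of the recurrence plot of length at
least ``minL`` — i.e. inside a repeated sub-sequence of at least ``minL``
visits, run in the same order (forward repeat, main-diagonal lines) or in
reverse order (reverse repeat, anti-diagonal lines).  DET is the proportion
of recurrences that are repeats; it is undefined (not zero) for sequences
without any recurrence, such as a trial with no revisit.

``minL = 3`` throughout this package: a repeat is an identical (or
reversed) sub-sequence of at least three platform visits.

Indices in returned pair sets are 0-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .records import SEQ_DELIMITER, TrialRecord

__all__ = [
    "RecurrenceSummary",
    "recurrence_pairs",
    "det",
    "det_for_individual",
    "det_table",
    "minL_sensitivity",
    "collapse_consecutive",
]

logger = logging.getLogger(__name__)

Direction = Literal["forward", "reverse", "both"]

#: minimum repeated sub-sequence length used throughout the analysis
DEFAULT_MINL = 3
#: number of initial trials entering the DET analysis
DEFAULT_FIRST_N = 10


@dataclass(frozen=True)
class RecurrenceSummary:
    """Recurrence/repeat counts and the DET ratio for one sequence."""

    n: int
    recurrences: int
    repeats_forward: int
    repeats_reverse: int
    minL: int
    direction: Direction = "forward"

    @property
    def repeats(self) -> int:
        """Repeat count in the configured direction (capped at recurrences)."""
        if self.direction == "forward":
            return self.repeats_forward
        if self.direction == "reverse":
            return self.repeats_reverse
        return min(self.repeats_forward + self.repeats_reverse, self.recurrences)

    @property
    def defined(self) -> bool:
        return self.recurrences > 0

    @property
    def det(self) -> float:
        """repeats / recurrences, or NaN when there is no recurrence."""
        if not self.defined:
            return math.nan
        return self.repeats / self.recurrences


def collapse_consecutive(seq: Sequence[str]) -> tuple[str, ...]:
    """Drop consecutive duplicate visits (zero-distance self-transitions)."""
    out = []
    for s in seq:
        if not out or out[-1] != s:
            out.append(s)
    return tuple(out)


def recurrence_pairs(seq: Sequence[str]) -> set[tuple[int, int]]:
    """All 0-based index pairs ``i < j`` with ``seq[i] == seq[j]``."""
    if len(seq) < 1:
        raise ValueError("sequence must be non-empty")
    by_symbol: dict[str, list[int]] = {}
    for i, s in enumerate(seq):
        by_symbol.setdefault(s, []).append(i)
    pairs = set()
    for positions in by_symbol.values():
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                pairs.add((positions[a], positions[b]))
    return pairs


def _forward_repeats(codes: np.ndarray, minL: int) -> int:
    """Recurrent pairs on main-diagonal lines of length >= minL.

    For offset ``d`` the cells are ``(i, i+d)``; a maximal run of matches of
    length ``L`` contributes all ``L`` of its pairs when ``L >= minL``.
    """
    n = len(codes)
    total = 0
    for d in range(1, n):
        match = codes[: n - d] == codes[d:]
        total += _run_pair_count(match, minL)
    return total


def _run_pair_count(match: np.ndarray, minL: int) -> int:
    count = 0
    run = 0
    for m in match:
        if m:
            run += 1
        else:
            if run >= minL:
                count += run
            run = 0
    if run >= minL:
        count += run
    return count


def _reverse_repeats(codes: np.ndarray, minL: int) -> int:
    """Recurrent pairs on anti-diagonal lines of length >= minL.

    For the anti-diagonal ``i + j = s`` the cells are ``(i, s-i)``.  Line
    length is measured over the whole symmetric recurrence matrix — runs may
    pass through the main diagonal (a palindrome's centre always matches) —
    but only strict upper-triangle cells ``i < s-i`` are counted as pairs.
    """
    n = len(codes)
    total = 0
    for s in range(1, 2 * n - 2):
        lo = max(0, s - n + 1)
        hi = min(n - 1, s)  # inclusive
        i_vals = np.arange(lo, hi + 1)
        match = codes[i_vals] == codes[s - i_vals]
        run_start = 0
        m = len(i_vals)
        for k in range(m + 1):
            if k == m or not match[k]:
                run_len = k - run_start
                if run_len >= minL:
                    # pairs in this run with i < s - i
                    i_run = i_vals[run_start:k]
                    total += int(np.count_nonzero(2 * i_run < s))
                run_start = k + 1
    return total


def det(
    seq: Sequence[str], minL: int = DEFAULT_MINL, direction: Direction = "forward"
) -> RecurrenceSummary:
    """Recurrence summary and DET of one visit sequence.

    ``direction`` selects which repeats enter the DET numerator; forward and
    reverse counts are always both computed and reported.
    """
    if minL < 2:
        raise ValueError("minL must be >= 2")
    if direction not in ("forward", "reverse", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    seq = tuple(seq)
    _, codes = np.unique(np.asarray(seq, dtype=object), return_inverse=True)
    counts = np.bincount(codes)
    recurrences = int((counts * (counts - 1) // 2).sum())
    return RecurrenceSummary(
        n=len(seq),
        recurrences=recurrences,
        repeats_forward=_forward_repeats(codes, minL) if recurrences else 0,
        repeats_reverse=_reverse_repeats(codes, minL) if recurrences else 0,
        minL=minL,
        direction=direction,
    )


Mode = Literal["per_trial", "concatenated"]


def det_for_individual(
    trials: Sequence[TrialRecord],
    mode: Mode = "per_trial",
    first_n: int = DEFAULT_FIRST_N,
    minL: int = DEFAULT_MINL,
    direction: Direction = "forward",
) -> pd.DataFrame | None:
    """Recurrence/repeat rows for one individual's first ``first_n`` trials.

    Sequence length affects DET, so the analysis is limited to the first
    ``first_n`` trials; individuals with fewer completed trials are excluded
    (returns ``None`` and logs the exclusion).  ``per_trial`` yields one row
    per trial; ``concatenated`` joins the trials into a single sequence, so
    repeated routes in different trials form cross-trial diagonal lines.
    """
    trials = sorted(trials, key=lambda r: r.trial)
    if not trials:
        raise ValueError("empty trial list")
    if len(trials) < first_n:
        logger.warning(
            "excluding %s: only %d trials (< %d required)",
            trials[0].individual,
            len(trials),
            first_n,
        )
        return None
    trials = trials[:first_n]
    ref = trials[0]

    def row(unit_id: str, summary: RecurrenceSummary) -> dict:
        return {
            "individual": ref.individual,
            "species": ref.species,
            "source": ref.source,
            "experiment": ref.experiment,
            "unit_id": unit_id,
            "n": summary.n,
            "recurrences": summary.recurrences,
            "repeats_forward": summary.repeats_forward,
            "repeats_reverse": summary.repeats_reverse,
            "repeats": summary.repeats,
            "minL": minL,
            "mode": mode,
        }

    if mode == "per_trial":
        rows = [
            row(f"trial{t.trial}", det(t.sequence, minL, direction))
            for t in trials
        ]
    elif mode == "concatenated":
        joined: list[str] = []
        for t in trials:
            joined.extend(t.sequence)
        rows = [row("concat", det(collapse_consecutive(joined), minL, direction))]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)


def det_table(
    trials: pd.DataFrame,
    mode: Mode = "per_trial",
    first_n: int = DEFAULT_FIRST_N,
    minL: int = DEFAULT_MINL,
    direction: Direction = "forward",
) -> pd.DataFrame:
    """Recurrence table for every individual in a trials table.

    Excluded individuals (fewer than ``first_n`` trials) are listed in the
    result's ``attrs["excluded"]``.
    """
    frames = []
    excluded = []
    for ind, grp in trials.groupby("individual", sort=True):
        records = [
            TrialRecord(
                experiment=r.experiment,
                species=r.species,
                individual=r.individual,
                trial=int(r.trial),
                sequence=tuple(str(r.sequence).split(SEQ_DELIMITER)),
                source=r.source,
                distance=float(getattr(r, "distance", math.nan)),
            )
            for r in grp.itertuples()
        ]
        out = det_for_individual(records, mode, first_n, minL, direction)
        if out is None:
            excluded.append(ind)
        else:
            frames.append(out)
    if not frames:
        raise ValueError("no individual had enough trials for the DET analysis")
    table = pd.concat(frames, ignore_index=True)
    table.attrs["excluded"] = excluded
    return table


def minL_sensitivity(
    seqs: Iterable[Sequence[str]],
    minL_grid: Sequence[int],
    direction: Direction = "forward",
) -> pd.DataFrame:
    """DET of each sequence across a grid of ``minL`` values.

    DET is non-increasing in ``minL``: raising the minimum line length can
    only demote repeats back to plain recurrences.
    """
    if any(m < 2 for m in minL_grid):
        raise ValueError("minL values must be >= 2")
    rows = []
    for i, seq in enumerate(seqs):
        for m in minL_grid:
            s = det(seq, m, direction)
            rows.append(
                {
                    "seq_id": i,
                    "minL": m,
                    "recurrences": s.recurrences,
                    "repeats": s.repeats,
                    "det": s.det,
                }
            )
    return pd.DataFrame(rows)
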