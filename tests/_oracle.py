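"""Independent brute-force oracles used by the tests.

These deliberately use the most direct (and slow) formulation of each
quantity so they share no code path with the package implementation.
"""

from __future__ import annotations

import itertools
from typing import Sequence


def brute_force_repeats(
    seq: Sequence[str], minL: int
) -> tuple[int, int, int]:
    """(recurrences, forward repeats, reverse repeats) by window enumeration.

    Enumerates every pair of length-``minL`` windows; a recurrence point is
    a forward repeat if it is covered by some pair of identically matching
    windows, and a reverse repeat if covered by some pair matching in
    reversed order (self-overlapping windows allowed — a palindrome
    matches itself reversed).
    """
    n = len(seq)
    rec = {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if seq[i] == seq[j]
    }
    fwd: set = set()
    rev: set = set()
    for a in range(n - minL + 1):
        for b in range(n - minL + 1):
            if a == b:
                continue
            if all(seq[a + m] == seq[b + m] for m in range(minL)):
                for m in range(minL):
                    i, j = sorted((a + m, b + m))
                    if i != j:
                        fwd.add((i, j))
        for b in range(minL - 1, n):
            # windows a..a+minL-1 ascending vs b..b-minL+1 descending
            if all(seq[a + m] == seq[b - m] for m in range(minL)):
                for m in range(minL):
                    i, j = sorted((a + m, b - m))
                    if i != j:
                        rev.add((i, j))
    return len(rec), len(fwd & rec), len(rev & rec)


def brute_force_open_path(
    labels: Sequence[str], dist_lookup
) -> tuple[tuple[str, ...], float]:
    """Shortest open path by direct permutation scan (random tie handling).

    ``dist_lookup(a, b)`` returns the distance between two labels.
    """
    best = None
    best_len = float("inf")
    for perm in itertools.permutations(labels):
        length = sum(dist_lookup(a, b) for a, b in zip(perm, perm[1:]))
        if length < best_len - 1e-12:
            best_len = length
            best = perm
    return best, best_len
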