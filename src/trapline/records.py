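"""Shared record types for trial data."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TrialRecord", "TRIALS_COLUMNS", "factor_label"]

#: canonical column order of the trials CSV schema
TRIALS_COLUMNS = (
    "experiment",
    "species",
    "individual",
    "trial",
    "sequence",
    "source",
    "distance",
)

#: delimiter used to join platform labels into the CSV ``sequence`` field
SEQ_DELIMITER = "-"


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial: an ordered platform-visit sequence plus metadata.

    ``source`` tags the provenance of the trial: ``"empirical"`` for animal
    data, ``"F1"``/``"F1.2"``/``"F2"`` for reinforcement-learning agents at
    the corresponding factor, or another tag for synthetic heuristic agents.
    """

    experiment: str
    species: str
    individual: str
    trial: int
    sequence: tuple[str, ...]
    source: str
    distance: float


def factor_label(factor: float) -> str:
    """Canonical source tag for a reinforcement factor (1 -> ``"F1"``)."""
    return f"F{factor:g}"
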