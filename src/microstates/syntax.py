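"""Microstate syntax: doublet and triplet transition statistics.

With four classes there are 12 admissible ordered doublets (X->Y, X != Y)
and 36 admissible triplets (X->Y->Z with X != Y and Y != Z; X may equal Z).
Consecutive runs within an epoch form the transition sequence; epochs are
temporally discontinuous selections, so no transition is counted across an
epoch boundary.  Counts are pooled over all of a subject's epochs and
normalized to fractions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .segmentation import MicrostateRun

__all__ = [
    "TransitionStats",
    "doublet_keys",
    "triplet_keys",
    "count_doublets",
    "count_triplets",
    "transition_stats",
]

CLASS_LETTERS = ("A", "B", "C", "D")


def doublet_keys(letters: tuple[str, ...] = CLASS_LETTERS) -> list[tuple[str, str]]:
    """The 12 admissible ordered class pairs."""
    return [(a, b) for a, b in itertools.product(letters, letters) if a != b]


def triplet_keys(
    letters: tuple[str, ...] = CLASS_LETTERS,
) -> list[tuple[str, str, str]]:
    """The 36 admissible ordered class triples (no immediate repeats)."""
    return [
        (a, b, c)
        for a, b, c in itertools.product(letters, letters, letters)
        if a != b and b != c
    ]


@dataclass
class TransitionStats:
    """Normalized doublet/triplet transition fractions for one subject.

    Fractions are NaN-free dictionaries over the admissible keys; when a
    subject has no transitions (or no triples) the corresponding part is
    ``None`` (reported missing).
    """

    doublet_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    doublet_fractions: dict[tuple[str, str], float] | None = None
    triplet_counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    triplet_fractions: dict[tuple[str, str, str], float] | None = None


def _run_letters(
    runs_per_epoch: list[list[MicrostateRun]], letters: tuple[str, ...]
) -> list[list[str]]:
    out = []
    for runs in runs_per_epoch:
        out.append([letters[r.label] for r in runs])
    return out


def count_doublets(
    runs_per_epoch: list[list[MicrostateRun]],
    letters: tuple[str, ...] = CLASS_LETTERS,
) -> TransitionStats:
    """Count and normalize ordered pairs of consecutive runs."""
    counts = {key: 0 for key in doublet_keys(letters)}
    for seq in _run_letters(runs_per_epoch, letters):
        for a, b in zip(seq, seq[1:]):
            counts[(a, b)] += 1
    total = sum(counts.values())
    fractions = (
        {k: v / total for k, v in counts.items()} if total > 0 else None
    )
    return TransitionStats(doublet_counts=counts, doublet_fractions=fractions)


def count_triplets(
    runs_per_epoch: list[list[MicrostateRun]],
    letters: tuple[str, ...] = CLASS_LETTERS,
) -> TransitionStats:
    """Count and normalize ordered triples of consecutive runs."""
    counts = {key: 0 for key in triplet_keys(letters)}
    for seq in _run_letters(runs_per_epoch, letters):
        for a, b, c in zip(seq, seq[1:], seq[2:]):
            counts[(a, b, c)] += 1
    total = sum(counts.values())
    fractions = (
        {k: v / total for k, v in counts.items()} if total > 0 else None
    )
    return TransitionStats(triplet_counts=counts, triplet_fractions=fractions)


def transition_stats(
    runs_per_epoch: list[list[MicrostateRun]],
    letters: tuple[str, ...] = CLASS_LETTERS,
) -> TransitionStats:
    """Doublet and triplet statistics in one object."""
    d = count_doublets(runs_per_epoch, letters)
    t = count_triplets(runs_per_epoch, letters)
    return TransitionStats(
        doublet_counts=d.doublet_counts,
        doublet_fractions=d.doublet_fractions,
        triplet_counts=t.triplet_counts,
        triplet_fractions=t.triplet_fractions,
    )
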