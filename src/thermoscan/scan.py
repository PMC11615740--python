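"""Stage-two candidate generation: contact-pair ranking and saturation
double-mutant enumeration.

Pairs are the top-N off-diagonal contact-map entries (default N = 1000).
At each pair every one of the 20×20 residue combinations except the
double-wild-type is a candidate — 399 mutants per pair. Substituting the
wild-type residue at one position of the pair is deliberately legal, so a
"self" label like ``H287H/Q288Y`` (only the second position changes) is a
valid candidate. No minimum sequence separation is imposed: adjacent pairs
are real design targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .backend import ContactMap
from .msa_io import ALPHABET, SequenceRecord, canonical_index, AlphabetError

log = logging.getLogger(__name__)

MUTANTS_PER_PAIR = 399  # 20*20 combinations minus the double wild type


@dataclass(frozen=True)
class PositionPair:
    """An unordered alignment position pair (stored i < j) with its contact score."""

    i: int
    j: int
    contact_probability: float

    def __post_init__(self) -> None:
        if not 0 <= self.i < self.j:
            raise ValueError(f"require 0 <= i < j, got ({self.i}, {self.j})")


@dataclass(frozen=True)
class DoubleMutant:
    """A candidate double substitution at a position pair.

    ``aa_i == wt_i`` (or ``aa_j == wt_j``) is allowed as long as at least
    one position changes; the double wild type is excluded.
    """

    pair: PositionPair
    wt_i: str
    wt_j: str
    aa_i: str
    aa_j: str

    def __post_init__(self) -> None:
        if (self.aa_i, self.aa_j) == (self.wt_i, self.wt_j):
            raise ValueError("double-wild-type combination is not a mutant")

    @property
    def label(self) -> str:
        """1-based slash notation, e.g. ``F237R/S240G``."""
        return (
            f"{self.wt_i}{self.pair.i + 1}{self.aa_i}/"
            f"{self.wt_j}{self.pair.j + 1}{self.aa_j}"
        )


def select_top_pairs(cmap: ContactMap, n_pairs: int = 1000) -> list[PositionPair]:
    """The ``n_pairs`` highest-probability off-diagonal pairs of a contact map.

    Each unordered pair appears once (i < j), sorted by probability
    descending with ties broken by (i, j) ascending. Requesting more pairs
    than exist returns all L(L-1)/2 of them.
    """
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1, got {n_pairs}")
    L = cmap.length
    iu, ju = np.triu_indices(L, k=1)
    probs = cmap.probabilities[iu, ju]
    # sort by (-prob, i, j): lexsort keys are applied last-key-primary
    order = np.lexsort((ju, iu, -probs))
    take = order[: min(n_pairs, len(order))]
    return [
        PositionPair(i=int(iu[k]), j=int(ju[k]), contact_probability=float(probs[k]))
        for k in take
    ]


def enumerate_double_mutants(
    query: SequenceRecord, pair: PositionPair
) -> list[DoubleMutant]:
    """All 399 double mutants at a pair (20×20 minus the double wild type).

    Deterministic order: aa_i outer, aa_j inner, both in canonical alphabet
    order. Raises :class:`AlphabetError` if a wild-type residue is not
    canonical (e.g. was mapped to gap on input); callers scanning many pairs
    should catch it and skip the pair.
    """
    wt_i, wt_j = query.residues[pair.i], query.residues[pair.j]
    canonical_index(wt_i)  # validate; raises AlphabetError on gap/non-canonical
    canonical_index(wt_j)
    return [
        DoubleMutant(pair=pair, wt_i=wt_i, wt_j=wt_j, aa_i=a, aa_j=b)
        for a in ALPHABET
        for b in ALPHABET
        if (a, b) != (wt_i, wt_j)
    ]


def apply_mutant(query: SequenceRecord, mutant: DoubleMutant) -> SequenceRecord:
    """Return the query with the mutant's substitutions applied.

    The result differs from the query exactly at the changed position(s);
    the query itself is untouched (records are immutable).
    """
    i, j = mutant.pair.i, mutant.pair.j
    if j >= len(query):
        raise ValueError(f"pair position {j} out of range for length {len(query)}")
    if query.residues[i] != mutant.wt_i or query.residues[j] != mutant.wt_j:
        raise ValueError(
            f"mutant {mutant.label} wild types do not match the query at "
            f"positions {i + 1}/{j + 1}"
        )
    residues = list(query.residues)
    residues[i] = mutant.aa_i
    residues[j] = mutant.aa_j
    return SequenceRecord(
        identifier=f"{query.identifier}|{mutant.label}", residues="".join(residues)
    )


def scan_pairs(
    query: SequenceRecord, pairs: list[PositionPair]
) -> tuple[list[DoubleMutant], list[PositionPair]]:
    """Enumerate double mutants over many pairs, skipping unusable ones.

    A pair whose wild-type residue is non-canonical (mapped-to-gap input) is
    skipped with a warning rather than aborting the scan. Returns the full
    mutant list and the pairs actually used.
    """
    mutants: list[DoubleMutant] = []
    used: list[PositionPair] = []
    for pair in pairs:
        try:
            mutants.extend(enumerate_double_mutants(query, pair))
        except AlphabetError as exc:
            log.warning(
                "skipping pair (%d, %d): %s", pair.i + 1, pair.j + 1, exc
            )
            continue
        used.append(pair)
    return mutants, used
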