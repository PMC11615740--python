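"""Stage-one alignment conditioning.

Two steps condition the raw alignment into the scoring context:

1. gap-ratio filtering — homologs whose gap fraction exceeds a threshold
   (default 15%) are dropped; a ratio exactly at the threshold is kept,
   and the query is always retained;
2. greedy diversity-maximizing subsampling to a fixed context size
   (default 64 sequences) — deterministic max-min selection under Hamming
   distance, seeded with the query, ties broken by input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .msa_io import GAP, Msa, SequenceRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrepConfig:
    """Conditioning parameters.

    max_gap_ratio : fraction of gap columns above which a homolog is dropped.
    context_size : number of representative sequences kept for scoring.
    keep_query : retain the query regardless of its gap ratio (it is gap-free
        by construction, so this only matters for exotic subclassing).
    """

    max_gap_ratio: float = 0.15
    context_size: int = 64
    keep_query: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_gap_ratio <= 1.0:
            raise ValueError(f"max_gap_ratio must be in [0,1], got {self.max_gap_ratio}")
        if self.context_size < 1:
            raise ValueError(f"context_size must be >= 1, got {self.context_size}")


def gap_ratio(record: SequenceRecord, length: int | None = None) -> float:
    """Fraction of gap symbols in a canonicalized record."""
    L = len(record) if length is None else length
    if L == 0:
        raise ValueError("gap ratio is undefined for an empty record")
    return record.residues.count(GAP) / L


def filter_by_gap(msa: Msa, max_gap_ratio: float = 0.15) -> Msa:
    """Drop records whose gap ratio strictly exceeds ``max_gap_ratio``.

    A ratio exactly at the threshold is kept. The query is always retained;
    input order is preserved; the operation is idempotent.
    """
    kept = [
        rec
        for k, rec in enumerate(msa.records)
        if k == msa.query_index or gap_ratio(rec) <= max_gap_ratio
    ]
    if len(kept) == 1 and msa.depth > 1:
        log.warning(
            "gap filter at %.3f removed every homolog; context is query-only",
            max_gap_ratio,
        )
    return msa.with_records(kept)


def hamming_distance(a: SequenceRecord, b: SequenceRecord) -> int:
    """Count of differing columns; gap is a 21st symbol that matches only gap."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a.residues, b.residues))


def _encode(records: tuple[SequenceRecord, ...]) -> np.ndarray:
    # byte matrix (depth, L); exact symbol comparison, gap included
    return np.frombuffer(
        "".join(r.residues for r in records).encode("ascii"), dtype=np.uint8
    ).reshape(len(records), -1)


def greedy_diversity_subsample(msa: Msa, context_size: int = 64) -> Msa:
    """Greedy max-min Hamming selection of a diverse sequence context.

    Starts from the query, then repeatedly adds the record with the largest
    minimum Hamming distance to the already-selected set until
    ``context_size`` records are chosen or the pool is exhausted. Ties are
    broken by original record order, so the selection is deterministic with
    no random seed. The query is first in the output; the remaining records
    appear in selection order.
    """
    if context_size < 1:
        raise ValueError(f"context_size must be >= 1, got {context_size}")
    if msa.depth == 1:
        return msa

    X = _encode(msa.records)
    selected = [msa.query_index]
    # min distance from each pool record to the selected set
    min_dist = np.sum(X != X[msa.query_index], axis=1)
    min_dist[msa.query_index] = -1  # never re-selected
    while len(selected) < context_size:
        pick = int(np.argmax(min_dist))  # argmax takes the first max: input-order tie-break
        if min_dist[pick] < 0:
            break
        selected.append(pick)
        min_dist = np.minimum(min_dist, np.sum(X != X[pick], axis=1))
        min_dist[pick] = -1
    return msa.with_records([msa.records[k] for k in selected])


def prepare_context(msa: Msa, config: PrepConfig | None = None) -> Msa:
    """Full stage-one conditioning: gap filter, then diversity subsampling."""
    config = config or PrepConfig()
    filtered = filter_by_gap(msa, config.max_gap_ratio)
    log.info(
        "gap filter %.3f: %d -> %d sequences",
        config.max_gap_ratio,
        msa.depth,
        filtered.depth,
    )
    context = greedy_diversity_subsample(filtered, config.context_size)
    log.info("diversity subsample: %d -> %d sequences", filtered.depth, context.depth)
    return context
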