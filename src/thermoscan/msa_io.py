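"""Alignment I/O: reading, validating and writing MSAs in A3M / aligned FASTA.

The pipeline's coordinate system is defined by the query sequence: every
alignment column is a query match column, the query itself carries no gaps,
and positions are 0-based internally (1-based in user-facing mutation
labels such as ``F237R/S240G``).

Canonicalization rules
----------------------
* A3M lowercase letters and ``.`` are insertion states relative to the
  query's match columns; they are deleted from every record independently.
  After deletion every record must have exactly the query's match-column
  count, otherwise the file is rejected as ragged.
* The residue alphabet is the 20 canonical amino acids in alphabetical
  one-letter order ``ACDEFGHIKLMNPQRSTVWY`` plus the gap symbol ``-``.
* Non-canonical letters (X, B, Z, J, U, O) cannot be one-hot encoded under
  a 20-letter alphabet; by default they are mapped to gap, or rejected when
  ``ambiguous="reject"``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Fixed amino-acid ordering used by every L×20 matrix in the package.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
_AMBIGUOUS = set("XBZJUO")


class AlphabetError(ValueError):
    """A symbol outside the 20-letter canonical alphabet where one is required."""


class MsaFormatError(ValueError):
    """Structurally invalid alignment input."""


def canonical_index(residue: str) -> int:
    """Return the column index in [0, 19] of a canonical amino-acid letter.

    The bijection is alphabetical one-letter order, so ``'A' -> 0`` and
    ``'Y' -> 19``. Gaps and ambiguity codes are not amino acids and raise
    :class:`AlphabetError`.
    """
    try:
        return _INDEX[residue]
    except KeyError:
        raise AlphabetError(f"not a canonical amino acid: {residue!r}") from None


def index_to_residue(index: int) -> str:
    """Inverse of :func:`canonical_index`."""
    if not 0 <= index < 20:
        raise AlphabetError(f"amino-acid index out of range: {index}")
    return ALPHABET[index]


def canonicalize(residues: str, ambiguous: Literal["gap", "reject"] = "gap") -> str:
    """Map raw aligned residues onto the 21-symbol alphabet (20 letters + '-').

    Uppercases the input, rewrites ``.`` to ``-`` and applies the ambiguity
    policy. Idempotent on already-canonical strings. Lowercase insertion
    removal is *not* done here; see :func:`strip_insertions`.
    """
    out = []
    for pos, sym in enumerate(residues.upper()):
        if sym == ".":
            sym = GAP
        if sym in _AMBIGUOUS:
            if ambiguous == "reject":
                raise AlphabetError(
                    f"ambiguous residue {sym!r} at column {pos} (policy=reject)"
                )
            sym = GAP
        if sym != GAP and sym not in _INDEX:
            raise AlphabetError(f"unknown symbol {sym!r} at column {pos}")
        out.append(sym)
    return "".join(out)


def strip_insertions(residues: str) -> str:
    """Delete A3M insertion states (lowercase letters and '.') from a record."""
    return "".join(s for s in residues if not s.islower() and s != ".")


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence: an identifier and its canonicalized residue string."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise MsaFormatError("sequence identifier must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_gap_free(self) -> bool:
        return GAP not in self.residues


@dataclass(frozen=True)
class Msa:
    """An alignment: ordered records of identical length with a designated query.

    The query row is gap-free by construction — it defines the mutable
    coordinate system all positions refer to.
    """

    records: tuple[SequenceRecord, ...]
    query_index: int = 0

    def __post_init__(self) -> None:
        if not self.records:
            raise MsaFormatError("an alignment needs at least one record")
        if not 0 <= self.query_index < len(self.records):
            raise MsaFormatError(f"query_index {self.query_index} out of range")
        L = len(self.records[0])
        seen: set[str] = set()
        for k, rec in enumerate(self.records):
            if len(rec) != L:
                raise MsaFormatError(
                    f"record {k} ({rec.identifier!r}) has length {len(rec)}, "
                    f"expected {L}"
                )
            if rec.identifier in seen:
                raise MsaFormatError(f"duplicate identifier {rec.identifier!r}")
            seen.add(rec.identifier)
        if not self.query.is_gap_free:
            raise MsaFormatError(
                f"query {self.query.identifier!r} contains gaps; the query must "
                "be gap-free to define the position coordinate system"
            )

    @property
    def query(self) -> SequenceRecord:
        return self.records[self.query_index]

    @property
    def length(self) -> int:
        """Alignment length L in match columns."""
        return len(self.records[0])

    @property
    def depth(self) -> int:
        """Number of aligned records."""
        return len(self.records)

    def with_records(self, records: Iterable[SequenceRecord]) -> "Msa":
        """New Msa over a record subset; the query record must be present."""
        recs = tuple(records)
        ids = [r.identifier for r in recs]
        try:
            qi = ids.index(self.query.identifier)
        except ValueError:
            raise MsaFormatError("subset does not contain the query record") from None
        return Msa(records=recs, query_index=qi)


def read_msa(
    path: str | Path,
    format: Literal["a3m", "fasta"] = "fasta",
    query_id: str | None = None,
    ambiguous: Literal["gap", "reject"] = "gap",
) -> Msa:
    """Read an alignment file into an :class:`Msa`.

    Parameters
    ----------
    path
        Alignment file. A3M and aligned FASTA are both FASTA-shaped and are
        parsed with Bio.SeqIO; A3M additionally removes lowercase insertion
        states so all records share the query's match-column length.
    format
        ``"a3m"`` or ``"fasta"``.
    query_id
        Identifier of the query record. Default: the first record.
    ambiguous
        Policy for X/B/Z/J/U/O symbols: map to gap (default) or reject.
    """
    path = Path(path)
    with open(path) as handle:
        return _parse_handle(handle, format, query_id, ambiguous, source=str(path))


def _parse_handle(handle, format, query_id, ambiguous, source: str) -> Msa:
    if format not in ("a3m", "fasta"):
        raise ValueError(f"unknown alignment format {format!r}")
    path = source
    raw = list(SeqIO.parse(handle, "fasta"))
    if not raw:
        raise MsaFormatError(f"{path}: no sequence records found")
    records = []
    for k, rec in enumerate(raw):
        residues = str(rec.seq)
        if format == "a3m":
            residues = strip_insertions(residues)
        residues = canonicalize(residues, ambiguous=ambiguous)
        records.append(SequenceRecord(identifier=rec.id, residues=residues))
    L = len(records[0])
    for k, rec in enumerate(records):
        if len(rec) != L:
            raise MsaFormatError(
                f"{path}: record {k + 1} ({rec.identifier!r}) has "
                f"{len(rec)} match columns, expected {L}"
            )
    query_index = 0
    if query_id is not None:
        ids = [r.identifier for r in records]
        if query_id not in ids:
            raise MsaFormatError(f"{path}: query {query_id!r} not in alignment")
        query_index = ids.index(query_id)
    return Msa(records=tuple(records), query_index=query_index)


def write_msa(msa: Msa, path: str | Path, format: Literal["a3m", "fasta"] = "fasta") -> None:
    """Write an alignment to disk.

    Canonicalized alignments contain no insertion states, so the A3M and
    FASTA serializations coincide; the round trip through :func:`read_msa`
    reproduces identifiers, residues and record order exactly.
    """
    if format not in ("a3m", "fasta"):
        raise ValueError(f"unknown alignment format {format!r}")
    seqs = [
        SeqRecord(Seq(rec.residues), id=rec.identifier, description="")
        for rec in msa.records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqs, handle, "fasta")


def parse_msa_string(
    text: str,
    format: Literal["a3m", "fasta"] = "fasta",
    query_id: str | None = None,
    ambiguous: Literal["gap", "reject"] = "gap",
) -> Msa:
    """Parse an alignment from an in-memory FASTA/A3M string."""
    return _parse_handle(io.StringIO(text), format, query_id, ambiguous, source="<string>")
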