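"""Hamiltonian scoring, variant ranking, contact-change analysis and reports.

The score of a gap-free sequence *s* against a likelihood matrix *M*
(L×20 row-normalized log-probabilities) is the negated sum of the entries
selected by the sequence's one-hot encoding *oh*:

    H(s) = − Σ_{i=1..L} Σ_{j=1..20} oh_ij · M_ij
         = − Σ_i M[i, index(s_i)]

a negative log-likelihood in nats: H ≥ 0 and **lower predicts more
stable**. Variants are ranked ascending by H; the report also carries
ΔH = H(mutant) − H(wild type), which for a context-only backend reduces to
the two changed positions' likelihood differences.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .backend import ContactMap, LikelihoodMatrix, ScoringBackend
from .msa_io import Msa, SequenceRecord, canonical_index
from .scan import DoubleMutant, apply_mutant

log = logging.getLogger(__name__)

REPORT_COLUMNS = (
    "rank",
    "label",
    "pos_i",
    "pos_j",
    "wt_i",
    "wt_j",
    "mut_i",
    "mut_j",
    "contact_probability",
    "hamiltonian",
    "delta_vs_wildtype",
)


def one_hot(sequence: SequenceRecord) -> np.ndarray:
    """L×20 indicator matrix: row i has a single 1 at the residue's canonical index."""
    L = len(sequence)
    oh = np.zeros((L, 20), dtype=np.float64)
    for i, aa in enumerate(sequence.residues):
        try:
            oh[i, canonical_index(aa)] = 1.0
        except Exception as exc:
            raise type(exc)(f"position {i + 1}: {exc}") from None
    return oh


def hamiltonian(sequence: SequenceRecord, m: LikelihoodMatrix) -> float:
    """Negative log-likelihood of a gap-free sequence under a likelihood matrix."""
    if len(sequence) != m.length:
        raise ValueError(
            f"sequence length {len(sequence)} != matrix length {m.length}"
        )
    idx = np.fromiter(
        (canonical_index(aa) for aa in sequence.residues),
        dtype=np.int64,
        count=len(sequence),
    )
    return float(-np.sum(m.log_probabilities[np.arange(len(sequence)), idx]))


@dataclass(frozen=True)
class ScoredVariant:
    """A double mutant with its Hamiltonian, ΔH against the wild type and rank."""

    mutant: DoubleMutant
    hamiltonian: float
    delta_vs_wildtype: float
    rank: int = 0

    @property
    def sort_key(self):
        m = self.mutant
        return (self.hamiltonian, m.pair.i, m.pair.j, m.aa_i, m.aa_j)


def score_variants(
    query: SequenceRecord,
    mutants: list[DoubleMutant],
    context: Msa,
    backend: ScoringBackend,
) -> list[ScoredVariant]:
    """Score each mutant's full sequence with the backend's likelihoods.

    The wild-type reference Hamiltonian is computed once from the unmutated
    query, so ΔH stays meaningful for sequence-aware backends. A backend
    failure on one mutant is logged and skipped; failures are summarized at
    the end rather than aborting the scan.
    """
    m_wt = backend.likelihoods(query, context)
    h_wt = hamiltonian(query, m_wt)
    scored: list[ScoredVariant] = []
    failures = 0
    for mut in mutants:
        try:
            mutated = apply_mutant(query, mut)
            m = backend.likelihoods(mutated, context)
            h = hamiltonian(mutated, m)
        except Exception as exc:  # backend contract: keep scanning
            failures += 1
            log.warning("backend failed on %s: %s", mut.label, exc)
            continue
        scored.append(
            ScoredVariant(mutant=mut, hamiltonian=h, delta_vs_wildtype=h - h_wt)
        )
    if failures:
        log.warning("backend failed on %d of %d mutants", failures, len(mutants))
    return scored


def wildtype_hamiltonian(
    query: SequenceRecord, context: Msa, backend: ScoringBackend
) -> float:
    """Reference Hamiltonian of the unmutated query."""
    return hamiltonian(query, backend.likelihoods(query, context))


def rank_variants(scored: list[ScoredVariant], top_k: int = 20) -> list[ScoredVariant]:
    """Ascending Hamiltonian order (lower = predicted more stable), ranks 1..K.

    Ties break by (i, j, aa_i, aa_j) ascending so ranking is a total order:
    permuting the input leaves the output identical.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    if not scored:
        raise ValueError("cannot rank an empty variant list")
    ordered = sorted(scored, key=lambda v: v.sort_key)
    return [
        dataclasses.replace(v, rank=r + 1) for r, v in enumerate(ordered[:top_k])
    ]


def contact_delta(cmap_wt: ContactMap, cmap_mut: ContactMap) -> np.ndarray:
    """Elementwise contact-map change (mutant − wild type).

    Antisymmetric under argument swap. A positive entry at (i, j) means the
    mutant context shows an intensified pairwise signal there — the readout
    used to rationalize designs structurally.
    """
    if cmap_wt.length != cmap_mut.length:
        raise ValueError(
            f"contact map lengths differ: {cmap_wt.length} vs {cmap_mut.length}"
        )
    return cmap_mut.probabilities - cmap_wt.probabilities


def extract_pair_signal(cmap: ContactMap, i: int, j: int) -> float:
    """Contact probability at a single off-diagonal pair."""
    if i == j:
        raise ValueError("pair signal is undefined on the diagonal")
    return cmap.value(i, j)


@dataclass(frozen=True)
class RunReport:
    """Everything one pipeline run produced: ranked variants plus provenance."""

    variants: list[ScoredVariant]
    wildtype_hamiltonian: float
    backend_name: str
    parameters: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ranks = [v.rank for v in self.variants]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("report table must be sorted by rank 1..K")


def sequence_digest(msa: Msa) -> str:
    """Stable content hash of an alignment, for provenance records."""
    h = hashlib.sha256()
    for rec in msa.records:
        h.update(rec.identifier.encode())
        h.update(b"\0")
        h.update(rec.residues.encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


def write_report(report: RunReport, path: str | Path) -> None:
    """Write the ranked-variant table as TSV plus a JSON provenance sidecar.

    All floats use fixed 6-decimal formatting, so re-reading reproduces
    every value to full printed precision and reruns diff byte-for-byte.
    The sidecar lands next to the table at ``<path>.provenance.json``.
    """
    path = Path(path)
    lines = ["\t".join(REPORT_COLUMNS)]
    for v in report.variants:
        m = v.mutant
        lines.append(
            "\t".join(
                [
                    str(v.rank),
                    m.label,
                    str(m.pair.i + 1),
                    str(m.pair.j + 1),
                    m.wt_i,
                    m.wt_j,
                    m.aa_i,
                    m.aa_j,
                    f"{m.pair.contact_probability:.6f}",
                    f"{v.hamiltonian:.6f}",
                    f"{v.delta_vs_wildtype:.6f}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "backend": report.backend_name,
        "wildtype_hamiltonian": f"{report.wildtype_hamiltonian:.6f}",
        "parameters": report.parameters,
        "provenance": report.provenance,
    }
    Path(f"{path}.provenance.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def read_report(path: str | Path) -> list[dict]:
    """Re-read a report table into a list of row dicts (strings kept verbatim)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty report")
    header = lines[0].split("\t")
    if tuple(header) != REPORT_COLUMNS:
        raise ValueError(f"{path}: unexpected report header {header}")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:]]
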