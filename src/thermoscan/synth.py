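"""Synthetic MSA generator with planted inter-column couplings.

Real alignments for this pipeline come from a homology search against a
large sequence database; that step needs external binaries and a
multi-gigabyte download. This module generates alignments with a known
covariation ground truth instead, so every pipeline stage — gap filtering,
diversity subsampling, contact estimation, pair selection, mutant scoring —
can be exercised end-to-end and checked against planted truth.

Sampling model
--------------
* The query is gap-free: background draws at uncoupled columns, the primary
  coupled state at each planted pair.
* Each homolog draws uncoupled columns i.i.d. from the background residue
  distribution. A planted pair (i, j, c) draws, with probability c, one of
  its two coupled state pairs {(A1, B1), (A2, B2)} with equal probability,
  and with probability 1 − c two independent background residues.
* Gaps then overwrite homolog symbols independently with probability
  ``gap_rate``.

With coupling c = 1 and no gaps the two columns form a two-state symmetric
joint distribution whose mutual information is exactly ln 2 — an analytic
anchor the contact estimators are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa_io import ALPHABET, GAP, Msa, SequenceRecord
from .scan import PositionPair

#: Study conditions the generator defaults emulate: a modest protein segment
#: with a deep filtered alignment and sparse strong covariation.
DEFAULT_LENGTH = 50
DEFAULT_DEPTH = 512
DEFAULT_N_PAIRS = 5
DEFAULT_COUPLING = 0.9
DEFAULT_GAP_RATE = 0.02


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic alignment.

    planted_pairs are (i, j, coupling) triples with disjoint positions;
    background is a 20-vector of residue probabilities (default uniform).
    """

    length: int = DEFAULT_LENGTH
    depth: int = DEFAULT_DEPTH
    planted_pairs: tuple[tuple[int, int, float], ...] = ()
    background: tuple[float, ...] | None = None
    gap_rate: float = DEFAULT_GAP_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 2 or self.depth < 1:
            raise ValueError("need length >= 2 and depth >= 1")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError(f"gap_rate must be in [0,1), got {self.gap_rate}")
        seen: set[int] = set()
        for i, j, c in self.planted_pairs:
            if not 0 <= i < j < self.length:
                raise ValueError(f"planted pair ({i}, {j}) out of range")
            if i in seen or j in seen:
                raise ValueError(f"planted pairs share position: ({i}, {j})")
            seen.update((i, j))
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coupling must be in [0,1], got {c}")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or bg.min() < 0 or abs(bg.sum() - 1.0) > 1e-9:
                raise ValueError("background must be 20 non-negative probs summing to 1")

    @property
    def background_probs(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 1.0 / 20.0)
        return np.asarray(self.background, dtype=float)


@dataclass(frozen=True)
class SynthTruth:
    """The planted pairs and the coupled residue states used to sample them."""

    pairs: tuple[tuple[int, int, float], ...]
    states: tuple[tuple[tuple[str, str], tuple[str, str]], ...]

    @property
    def pair_set(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.pairs}


def standard_spec(seed: int = 0, **overrides) -> SynthSpec:
    """The standard synthetic fixture: 5 strongly coupled pairs, light gaps.

    Pair positions are spread deterministically across the sequence so they
    never collide regardless of length.
    """
    length = overrides.pop("length", DEFAULT_LENGTH)
    n_pairs = overrides.pop("n_pairs", DEFAULT_N_PAIRS)
    coupling = overrides.pop("coupling", DEFAULT_COUPLING)
    stride = length // n_pairs
    pairs = tuple(
        (k * stride, k * stride + stride // 2, coupling) for k in range(n_pairs)
    )
    return SynthSpec(
        length=length, planted_pairs=pairs, seed=seed, **overrides
    )


def generate_msa(spec: SynthSpec) -> tuple[Msa, SynthTruth]:
    """Sample an alignment and its covariation ground truth from a spec.

    Fully reproducible: the same spec (seed included) yields byte-identical
    alignments.
    """
    rng = np.random.default_rng(spec.seed)
    bg = spec.background_probs
    L, N = spec.length, spec.depth

    # coupled two-state tables: A1 != A2 and B1 != B2 so the c=1 joint has
    # two distinguishable states and MI -> ln 2
    states = []
    for i, j, c in spec.planted_pairs:
        a1, a2 = rng.choice(20, size=2, replace=False, p=bg)
        b1, b2 = rng.choice(20, size=2, replace=False, p=bg)
        states.append(((ALPHABET[a1], ALPHABET[b1]), (ALPHABET[a2], ALPHABET[b2])))
    truth = SynthTruth(pairs=tuple(spec.planted_pairs), states=tuple(states))

    codes = rng.choice(20, size=(N, L), p=bg)
    for (i, j, c), ((a1, b1), (a2, b2)) in zip(spec.planted_pairs, states):
        coupled = rng.random(N) < c
        which = rng.random(N) < 0.5
        ai = np.where(which, ALPHABET.index(a1), ALPHABET.index(a2))
        bj = np.where(which, ALPHABET.index(b1), ALPHABET.index(b2))
        codes[coupled, i] = ai[coupled]
        codes[coupled, j] = bj[coupled]

    symbols = np.array(list(ALPHABET))
    rows = ["".join(symbols[row]) for row in codes]

    # query: background draw with every planted pair in its primary state
    qcodes = rng.choice(20, size=L, p=bg)
    for (i, j, _), ((a1, b1), _state2) in zip(spec.planted_pairs, states):
        qcodes[i] = ALPHABET.index(a1)
        qcodes[j] = ALPHABET.index(b1)
    query = "".join(symbols[qcodes])

    # gaps overwrite homolog symbols only, independently per cell
    if spec.gap_rate > 0:
        gap_mask = rng.random((N, L)) < spec.gap_rate
        rows = [
            "".join(GAP if gap_mask[n, i] else s for i, s in enumerate(row))
            for n, row in enumerate(rows)
        ]

    records = [SequenceRecord(identifier="query", residues=query)]
    records += [
        SequenceRecord(identifier=f"synth_{n:05d}", residues=row)
        for n, row in enumerate(rows)
    ]
    return Msa(records=tuple(records), query_index=0), truth


def recovery_metrics(
    selected: list[PositionPair], truth: SynthTruth, k: int
) -> tuple[float, float]:
    """Precision@k and recall@k of selected pairs against the planted truth."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    planted = truth.pair_set
    if not planted:
        raise ValueError("truth contains no planted pairs")
    top = {(p.i, p.j) for p in selected[:k]}
    hits = len(top & planted)
    return hits / k, hits / len(planted)


def write_truth(truth: SynthTruth, path) -> None:
    """Planted-truth TSV: i, j (1-based), coupling, and the two state pairs."""
    from pathlib import Path

    lines = ["pos_i\tpos_j\tcoupling\tstate1\tstate2"]
    for (i, j, c), (s1, s2) in zip(truth.pairs, truth.states):
        lines.append(f"{i + 1}\t{j + 1}\t{c:.6f}\t{s1[0]}{s1[1]}\t{s2[0]}{s2[1]}")
    Path(path).write_text("\n".join(lines) + "\n")
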