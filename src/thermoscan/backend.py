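"""Pluggable scoring backends: contact maps and per-position likelihoods.

The pipeline needs two quantities from an alignment context:

* a **contact map** — a symmetric L×L matrix whose entry (i, j) estimates
  how likely alignment positions i and j are to be in spatial contact;
* a **likelihood matrix** M — an L×20 matrix of per-position amino-acid
  log-probabilities for a given (possibly mutated) sequence in its context.

Both are abstracted behind the :class:`ScoringBackend` contract so that an
MSA-conditioned protein language model can be plugged in via
:func:`register_backend`. The tested default, :class:`BaselineBackend`, is a
deterministic closed-form backend:

* M is the log of Laplace-smoothed per-column residue frequencies of the
  context (independent of the variant sequence — a documented limitation a
  sequence-aware neural adapter does not share);
* the contact map is average-product-corrected mutual information (MI + APC),
  the standard background correction for covariation-based contact
  estimates, min-max rescaled into [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from scipy.special import logsumexp

from .msa_io import ALPHABET, GAP, Msa, SequenceRecord

log = logging.getLogger(__name__)

N_AA = 20
N_SYM = 21  # 20 amino acids + gap as a 21st symbol
_SYM_INDEX = {aa: i for i, aa in enumerate(ALPHABET + GAP)}


class DegenerateInputError(ValueError):
    """Input too small or empty for the requested statistic."""


@dataclass(frozen=True)
class ContactMap:
    """Symmetric L×L matrix of contact probabilities; diagonal fixed at 0."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = self.probabilities
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError(f"contact map must be square, got shape {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValueError("contact map contains non-finite entries")
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValueError("contact probabilities must lie in [0, 1]")
        if np.any(np.diag(p) != 0.0):
            raise ValueError("contact map diagonal must be 0")
        if not np.array_equal(p, p.T):
            raise ValueError("contact map must be symmetric")

    @property
    def length(self) -> int:
        return self.probabilities.shape[0]

    def value(self, i: int, j: int) -> float:
        return float(self.probabilities[i, j])


@dataclass(frozen=True)
class LikelihoodMatrix:
    """L×20 row-normalized log-probabilities, columns in canonical order.

    Rows satisfy logsumexp(row) = 0 within 1e-9, so the Hamiltonian built
    from them is a plain negative log-likelihood.
    """

    log_probabilities: np.ndarray

    def __post_init__(self) -> None:
        m = self.log_probabilities
        if m.ndim != 2 or m.shape[1] != N_AA:
            raise ValueError(f"likelihood matrix must be L x 20, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("likelihood matrix contains non-finite entries")
        if m.max() > 0.0:
            raise ValueError("log-probabilities must be <= 0")
        norms = logsumexp(m, axis=1)
        if np.max(np.abs(norms)) > 1e-9:
            raise ValueError("likelihood rows must logsumexp to 0 within 1e-9")

    @property
    def length(self) -> int:
        return self.log_probabilities.shape[0]


@runtime_checkable
class ScoringBackend(Protocol):
    """Contract every scoring backend satisfies."""

    name: str
    deterministic: bool

    def contact_map(self, msa: Msa) -> ContactMap: ...

    def likelihoods(self, variant_sequence: SequenceRecord, context: Msa) -> LikelihoodMatrix: ...


def encode_msa(msa: Msa) -> np.ndarray:
    """Integer-encode an alignment: (depth, L) with codes 0..19 = residues, 20 = gap."""
    flat = "".join(r.residues for r in msa.records)
    codes = np.fromiter((_SYM_INDEX[s] for s in flat), dtype=np.int64, count=len(flat))
    return codes.reshape(msa.depth, msa.length)


def column_frequencies(msa: Msa, pseudocount: float = 1.0) -> np.ndarray:
    """Laplace-smoothed per-column amino-acid frequencies, gaps excluded.

    For column i and residue a:
    p(i, a) = (count(i, a) + pseudocount) / (n_i + 20 * pseudocount),
    where n_i counts non-gap symbols in column i. An all-gap column falls
    back to the uniform row 1/20 (with a warning).
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    codes = encode_msa(msa)
    L = msa.length
    counts = np.zeros((L, N_AA), dtype=np.float64)
    for i in range(L):
        col = codes[:, i]
        col = col[col < N_AA]
        if col.size == 0:
            log.warning("column %d is entirely gaps; using uniform frequencies", i)
        counts[i] = np.bincount(col, minlength=N_AA)
    n = counts.sum(axis=1, keepdims=True)
    return (counts + pseudocount) / (n + N_AA * pseudocount)


def baseline_likelihoods(
    variant_sequence: SequenceRecord, context: Msa, pseudocount: float = 1.0
) -> LikelihoodMatrix:
    """Log column frequencies of the context as a LikelihoodMatrix.

    Independent of ``variant_sequence`` by construction; the argument is
    kept so the call signature matches sequence-aware backends.
    """
    if len(variant_sequence) != context.length:
        raise ValueError(
            f"sequence length {len(variant_sequence)} != context length {context.length}"
        )
    freqs = column_frequencies(context, pseudocount=pseudocount)
    return LikelihoodMatrix(log_probabilities=np.log(freqs))


def mutual_information(msa: Msa) -> np.ndarray:
    """Empirical mutual information between all column pairs, in nats.

    MI(i, j) = sum_{a,b} p(a,b) ln[p(a,b) / (p(a) p(b))] over the joint
    empirical distribution of symbols at columns i and j, with gap treated
    as a 21st symbol and no pseudocount. Diagonal is 0; the matrix is
    symmetric and non-negative up to floating-point error.
    """
    if msa.length < 2:
        raise DegenerateInputError("mutual information needs at least 2 columns")
    if msa.depth < 2:
        raise DegenerateInputError("mutual information needs at least 2 sequences")
    codes = encode_msa(msa)
    N, L = codes.shape
    # one-hot over 21 symbols -> joint counts for all pairs in one matmul
    onehot = np.zeros((N, L, N_SYM), dtype=np.float64)
    idx = np.arange(N)[:, None], np.arange(L)[None, :]
    onehot[idx[0], idx[1], codes] = 1.0
    flat = onehot.reshape(N, L * N_SYM)
    joint = (flat.T @ flat).reshape(L, N_SYM, L, N_SYM).transpose(0, 2, 1, 3) / N
    marg = onehot.sum(axis=0) / N  # (L, N_SYM)
    outer = marg[:, None, :, None] * marg[None, :, None, :]  # p(a)p(b), (L, L, S, S)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(joint > 0, joint / outer, 1.0)
        mi = np.sum(joint * np.log(ratio), axis=(2, 3))
    mi = 0.5 * (mi + mi.T)  # enforce exact symmetry against summation-order noise
    np.fill_diagonal(mi, 0.0)
    return mi


def apc_correct(raw: np.ndarray) -> ContactMap:
    """Average-product correction plus [0, 1] rescaling of a covariation matrix.

    corrected(i, j) = raw(i, j) - rowmean(i) * rowmean(j) / grandmean, with
    row and grand means taken over off-diagonal entries. The corrected
    matrix is then min-max rescaled to [0, 1] over its off-diagonal entries
    (a constant input maps to the all-zero map) and the diagonal forced
    to 0, honoring the ContactMap invariants while preserving ranking.
    """
    L = raw.shape[0]
    if raw.shape != (L, L):
        raise ValueError(f"expected a square matrix, got {raw.shape}")
    if not np.allclose(raw, raw.T):
        raise ValueError("APC input must be symmetric")
    if L < 2:
        return ContactMap(probabilities=np.zeros((L, L)))
    off = ~np.eye(L, dtype=bool)
    rowmean = (raw.sum(axis=1) - np.diag(raw)) / (L - 1)
    grandmean = raw[off].mean()
    if grandmean == 0.0:
        log.warning("APC grand mean is 0; returning all-zero contact map")
        return ContactMap(probabilities=np.zeros((L, L)))
    corrected = raw - np.outer(rowmean, rowmean) / grandmean
    corrected = 0.5 * (corrected + corrected.T)
    lo, hi = corrected[off].min(), corrected[off].max()
    if hi == lo:
        scaled = np.zeros((L, L))
    else:
        scaled = (corrected - lo) / (hi - lo)
        scaled = np.clip(scaled, 0.0, 1.0)
    np.fill_diagonal(scaled, 0.0)
    return ContactMap(probabilities=scaled)


class BaselineBackend:
    """Deterministic statistics backend: MI + APC contacts, column-frequency M.

    Because its likelihoods depend only on the context (never on the variant
    sequence), the matrix is computed once per context and cached by object
    identity; scanning 10^5 mutants costs no more than one mutant.
    """

    name = "baseline"
    deterministic = True

    def __init__(self, pseudocount: float = 1.0) -> None:
        if pseudocount <= 0:
            raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
        self.pseudocount = pseudocount
        self._cache: tuple[int, LikelihoodMatrix] | None = None

    def contact_map(self, msa: Msa) -> ContactMap:
        return apc_correct(mutual_information(msa))

    def likelihoods(self, variant_sequence: SequenceRecord, context: Msa) -> LikelihoodMatrix:
        if len(variant_sequence) != context.length:
            raise ValueError(
                f"sequence length {len(variant_sequence)} != context length {context.length}"
            )
        if self._cache is not None and self._cache[0] == id(context):
            return self._cache[1]
        m = baseline_likelihoods(variant_sequence, context, pseudocount=self.pseudocount)
        self._cache = (id(context), m)
        return m


_REGISTRY: dict[str, Callable[..., ScoringBackend]] = {"baseline": BaselineBackend}


def register_backend(name: str, factory: Callable[..., ScoringBackend]) -> None:
    """Register an external scoring backend (e.g. a pretrained MSA-conditioned
    language-model adapter) under ``name`` for CLI/config selection."""
    if name in _REGISTRY:
        raise ValueError(f"backend {name!r} already registered")
    _REGISTRY[name] = factory


def get_backend(name: str = "baseline", **kwargs) -> ScoringBackend:
    """Instantiate a registered backend by name."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(_REGISTRY))
        raise KeyError(f"unknown backend {name!r}; registered: {known}") from None
    return factory(**kwargs)
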