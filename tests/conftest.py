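import numpy as np
import pytest

from thermoscan.msa_io import ALPHABET, Msa, SequenceRecord


def make_msa(rows, query_index=0, ids=None):
    """Build an Msa from plain residue strings."""
    ids = ids or [f"s{k}" for k in range(len(rows))]
    return Msa(
        records=tuple(
            SequenceRecord(identifier=i, residues=r) for i, r in zip(ids, rows)
        ),
        query_index=query_index,
    )


def random_msa(rng, depth=12, length=8, gap_rate=0.1):
    """Random alignment with a gap-free query row."""
    aas = np.array(list(ALPHABET))
    rows = ["".join(aas[rng.integers(0, 20, size=length)])]
    for _ in range(depth - 1):
        syms = aas[rng.integers(0, 20, size=length)]
        gaps = rng.random(length) < gap_rate
        rows.append("".join("-" if g else s for s, g in zip(syms, gaps)))
    return make_msa(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def msa_factory():
    return make_msa


@pytest.fixture
def random_msa_factory():
    return random_msa
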