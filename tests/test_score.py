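"""Hamiltonian scoring, ranking, contact-change analysis and report I/O."""

import math

import numpy as np
import pytest
from scipy.special import logsumexp

from thermoscan.backend import BaselineBackend, ContactMap, LikelihoodMatrix
from thermoscan.msa_io import ALPHABET, AlphabetError, SequenceRecord, canonical_index
from thermoscan.scan import DoubleMutant, PositionPair, enumerate_double_mutants
from thermoscan.score import (
    RunReport,
    ScoredVariant,
    contact_delta,
    extract_pair_signal,
    hamiltonian,
    one_hot,
    rank_variants,
    read_report,
    score_variants,
    write_report,
)


def random_likelihoods(rng, L):
    logits = rng.normal(size=(L, 20))
    return LikelihoodMatrix(
        log_probabilities=logits - logsumexp(logits, axis=1, keepdims=True)
    )


def random_sequence(rng, L):
    return SequenceRecord("q", "".join(np.array(list(ALPHABET))[rng.integers(0, 20, L)]))


def double_sum_oracle(sequence, m):
    """Literal oh_ij * M_ij double sum, negated."""
    oh = one_hot(sequence)
    total = 0.0
    for i in range(len(sequence)):
        for j in range(20):
            total += oh[i, j] * m.log_probabilities[i, j]
    return -total


class TestOneHot:
    def test_alphabet_anchor(self):
        oh = one_hot(SequenceRecord("q", "A"))
        assert oh.shape == (1, 20)
        assert oh[0, 0] == 1.0 and oh.sum() == 1.0

    def test_rows_sum_to_one(self):
        oh = one_hot(SequenceRecord("q", "AC"))
        assert np.all(oh.sum(axis=1) == 1.0)
        assert oh.sum() == 2.0
        assert set(np.unique(oh)) <= {0.0, 1.0}

    def test_argmax_decodes_back_to_sequence(self, rng):
        seq = random_sequence(rng, 30)
        oh = one_hot(seq)
        decoded = "".join(ALPHABET[k] for k in oh.argmax(axis=1))
        assert decoded == seq.residues

    def test_gap_raises_naming_position(self):
        with pytest.raises(AlphabetError, match="position 2"):
            one_hot(SequenceRecord("q", "A-C"))


class TestHamiltonian:
    def test_uniform_matrix_closed_form(self):
        m = LikelihoodMatrix(log_probabilities=np.full((3, 20), math.log(1 / 20)))
        h = hamiltonian(SequenceRecord("q", "ACD"), m)
        assert h == pytest.approx(3 * math.log(20), abs=1e-12)

    def test_single_position_closed_form(self):
        row = np.full((1, 20), math.log(0.5 / 19))
        row[0, 0] = math.log(0.5)
        m = LikelihoodMatrix(log_probabilities=row)
        assert hamiltonian(SequenceRecord("q", "A"), m) == pytest.approx(
            math.log(2), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_literal_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        m = random_likelihoods(rng, 25)
        seq = random_sequence(rng, 25)
        assert hamiltonian(seq, m) == pytest.approx(
            double_sum_oracle(seq, m), abs=1e-10
        )

    def test_nonnegative_for_normalized_matrices(self, rng):
        m = random_likelihoods(rng, 12)
        assert hamiltonian(random_sequence(rng, 12), m) >= 0.0

    def test_additive_over_positions(self, rng):
        # H(s) decomposes as a sum of per-position terms: swapping one
        # residue changes H by exactly that position's entry difference
        m = random_likelihoods(rng, 10)
        seq = random_sequence(rng, 10)
        other = "W" if seq.residues[4] != "W" else "Y"
        swapped = SequenceRecord("q2", seq.residues[:4] + other + seq.residues[5:])
        dh = hamiltonian(swapped, m) - hamiltonian(seq, m)
        expected = -(
            m.log_probabilities[4, canonical_index(other)]
            - m.log_probabilities[4, canonical_index(seq.residues[4])]
        )
        assert dh == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            hamiltonian(SequenceRecord("q", "AC"), random_likelihoods(rng, 3))


class TestScoreVariants:
    def test_baseline_delta_matches_two_position_closed_form(self, random_msa_factory):
        rng = np.random.default_rng(17)
        msa = random_msa_factory(rng, depth=24, length=8, gap_rate=0.1)
        backend = BaselineBackend()
        query = msa.query
        pair = PositionPair(2, 6, 0.8)
        mutants = enumerate_double_mutants(query, pair)
        scored = score_variants(query, mutants, msa, backend)
        m = backend.likelihoods(query, msa).log_probabilities
        for v in scored:
            mut = v.mutant
            expected = -(
                m[2, canonical_index(mut.aa_i)] - m[2, canonical_index(mut.wt_i)]
            ) - (m[6, canonical_index(mut.aa_j)] - m[6, canonical_index(mut.wt_j)])
            assert v.delta_vs_wildtype == pytest.approx(expected, abs=1e-12)

    def test_scoring_twice_is_identical(self, random_msa_factory, rng):
        msa = random_msa_factory(rng, depth=16, length=6)
        query = msa.query
        mutants = enumerate_double_mutants(query, PositionPair(0, 3, 0.5))[:25]
        a = score_variants(query, mutants, msa, BaselineBackend())
        b = score_variants(query, mutants, msa, BaselineBackend())
        assert [v.hamiltonian for v in a] == [v.hamiltonian for v in b]

    def test_full_scan_matches_double_sum_oracle(self, random_msa_factory):
        from thermoscan.scan import apply_mutant, scan_pairs

        rng = np.random.default_rng(23)
        msa = random_msa_factory(rng, depth=32, length=10, gap_rate=0.05)
        query = msa.query
        pairs = [PositionPair(0, 4, 0.9), PositionPair(1, 7, 0.8), PositionPair(3, 9, 0.7)]
        mutants, _ = scan_pairs(query, pairs)
        assert len(mutants) == 3 * 399
        backend = BaselineBackend()
        scored = score_variants(query, mutants, msa, backend)
        m = backend.likelihoods(query, msa)
        for v in scored[::37]:  # stride keeps the check fast, order preserved
            assert v.hamiltonian == pytest.approx(
                double_sum_oracle(apply_mutant(query, v.mutant), m), abs=1e-10
            )


class TestRankVariants:
    @staticmethod
    def _mk(h, i=0, j=1, aa_i="A", aa_j="C"):
        mut = DoubleMutant(PositionPair(i, j, 0.5), "W", "Y", aa_i, aa_j)
        return ScoredVariant(mutant=mut, hamiltonian=h, delta_vs_wildtype=0.0)

    def test_ascending_sort_and_ranks(self):
        scored = [self._mk(3.0, aa_i="D"), self._mk(1.0, aa_i="E"), self._mk(2.0, aa_i="F")]
        top = rank_variants(scored, 2)
        assert [v.hamiltonian for v in top] == [1.0, 2.0]
        assert [v.rank for v in top] == [1, 2]

    def test_tie_break_is_positional_and_deterministic(self):
        scored = [self._mk(1.0, i=2, j=3), self._mk(1.0, i=0, j=1), self._mk(1.0, i=0, j=4)]
        top = rank_variants(scored, 3)
        assert [(v.mutant.pair.i, v.mutant.pair.j) for v in top] == [(0, 1), (0, 4), (2, 3)]

    def test_permuting_input_leaves_ranking_identical(self, rng):
        scored = [self._mk(float(h), aa_i=a) for h, a in zip(rng.normal(size=15), ALPHABET)]
        base = rank_variants(scored, 10)
        perm = rank_variants([scored[k] for k in rng.permutation(15)], 10)
        assert [(v.mutant.label, v.rank) for v in base] == [
            (v.mutant.label, v.rank) for v in perm
        ]

    def test_top_k_caps_at_list_size(self):
        assert len(rank_variants([self._mk(1.0)], 20)) == 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rank_variants([], 5)
        with pytest.raises(ValueError):
            rank_variants([self._mk(1.0)], 0)


class TestContactDelta:
    def _cmap(self, rng, L=6):
        raw = rng.random((L, L))
        raw = 0.5 * (raw + raw.T)
        np.fill_diagonal(raw, 0.0)
        return ContactMap(probabilities=raw / raw.max())

    def test_identical_maps_give_zero(self, rng):
        c = self._cmap(rng)
        assert np.all(contact_delta(c, c) == 0.0)

    def test_antisymmetric_under_swap(self, rng):
        a, b = self._cmap(rng), self._cmap(rng)
        assert np.array_equal(contact_delta(a, b), -contact_delta(b, a))

    def test_strengthened_pair_has_positive_delta(self, rng):
        a = self._cmap(rng)
        stronger = a.probabilities.copy()
        stronger[1, 4] = stronger[4, 1] = min(1.0, a.probabilities[1, 4] + 0.3)
        b = ContactMap(probabilities=stronger)
        delta = contact_delta(a, b)
        assert delta[1, 4] == pytest.approx(
            b.probabilities[1, 4] - a.probabilities[1, 4]
        )
        assert delta[1, 4] > 0
        assert extract_pair_signal(b, 1, 4) == b.probabilities[1, 4]

    def test_diagonal_signal_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_pair_signal(self._cmap(rng), 2, 2)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            contact_delta(self._cmap(rng, 5), self._cmap(rng, 6))


class TestReportIO:
    def _report(self, n):
        variants = []
        for k in range(n):
            mut = DoubleMutant(
                PositionPair(k, k + 1, 0.5 + 0.01 * k), "F", "S", "R", "G"
            )
            variants.append(
                ScoredVariant(
                    mutant=mut,
                    hamiltonian=10.0 + 0.1 * k,
                    delta_vs_wildtype=-0.5 + 0.1 * k,
                    rank=k + 1,
                )
            )
        return RunReport(
            variants=variants,
            wildtype_hamiltonian=11.5,
            backend_name="baseline",
            parameters={"top_pairs": 5},
        )

    def test_round_trip_reproduces_ranks_and_labels(self, tmp_path):
        report = self._report(10)
        path = tmp_path / "r.tsv"
        write_report(report, path)
        rows = read_report(path)
        assert [int(r["rank"]) for r in rows] == list(range(1, 11))
        assert rows[0]["label"] == report.variants[0].mutant.label
        assert rows[3]["hamiltonian"] == f"{report.variants[3].hamiltonian:.6f}"

    def test_empty_variant_list_writes_header_only(self, tmp_path):
        report = RunReport(
            variants=[], wildtype_hamiltonian=1.0, backend_name="baseline"
        )
        path = tmp_path / "empty.tsv"
        write_report(report, path)
        assert read_report(path) == []
        assert len(path.read_text().splitlines()) == 1

    def test_labels_use_slash_notation(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_report(self._report(3), path)
        import re

        for row in read_report(path):
            assert re.fullmatch(r"[A-Y]\d+[A-Y]/[A-Y]\d+[A-Y]", row["label"])

    def test_provenance_sidecar_written(self, tmp_path):
        import json

        path = tmp_path / "r.tsv"
        write_report(self._report(2), path)
        sidecar = json.loads((tmp_path / "r.tsv.provenance.json").read_text())
        assert sidecar["backend"] == "baseline"
        assert sidecar["parameters"]["top_pairs"] == 5

    def test_unsorted_ranks_rejected(self):
        v = self._report(2).variants
        with pytest.raises(ValueError, match="rank"):
            RunReport(
                variants=[v[1], v[0]], wildtype_hamiltonian=0.0, backend_name="b"
            )
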