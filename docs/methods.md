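# Methods

## Model

`thermoscan` scores a protein variant by how likely its full sequence is
under the evolutionary context of its family. Given an L-column alignment
with a gap-free query row, a backend supplies an L×20 matrix `M` of
row-normalized per-position amino-acid log-probabilities (columns in the
fixed order `ACDEFGHIKLMNPQRSTVWY`). The score of a gap-free sequence *s*
is the Hamiltonian

    H(s) = − Σ_i Σ_j oh_ij · M_ij = − Σ_i M[i, index(s_i)]

with `oh` the L×20 one-hot encoding of *s*. Because rows of `M` satisfy
logsumexp = 0, H is a plain negative log-likelihood in nats (H ≥ 0), and
lower H is taken to predict greater thermostability. Natural log is used
throughout; the base only rescales scores and never changes ranks.

The assumption doing the work is the zero-shot one: no stability-labeled
data enter anywhere. Sequence likelihood under the family context is used
directly as the stability proxy, which is exactly as strong — and as
limited — as that proxy is for the protein at hand.

## Pipeline and parameters

| parameter | default | meaning |
|---|---|---|
| `max_gap_ratio` | 0.15 | homologs with gap fraction **strictly above** this are dropped; exactly 15% is kept; the query is always retained |
| `context_size` | 64 | sequences kept by greedy diversity subsampling |
| `top_pairs` | 1000 | contact pairs carried into the mutation scan |
| `top_variants` | 20 | ranked designs reported |
| `pseudocount` | 1.0 | Laplace smoothing of the baseline column frequencies |

Defaults follow the published two-stage design protocol these numbers come
from; they are what a practitioner running the method as described would
use.

**Diversity subsampling** is greedy max-min selection under Hamming
distance on match columns, with gap as a 21st symbol: start from the query,
repeatedly add the record whose minimum distance to the selected set is
largest, ties broken by input order. This is the common deterministic
reading of diversity-maximizing MSA subsampling; seeding with the query
(rather than a random record) makes runs reproducible with no seed at all.
Filtering happens after A3M canonicalization.

**Pair selection** takes the top `top_pairs` off-diagonal contact-map
entries, each unordered pair once (i < j), sorted by probability descending
and then (i, j) ascending. No minimum sequence separation is imposed —
adjacent pairs are legitimate design targets in this protocol — and pairs
sharing a position are all kept.

**Enumeration** at a pair is all 20×20 residue combinations minus the
double wild type: 399 mutants, in alphabet order (aa_i outer, aa_j inner).
Keeping the wild-type residue at one position is deliberately legal, so
effectively-single mutants with labels like `H1H/Q2Y` are scanned too. A
pair whose query residue was mapped to gap on input (ambiguity codes) is
skipped with a warning rather than aborting the scan.

**Ranking** is ascending H with (i, j, aa_i, aa_j) tie-break — a total
order, so permuting the candidate list cannot change the report. The
report also carries ΔH = H(mutant) − H(wild type), with the wild-type
reference computed from the *unmutated* query's own likelihood matrix, so
ΔH stays meaningful for sequence-aware backends whose `M` depends on the
input sequence. For such backends, raw Hamiltonians of different mutants
are each computed under their own `M` (self-referential scoring); both the
raw H and ΔH are reported so users can see when the two orderings diverge.

## Baseline backend

The default backend is deterministic and dependency-free:

* **Likelihoods**: `M = log[(count(i,a) + κ) / (n_i + 20κ)]` with
  pseudocount κ = 1 and gaps excluded from both counts; an all-gap column
  falls back to uniform 1/20 with a warning. `M` is independent of the
  variant sequence, so a full scan costs one matrix; this is a documented
  simplification relative to a conditional language model, and it makes ΔH
  collapse exactly to the two changed positions' entry differences (a
  property the tests exploit as a closed-form oracle).
* **Contacts**: empirical mutual information between column pairs (gap as
  a 21st symbol, no pseudocount, diagonal 0), followed by the average
  product correction `raw(i,j) − rowmean(i)·rowmean(j)/grandmean` with
  means over off-diagonal entries — the standard suppression of
  phylogenetic/entropic background in covariation maps — then min-max
  rescaled into [0, 1] over off-diagonal entries so the result honors the
  contact-probability range. Rescaling is monotone, and ranking is the
  only property pair selection consumes. A constant input maps to the
  all-zero matrix; so does a zero grand mean (with a warning).

A neural MSA-conditioned backend can replace both estimators via
`register_backend(name, factory)`; it must satisfy the same type
invariants (symmetric [0,1] contact map with zero diagonal; row-normalized
log-probability matrix). No neural code ships in the tested core.

## Synthetic data

`thermoscan.synth` generates alignments with planted couplings: homolog
columns are i.i.d. draws from a background residue distribution (default
uniform), except at planted pairs (i, j, c), which with probability c emit
one of two coupled state pairs {(A1,B1), (A2,B2)} chosen equiprobably, and
with probability 1 − c two independent background draws. Gaps then
overwrite homolog cells independently at `gap_rate`; the query is sampled
gap-free with planted pairs in their primary states. At c = 1 with no gaps
the planted pair's mutual information is analytically ln 2, giving the
contact estimators an exact anchor.

The standard study conditions — L = 50, depth 512, five planted pairs at
coupling 0.9, gap rate 0.02 — are the generator defaults. They emulate a
deep, well-filtered alignment with sparse strong covariation at a size
where a full analysis runs in seconds; the acceptance run scores 5 pairs ×
399 = 1995 mutants. What this generator does **not** emulate: phylogenetic
correlation between homologs, realistic substitution matrices, indel
evolution, or the entropy gradients of real families. Passing tests
therefore demonstrate that the machinery is correct and deterministic, not
that MI + APC matches a transformer contact head on real proteins.

## Numerical choices and edge cases

* Likelihood rows are validated to logsumexp to 0 within 1e-9; MI is
  symmetrized (`(M + Mᵀ)/2`) to cancel summation-order noise and its
  diagonal forced to 0.
* All report floats use fixed 6-decimal formatting; with the baseline
  backend two identical runs produce byte-identical TSVs.
* Coordinates are 0-based half-open internally; 1-based in labels and
  reports, matching standard mutation nomenclature (`F237R/S240G`).
* Ambiguity codes (X/B/Z/J/U/O) map to gap by default (they cannot be
  one-hot encoded over 20 letters) or are rejected under
  `ambiguous="reject"`; how database pipelines should treat them is
  genuinely open, so the policy is a flag.
* Degenerate inputs: an alignment whose homologs are all filtered away
  proceeds query-only with a warning; MI requires at least 2 columns and
  2 sequences; an empty candidate list cannot be ranked.

## Known limitations

* The baseline likelihood ignores the variant sequence, so it cannot model
  epistasis between the two mutated positions; it exists to make the
  pipeline exact, fast and testable, with fidelity to conditional models
  delegated to the backend contract.
* Contact-map "probabilities" from MI + APC are rescaled scores, not
  calibrated probabilities.
* The score predicts no physical quantity (no Tm or ΔTm in degrees) and
  nothing about expression; it orders candidates.
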