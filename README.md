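# thermoscan

Contact-guided saturation double mutagenesis for protein thermostability
design, scored by a zero-shot MSA-conditioned Hamiltonian.

## The problem

Enzyme engineers want double mutations that raise a protein's
thermostability without training data for the target. One successful
zero-shot recipe is coevolutionary: residue pairs that covary across a deep
multiple sequence alignment (MSA) tend to be in spatial contact, and
substitutions that make the sequence *more likely* under its evolutionary
context tend to be stabilizing. `thermoscan` implements that recipe as a
two-stage pipeline:

1. **Site discovery.** Condition the alignment — drop homologs with more
   than 15% gaps, then greedily pick 64 maximally diverse representatives —
   and estimate an L×L contact map from it. The top 1000 pairs by contact
   probability are the candidate sites.
2. **Mutation scanning.** At every selected pair (i, j), enumerate all
   20×20 − 1 = 399 residue combinations (keeping the wild type at one
   position is allowed; reverting both is not), rebuild the full mutant
   sequence, and score it with the Hamiltonian

   ```
   H(s) = − Σ_{i=1..L} Σ_{j=1..20} oh_ij · M_ij = − Σ_i M[i, s_i]
   ```

   where `oh` is the L×20 one-hot encoding of the mutant sequence and `M`
   is an L×20 matrix of per-position amino-acid log-probabilities given the
   MSA context. H is a negative log-likelihood in nats: **lower H predicts
   more stable**. The top 20 variants by ascending H are reported.

The per-position likelihood matrix `M` and the contact map come from a
pluggable **scoring backend**. The tested default is a deterministic
statistics backend — Laplace-smoothed column frequencies for `M`, and
average-product-corrected mutual information (MI + APC) for the contact
map. An MSA-conditioned protein language model can be attached through
`thermoscan.register_backend` to supply both quantities instead; the
pipeline around it is unchanged.

A bundled synthetic-MSA generator plants known inter-column couplings, so
the whole pipeline is testable end-to-end against ground truth with no
database or model download.

## Worked example

Generate a synthetic alignment with three planted couplings, then run the
full design scan:

```bash
thermoscan simulate --length 50 --depth 512 \
    --pairs 8:16:0.9,24:31:0.9,37:45:0.9 --gap-rate 0.02 --seed 11 \
    --out demo.fasta --truth demo_truth.tsv
thermoscan scan --msa demo.fasta --out demo_report.tsv \
    --top-pairs 5 --top-variants 5
```

The scan prints

```
wild-type Hamiltonian 136.880447; best variant V43I/N50D H=136.228122
```

and `demo_report.tsv` begins

```
rank  label      pos_i  pos_j  wt_i  wt_j  mut_i  mut_j  contact_probability  hamiltonian  delta_vs_wildtype
1     V43I/N50D  43     50     V     N     I      D      0.273768             136.228122   -0.652325
2     V43I/N50P  43     50     V     N     I      P      0.273768             136.228122   -0.652325
3     V43I/N50Q  43     50     V     N     I      Q      0.273768             136.228122   -0.652325
```

Reading row 1: at alignment positions 43 and 50 (1-based), replacing V→I
and N→D gives the lowest Hamiltonian found, 136.23 nats, 0.65 nats below
the wild type — i.e. the mutant sequence is e^0.65 ≈ 1.9× more likely
under the alignment context. Ties (rows 1–3 share H because the context
supports D, P and Q equally at position 50) are broken deterministically,
so reruns are byte-identical. The provenance sidecar
`demo_report.tsv.provenance.json` records every resolved parameter and
input digest.

Real alignments are accepted as A3M (e.g. from HHblits with `-e 1e-20
-n 3` against a Uniclust30-style database) or aligned FASTA via
`--msa`/`--msa-format`; MSA construction itself is outside this package.

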