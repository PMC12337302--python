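# oligopop

Design software for synthesizing multi-kilobase genes from oligonucleotide
pools. Given a set of target coding sequences, `oligopop` produces
ready-to-order oligo pools and assembly plans for type IIS (Golden Gate)
cloning, plus the primer/barcode sets and read-validation tools needed to
pull individual constructs out of a pool and verify the clones you get
back.

It is aimed at synthetic-biology groups building many constructs at once —
libraries of transcription factors, reporter fusions, codon-optimized
pathway genes — who want array-synthesized oligos (~250 nt) instead of
per-gene synthesis.

## What it does

1. **Sequence design** — protein-preserving "domestication": removal of
   BsaI/BsmBI/BbsI sites on both strands, duplicated k-mers (k = 12) and
   long inverted repeats (stems ≥ 20 nt within 250 bp); codon optimization
   against a usage table (Arabidopsis bundled); minimum-GC enforcement over
   a 60 bp sliding window with a 4× objective boost; optional iterative
   removal of predicted splice junctions (pluggable predictor, PWM
   default).
2. **Overhang fidelity model** — an all-by-all 256×256 ligation-count
   matrix scores 4-nt junction overhangs. The predicted fidelity of
   junction *o* within an overhang pool *P* is

       f(o) = (N[o, rc(o)] + N[rc(o), o]) / Σ_{p∈P} (N[o,p] + N[rc(o),p])

   and a set's fidelity is ∏ f(o) over its members — monotonically
   non-increasing as overhangs are added. A genetic algorithm builds
   high-fidelity overhang sets ("hingesets") of any size; every set
   contains the standard coding-sequence terminals 5′-AATG and GCTT.
3. **Fragmentation** — targets are cut at hingeset-constrained junctions
   within a radius of ideal equidistant positions, using the fewest
   fragments that fit the oligo payload budget (198 nt payload inside a
   250 nt oligo). Any admissible plan's fidelity is ≥ the constraining
   set's fidelity; the search additionally maximizes it.
4. **Oligo layout and pools** — each fragment is wrapped as
   `fwd_index(18) + BbsI site + spacer + payload + rc(spacer + site) +
   rc(rev_index)` (52 nt overhead); all fragments of one target share an
   orthogonal index-primer pair so they amplify together from the pool.
5. **Two-step assembly** — targets above ~2 kb are split into ~1,050 bp
   BsmBI-flanked blocks (each block built from BbsI oligos), which then
   reassemble into a BsaI-compatible final part. A digital digest–ligate
   simulator verifies every plan end to end.
6. **Validation** — 96-member 18-mer barcode sets with minimum pairwise
   Levenshtein distance 8 for pooled colony amplicon sequencing; a read
   simulator with nanopore-like errors; demultiplexing, reference-anchored
   consensus, and per-clone verdicts (`error_free`,
   `correct_with_errors`, `misassembled`, `unassigned`).

## Worked example

```python
import oligopop as op

matrix = op.default_ligation_matrix()       # or load_ligation_matrix(csv)
hingeset = op.default_hingeset(30)          # bundled GA-optimized set

cds = op.random_cds(918, gc=0.45, seed=42)  # or your own CDS
designed = op.domesticate(cds, seed=1)
prepared = op.prepare_cds(designed)         # A + cds + GCTT context, 923 nt

plan = op.fragment_sequence(prepared, hingeset, matrix)
print(plan.n_fragments, round(plan.predicted_fidelity, 4))
# 5 0.9985

oligos = op.layout_oligos(plan, index_pair=("GTACAGCTTGACCTGAAG",
                                            "CAGTTGGACTCAAGTGTC"))
print([len(o.full_sequence) for o in oligos])
# [242, 237, 238, 234, 248]

result = op.digest_ligate([o.full_sequence for o in oligos], "BbsI")
print(result.matches(prepared))
# True
```

The 923 nt target splits into 5 oligos (the smallest n with
(923 + 4·(n−1))/n ≤ 198), each ≤ 250 nt; the in-silico BbsI digest and
ligation reassemble the prepared input exactly, and the plan's predicted
ligation fidelity is at least that of the constraining hingeset.

For a 9.5 kb construct:

```python
plan2 = op.plan_two_step(op.prepare_cds(op.random_cds(9495, 0.45, seed=30)),
                         hingeset, matrix, already_prepared=True)
print(plan2.n_blocks)                        # 9
final, diag = op.simulate_two_step(plan2)
print(diag["ok"])                            # True
```

A command-line interface mirrors the library:

```bash
oligopop run targets.fasta --seed 1 --outdir out/
oligopop barcodes -n 5000 --size 96 --min-distance 8 --seed 1
oligopop hingesets --sizes 10,20,30 --seed 1
```

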