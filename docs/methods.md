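# Methods

This note records the models, defaults and design choices behind
`oligopop`, and what the test suite does and does not demonstrate.

## Ligation-fidelity model

The substrate is a 256×256 matrix N of observed ligation counts between
all 4-nt overhangs, rows and columns indexed by the overhang read 5′→3′ on
the strand carrying the single-stranded extension. Raw count data of this
kind is strand-asymmetric, so the matrix is symmetrized before scoring:
N′[a,b] = (N[a,b] + N[rc(b), rc(a)])/2 (idempotent).

A junction contributes both its top-strand overhang o and the bottom-strand
rc(o) to the ligation pool. Within a pool P = members ∪ rc(members), the
predicted junction fidelity is

    f(o) = (N[o, rc(o)] + N[rc(o), o]) / Σ_{p∈P} (N[o,p] + N[rc(o),p]),

i.e. correct ligations over all in-pool ligations involving either strand
of the junction. A set's fidelity is the product of f over its members.
Because enlarging the pool can only add denominator mass and factors ≤ 1,
set fidelity is monotonically non-increasing in set size — a property the
tests verify exhaustively on a 16-overhang toy alphabet. Palindromic
overhangs are excluded everywhere (they self-ligate between copies of the
same junction), as are reverse-complement pairs within a set. An
alternative per-overhang convention can be obtained by scoring a set built
with `fixed_members=()`; the scoring convention in use is recorded in plan
metadata via the constraining set.

The package does not model ligation time, temperature or enzyme-condition
dependence; one matrix is active per run, and its provenance is carried in
`source_label`.

## Synthetic ligation matrix

When no measured matrix is supplied, `synthetic_ligation_matrix` builds a
Watson–Crick-dominant stand-in: N[o, rc(o)] = 1,000 exactly; off-target
counts are Poisson draws with an expected per-row mismatch mass of
`mismatch_rate × 1000`, of which 75% is concentrated on single-mismatch
partners (Hamming distance 1 from the true partner) and 25% spread
uniformly — mimicking the qualitative structure of measured ligation
error, where single-base mismatches dominate. The default
(`default_ligation_matrix()`) uses mismatch_rate = 0.05, seed = 2024; under
it the AATG/GCTT terminal pair scores > 0.99 and GA-optimized sets of size
20 land near 0.98, in the range reported for real multi-fragment designs.
The generator is not statistically fitted to any measured dataset; tests
passing under it show algorithmic correctness (round trips, monotonicity,
oracle equivalence), not numerical agreement with a particular enzyme
condition. Supplying the measured matrix as a CSV reproduces the published
fidelity benchmarks (see the acceptance suite).

## Hingeset optimization (GA)

Genome = the member set. Tournament selection (k = 3), uniform
set-crossover (child sampled from the union of its parents with fixed
members forced and reverse-complement collisions removed), point mutation
replacing one non-fixed member (rate 0.3), elitism 2, population 50, at
most 500 generations with stop after 50 stagnant ones. All randomness
flows from one integer seed, so identical inputs give identical sets. On
the 16-overhang toy alphabet the GA provably (by enumeration) reaches the
global optimum for sizes 2–6; at full scale it beats the best of 1,000
random valid sets. A library of sets (sizes 10–60, step 10) optimized
against the default matrix ships with the package; size 30 is the default
for fragmentation — large enough that junction windows almost always
contain an admissible 4-mer, small enough to keep set fidelity high.

## Sequence design

Constraint checking and repair are a per-codon local search rather than a
general-purpose optimizer: violations are located by dedicated scanners
(motif occurrences on both strands; duplicated 12-mers counting
reverse-complement duplicates; inverted repeats with stems ≥ 20 nt whose
arms lie within a 250 bp span — loop length deliberately unconstrained, no
thermodynamics), and codons overlapping a violating span are swapped for
synonymous alternatives, preferring frequent codons, until the scanners
pass. Only violating spans are touched, so compliant input is returned
byte-identical and the edit count is near-minimal for isolated sites.
Unsatisfiable windows (e.g. a motif forced by a unique codon) raise an
error naming the window.

GC tuning first recodes to match table usage, then sweeps 60 bp windows
below the floor, applying the single synonymous swap with the best score
`4 × ΔGC/3 + Δfrequency` (the 4× boost makes GC dominate codon usage). A
window is accepted once no swap can improve it further and it is within
the documented tolerance of 0.02; otherwise the run fails naming the
window. Raising the floor never lowers global GC (tested). Typical random
proteins cap out near a 60 bp-window floor of ~0.58–0.60; higher requests
fail honestly.

Codon optimization in `match_usage` mode apportions codons per amino acid
by largest-remainder quotas of the table frequencies and places them by a
seeded shuffle — this bounds the per-amino-acid L1 distance to the table
by one codon per synonym class, tighter than multinomial sampling.

## Splice-site handling

The default predictor is a log-odds position-weight model of canonical
plant donor (MAG|GTAAGT) and acceptor (polypyrimidine tract + YAG|)
motifs, scanned exhaustively; thresholds (9.0 log2-odds for both) flag
consensus-like sites while leaving a typical random CDS nearly clean. Any
callable with the same signature can replace it — the published workflows
in this space use neural predictors, and this PWM is a motif-level
stand-in, so predicted site counts are not expected to match any external
model. Deintronization alternates prediction with synonymous disruption of
any codon inside the predicted motif (up to 4 iterations), re-runs
constraint repair, and retries from up to 3 seeds, returning the cleanest
result (fewest residual sites, then fewest edits).

## Fragmentation

Coordinates are 0-based half-open; the 4-nt overhang at a junction belongs
to both flanking fragments, so n fragments carry length + 4(n−1) nt of
payload. The fragment count is the smallest n with
(L + 4(n−1))/n ≤ 198 (250 nt oligo budget minus 52 nt overhead),
incremented only if no junction assignment exists. Ideal cut positions are
equidistant (round(i·L/n)); candidates within radius 30 are admissible
when their 4-mer is in the hingeset and distinct/rc-distinct from all
overhangs already in the plan. When the assignment space is ≤ 20,000 the
search enumerates it exhaustively and returns the fidelity-optimal plan,
breaking ties by closeness to ideal positions then lexicographic overhang
order; larger spaces use depth-first search (nearest-ideal first) plus a
coordinate-improvement pass. Both paths are deterministic. Since plan
overhangs are a subset of the hingeset, any plan's fidelity is ≥ the
constraining set's fidelity; optimality beyond that is best-effort in the
DFS regime.

## Oligo layout and digest–ligate simulation

Layout: `fwd_index(18) + recognition + spacer + payload + rc(spacer +
recognition as a unit) + rc(rev_index)`. BbsI (GAAGAC, 2-nt spacer) is the
oligo-level enzyme, giving exactly 52 nt overhead; BsmBI/BsaI (1-nt
spacers) serve the block and downstream levels. Spacer bases default to
TT/A, switching to AA/T if the junction context would recreate a
recognition site; each oligo is verified by digesting it in silico and
checking that exactly the payload is released. The digestion model cuts at
recognition + spacer offset exposing 4-nt 5′ overhangs; fragments are
tracked in an "extended top-strand span" form in which ligation of
complementary overhangs is string overlap. Assembly enumerates maximal
chains over both orientations of every doubly-sticky fragment and reports
the unique full-length product, flagging ambiguous overhangs (two possible
continuations) and dead ends. Products are reported strand-canonically
(min of sequence and reverse complement); `AssemblyResult.matches(target)`
compares orientation-insensitively. Vector circularization is modeled by
adding vector ends as extra fragments carrying GCTT…AATG overhangs.

## Two-step planning

Targets are prepared as A + CDS + GCTT so the AATG terminal overhang
embeds the start codon (standard coding-sequence part syntax) and wrapped
in BsaI adapters for downstream reuse. Block count is round(L/1050)
(minimum 1; 9,500 nt → 9 blocks of ~1,055 nt). Block junctions are chosen
by the same hingeset-constrained search at block scale (payload cap
max(1050, ⌈L/n⌉) + 2·radius + 4); each block payload is wrapped in BsmBI
flanks and fragmented into BbsI-layout oligos. The same hingeset serves
both levels by default: block-level and oligo-level overhang namespaces
are independent (separate reactions) but never collide within a level.
`simulate_two_step` replays both assembly steps digitally and must
reproduce the prepared sequence exactly.

## Primers and barcodes

Index-primer candidates are rejection-sampled 18-mers: exactly 9 G/C,
homopolymer runs ≤ 4, no type IIS site on either strand, no ≥5-nt
self-complementary stretch, and nearest-neighbor Tm within 60 ± 1.5 °C.
The Tm model is Biopython's SantaLucia nearest-neighbor implementation
under PCR-like conditions (50 mM Na⁺, 1.5 mM Mg²⁺, 0.2 mM dNTPs, 500 nM
primer, Owczarzy divalent correction); an independent hand-rolled NN
implementation in the tests agrees within 0.5 °C. Cross-hybridization is
scored as the longest Watson–Crick complementary run between two primers,
doubled when the run reaches either primer's 3′ terminus; this is a
deliberately simple in-house metric calibrated so perfect-complement
fixtures score maximally and ≥95% of random pairs fall below the dimer
threshold (16). It does not reproduce any external tool's energies. Index
sets are selected by first removing members of any pair at/above the
threshold, then greedily dropping the worst aggregate scorer until k
remain (tests use k in the hundreds; full-scale 10,000-primer runs use the
same code path).

Barcode sets use greedy max–min selection under Levenshtein distance:
seed with the globally farthest pair, repeatedly add the candidate whose
minimum distance to the chosen set is largest, fail loudly when the floor
(8 edits at size 96) is unreachable. The pairwise matrix over thousands of
candidates is computed by a batched numpy dynamic program; the scalar
`edit_distance` uses edlib, and tests cross-check both against a plain DP.
From 5,000 generated candidates the selector reaches min distance 9, mean
≈ 11.5 at size 96.

## Amplicon validation

The read simulator applies independent per-base substitutions (default
0.02), insertions and deletions (0.005 each) to fwd_barcode + template +
rc(rev_barcode), on a random strand — a deliberately simple i.i.d. stand-in
for nanopore error, with flat quality strings; it does not model
homopolymer-length biases or quality correlation, so validation tests
demonstrate verdict logic, not basecaller realism. Demultiplexing matches
both terminal windows against the barcode pair within 3 edits (either
orientation), refusing ambiguous assignments; a minimum pairwise barcode
distance > 2×3 is enforced as a precondition, which makes cross-assignment
of ≤2-edit-corrupted reads impossible. Reads within ±20% of the clone's
median read length (a stand-in for a quality filter) are aligned globally
with edlib; the consensus is the per-reference-position plurality call
(insertions by majority), chosen over de novo assembly because amplicons
have a known expected sequence. Verdicts: `unassigned` below 5 reads;
`misassembled` when consensus coverage < 0.98 or any junction's flanking
20-mer is absent (allowing ≤5 edits, so a handful of consensus errors is
not mistaken for a structural failure) or out of order; `error_free` when
the consensus equals the reference; otherwise `correct_with_errors` with
the variant list. On simulated 24-clone plates with constructed truth the
verdict confusion matrix is diagonal at ≤5% substitution error and depth
20.

## Problem sizes and limitations

The test and acceptance runs use desk-scale sizes chosen to exercise every
code path: 100 one-step round trips at 0.3–3 kb, 20 two-step round trips
at 3–10 kb, 5,000 barcode candidates, 24-clone plates at depth 20. The
synthetic matrix, PWM splice model, i.i.d. error model and in-house
cross-hybridization score are stand-ins whose passing tests establish the
pipeline's internal correctness and its contracts; numerical agreement
with measured ligation data, neural splice predictors, thermodynamic
dimer scanners or real flow-cell error profiles is explicitly out of
scope. Wet-lab efficiency outcomes are not predicted by any part of this
package.
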