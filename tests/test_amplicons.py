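"""Read simulation, demultiplexing, alignment, consensus and verdicts."""

import numpy as np
import pytest

from oligopop.amplicons import (
    CloneVerdict,
    ErrorModel,
    align_to_reference,
    consensus_and_classify,
    demultiplex,
    simulate_reads,
    summarize_run,
)
from oligopop.dna import revcomp
from oligopop.fragmenter import fragment_sequence, prepare_cds
from oligopop.hingesets import default_hingeset
from oligopop.primers import generate_primer_candidates, select_barcode_set
from oligopop.synth import random_cds

TEMPLATE = random_cds(900, 0.45, seed=1)


@pytest.fixture(scope="module")
def barcode_pairs():
    bs = select_barcode_set(generate_primer_candidates(400, seed=2), size=12, min_distance=8)
    return [(bs.members[2 * i], bs.members[2 * i + 1]) for i in range(6)]


class TestSimulateReads:
    def test_zero_rate_reads_are_exact(self, barcode_pairs):
        fwd, rev = barcode_pairs[0]
        reads = simulate_reads(TEMPLATE, (fwd, rev), ErrorModel(0, 0, 0, seed=1), 10)
        expected = fwd + TEMPLATE + revcomp(rev)
        for r in reads:
            assert r.sequence in (expected, revcomp(expected))

    def test_substitution_rate_within_binomial_bound(self, barcode_pairs):
        model = ErrorModel(0.02, 0.0, 0.0, seed=5)
        reads = simulate_reads(TEMPLATE, barcode_pairs[0], model, 12)
        total = subs = 0
        expected = barcode_pairs[0][0] + TEMPLATE + revcomp(barcode_pairs[0][1])
        for r in reads:
            seq = r.sequence
            if seq not in (expected,) and len(seq) == len(expected):
                pass
            fwd = seq if seq[:6] == expected[:6] else revcomp(seq)
            subs += sum(a != b for a, b in zip(fwd, expected))
            total += len(expected)
        p = subs / total
        sigma = np.sqrt(0.02 * 0.98 / total)
        assert abs(p - 0.02) <= 3 * sigma

    def test_both_strands_emitted(self, barcode_pairs):
        reads = simulate_reads(TEMPLATE, barcode_pairs[0], ErrorModel(0, 0, 0, seed=3), 100)
        head = barcode_pairs[0][0][:6]
        fwd = sum(r.sequence.startswith(head) for r in reads)
        assert 0 < fwd < 100

    def test_deterministic(self, barcode_pairs):
        a = simulate_reads(TEMPLATE, barcode_pairs[0], ErrorModel(seed=9), 5)
        b = simulate_reads(TEMPLATE, barcode_pairs[0], ErrorModel(seed=9), 5)
        assert [r.sequence for r in a] == [r.sequence for r in b]


class TestDemultiplex:
    def test_exact_and_corrupted_barcodes_assigned(self, barcode_pairs):
        reads = simulate_reads(TEMPLATE, barcode_pairs[2], ErrorModel(0, 0, 0, seed=1), 4)
        # corrupt 2 positions inside the forward barcode of one read
        r = reads[0]
        seq = r.sequence if r.sequence[:4] == barcode_pairs[2][0][:4] else revcomp(r.sequence)
        corrupted = "TT" + seq[2:]
        reads[0].sequence = corrupted
        got = demultiplex(reads, barcode_pairs, max_distance=3)
        assert len(got.get(2, [])) == 4

    def test_scrambled_ends_unassigned(self, barcode_pairs):
        reads = simulate_reads(TEMPLATE, barcode_pairs[1], ErrorModel(0, 0, 0, seed=2), 3)
        for r in reads:
            r.sequence = "ACGT" * 7 + r.sequence[28:]
        got = demultiplex(reads, barcode_pairs, max_distance=3)
        assert got.get(1, []) == []

    def test_close_barcode_set_rejected(self):
        pairs = [("A" * 18, "C" * 18), ("A" * 17 + "G", "C" * 17 + "G")]
        with pytest.raises(ValueError, match="min distance"):
            demultiplex([], pairs, max_distance=3)

    def test_trimmed_reads_align_cleanly(self, barcode_pairs):
        reads = simulate_reads(TEMPLATE, barcode_pairs[0], ErrorModel(0, 0, 0, seed=4), 6)
        got = demultiplex(reads, barcode_pairs, max_distance=3)
        for seq in got[0]:
            assert align_to_reference(seq, TEMPLATE).edit_distance == 0


class TestAlign:
    def test_identical_sequences(self):
        a = align_to_reference(TEMPLATE, TEMPLATE)
        assert a.edit_distance == 0 and a.coverage == 1.0

    def test_internal_deletion_block(self):
        query = TEMPLATE[:300] + TEMPLATE[500:]
        a = align_to_reference(query, TEMPLATE)
        assert a.coverage < 1.0
        assert a.calls.count("-") == 200

    def test_edit_distance_matches_dp_oracle(self):
        from test_primers import levenshtein_dp

        rng = np.random.default_rng(8)
        for _ in range(5):
            x = "".join(rng.choice(list("ACGT"), 300))
            y = "".join(rng.choice(list("ACGT"), 310))
            assert align_to_reference(x, y).edit_distance == levenshtein_dp(x, y)


class TestConsensusAndClassify:
    def test_error_free(self, barcode_pairs):
        reads = simulate_reads(TEMPLATE, barcode_pairs[0], ErrorModel(0.02, 0.005, 0.005, seed=7), 20)
        got = demultiplex(reads, barcode_pairs, max_distance=3)
        v = consensus_and_classify(got[0], TEMPLATE)
        assert v.category == "error_free"
        assert v.consensus == TEMPLATE

    def test_planted_variant_recovered(self, barcode_pairs):
        mut = TEMPLATE[:450] + ("A" if TEMPLATE[450] != "A" else "G") + TEMPLATE[451:]
        reads = simulate_reads(mut, barcode_pairs[1], ErrorModel(0.02, 0.005, 0.005, seed=3), 20)
        got = demultiplex(reads, barcode_pairs, max_distance=3)
        v = consensus_and_classify(got[1], TEMPLATE)
        assert v.category == "correct_with_errors"
        assert v.variants == [(450, TEMPLATE[450], mut[450])]

    def test_dropped_fragment_misassembled(self, barcode_pairs, matrix):
        plan = fragment_sequence(prepare_cds(TEMPLATE), default_hingeset(30), matrix)
        prep = plan.assembled()
        frs = plan.fragments
        broken = frs[0]
        for j, f in enumerate(frs[1:], 1):
            if j == 2:
                continue
            broken = broken[:-4] + f if broken[-4:] == f[:4] else broken + f
        reads = simulate_reads(broken, barcode_pairs[3], ErrorModel(0.02, 0.005, 0.005, seed=4), 20)
        got = demultiplex(reads, barcode_pairs, max_distance=3)
        v = consensus_and_classify(got[3], prep, plan=plan)
        assert v.category == "misassembled"

    def test_too_few_reads_unassigned(self):
        v = consensus_and_classify(["ACGT"], TEMPLATE, min_reads=5)
        assert v.category == "unassigned"
        assert consensus_and_classify([], TEMPLATE).category == "unassigned"


class TestSummarize:
    def test_all_error_free(self):
        vs = [CloneVerdict(f"t_{i}", "error_free") for i in range(10)]
        rep = summarize_run(vs)
        assert rep["percent_correct"] == 100.0
        assert rep["percent_error_free"] == 100.0

    def test_constructed_93_69(self):
        vs = (
            [CloneVerdict(f"a_{i}", "error_free") for i in range(69)]
            + [CloneVerdict(f"b_{i}", "correct_with_errors") for i in range(24)]
            + [CloneVerdict(f"c_{i}", "misassembled") for i in range(7)]
        )
        rep = summarize_run(vs)
        assert rep["percent_correct"] == pytest.approx(93.0)
        assert rep["percent_error_free"] == pytest.approx(69.0)

    def test_empty_input_no_division_error(self):
        rep = summarize_run([])
        assert rep["n_clones"] == 0
        assert rep["percent_correct"] == 0.0
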