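"""Index primers, melting temperature, cross-hybridization, barcodes."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligopop.dna import FORBIDDEN_SITES, revcomp
from oligopop.primers import (
    DIMER_THRESHOLD,
    PrimerCandidate,
    TM_CONDITIONS,
    cross_hybridization_score,
    edit_distance,
    generate_primer_candidates,
    melting_temperature,
    select_barcode_set,
    select_index_set,
)

# --- independent nearest-neighbor Tm oracle -------------------------------
# SantaLucia (1998) unified NN parameters (kcal/mol, cal/mol/K) and the
# Owczarzy et al. (2008) magnesium correction, implemented from the
# published equations, independently of the implementation under test.
NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
INIT_AT = (2.3, 4.1)
INIT_GC = (0.1, -2.8)


def oracle_tm(seq: str) -> float:
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        inc = INIT_AT if end in "AT" else INIT_GC
        dh += inc[0]
        ds += inc[1]
    for i in range(len(seq) - 1):
        h, s = NN[seq[i : i + 2]]
        dh += h
        ds += s
    k = (TM_CONDITIONS["dnac1"] - TM_CONDITIONS["dnac2"] / 2.0) * 1e-9
    tm_1m = 1000 * dh / (ds + 1.987 * math.log(k)) - 273.15
    # Owczarzy divalent correction with dNTP-bound Mg subtracted
    mon = TM_CONDITIONS["Na"] * 1e-3
    mg0 = TM_CONDITIONS["Mg"] * 1e-3
    dntps = TM_CONDITIONS["dNTPs"] * 1e-3
    ka = 3e4
    mg = (-(ka * dntps - ka * mg0 + 1.0)
          + math.sqrt((ka * dntps - ka * mg0 + 1.0) ** 2 + 4.0 * ka * mg0)) / (2.0 * ka)
    fgc = (seq.count("G") + seq.count("C")) / len(seq)
    a, b, c, d = 3.92, -0.911, 6.26, 1.42
    e, f, g = -48.2, 52.5, 8.31
    ratio = math.sqrt(mg) / mon
    if 0.22 <= ratio < 6.0:
        a = 3.92 * (0.843 - 0.352 * math.sqrt(mon) * math.log(mon))
        d = 1.42 * (1.279 - 4.03e-3 * math.log(mon) - 8.03e-3 * math.log(mon) ** 2)
        g = 8.31 * (0.486 - 0.258 * math.log(mon) + 5.25e-3 * math.log(mon) ** 3)
    corr = (a + b * math.log(mg) + fgc * (c + d * math.log(mg))
            + (1 / (2.0 * (len(seq) - 1))) * (e + f * math.log(mg)
                                              + g * math.log(mg) ** 2)) * 1e-5
    return 1 / (1 / (tm_1m + 273.15) + corr) - 273.15


def levenshtein_dp(a: str, b: str) -> int:
    """Quadratic DP oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(cur[-1] + 1, prev[j] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestGenerator:
    CANDS = generate_primer_candidates(200, seed=3)

    def test_half_gc_and_length(self):
        for c in self.CANDS:
            assert len(c.sequence) == 18
            assert sum(c.sequence.count(b) for b in "GC") == 9

    def test_site_free_both_strands(self):
        for c in self.CANDS:
            assert not any(site in c.sequence for site in FORBIDDEN_SITES)

    def test_tm_within_band_by_independent_oracle(self):
        for c in self.CANDS[:50]:
            tm = oracle_tm(c.sequence)
            assert abs(tm - c.tm) < 0.5
            assert abs(tm - 60.0) <= 1.5 + 0.5

    def test_no_long_homopolymers(self):
        for c in self.CANDS:
            for b in "ACGT":
                assert b * 5 not in c.sequence

    def test_deterministic(self):
        again = generate_primer_candidates(200, seed=3)
        assert [c.sequence for c in again] == [c.sequence for c in self.CANDS]


class TestTm:
    def test_gc_raises_tm(self):
        assert melting_temperature("AT" * 9) < melting_temperature("GC" * 9)

    def test_agreement_with_oracle_random(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), 18))
            assert melting_temperature(seq) == pytest.approx(oracle_tm(seq), abs=0.5)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGT")


class TestCrossHybridization:
    def test_self_rc_is_maximal(self):
        a = "ACGTGCATCGATGCAGTC"
        assert cross_hybridization_score(a, revcomp(a)) == 2 * len(a)

    def test_symmetric(self):
        a, b = "ACGTGCATCGATGCAGTC", "TTGACCTGCAGGCATGCA"
        assert cross_hybridization_score(a, b) == cross_hybridization_score(b, a)

    def test_random_pairs_mostly_below_threshold(self):
        rng = np.random.default_rng(11)
        seqs = ["".join(rng.choice(list("ACGT"), 18)) for _ in range(120)]
        scores = [
            cross_hybridization_score(a, b)
            for a, b in itertools.combinations(seqs, 2)
        ]
        below = sum(s < DIMER_THRESHOLD for s in scores) / len(scores)
        assert below >= 0.95

    def test_appending_complementary_3prime_base_never_decreases(self):
        rng = np.random.default_rng(13)
        b = "".join(rng.choice(list("ACGT"), 18))
        a = revcomp(b)[:6]  # complementary to b's 3' region
        scores = []
        for extra in range(6):
            scores.append(cross_hybridization_score(revcomp(b)[: 6 + extra], b))
        assert all(y >= x for x, y in zip(scores, scores[1:]))


class TestIndexSet:
    def test_identity_when_all_below_threshold(self):
        cands = generate_primer_candidates(40, seed=9)
        scores = [
            cross_hybridization_score(a.sequence, b.sequence)
            for a, b in itertools.combinations(cands, 2)
        ]
        if max(scores) < DIMER_THRESHOLD:
            kept = select_index_set(cands, 40)
            assert {c.sequence for c in kept} == {c.sequence for c in cands}

    def test_planted_rc_pair_loses_a_member(self):
        cands = generate_primer_candidates(60, seed=21)
        planted = cands + [
            PrimerCandidate(sequence=revcomp(cands[0].sequence), gc=0.5, tm=60.0)
        ]
        kept = select_index_set(planted, 55)
        survivors = {c.sequence for c in kept}
        assert not (
            cands[0].sequence in survivors
            and revcomp(cands[0].sequence) in survivors
        )

    def test_beats_random_subsets(self):
        cands = generate_primer_candidates(80, seed=33)
        kept = select_index_set(cands, 40)
        def max_pair(seqs):
            return max(
                cross_hybridization_score(a, b)
                for a, b in itertools.combinations(seqs, 2)
            )
        ours = max_pair([c.sequence for c in kept])
        rng = np.random.default_rng(0)
        baseline = []
        all_seqs = [c.sequence for c in cands]
        for _ in range(200):
            pick = rng.choice(len(all_seqs), 40, replace=False)
            baseline.append(max_pair([all_seqs[i] for i in pick]))
        assert ours <= min(baseline) + 1e-9 or ours <= np.percentile(baseline, 5)


class TestEditDistance:
    @pytest.mark.parametrize(
        "a, b, d", [("AATG", "AATG", 0), ("AATG", "AACG", 1), ("", "ACGT", 4)]
    )
    def test_known_values(self, a, b, d):
        assert edit_distance(a, b) == d

    @given(
        st.text(alphabet="ACGT", min_size=0, max_size=18),
        st.text(alphabet="ACGT", min_size=0, max_size=18),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_dp_oracle(self, a, b):
        assert edit_distance(a, b) == levenshtein_dp(a, b)


class TestBarcodeSelection:
    def test_trivial_two_candidates(self):
        bs = select_barcode_set(["A" * 18, "T" * 18], size=2, min_distance=8)
        assert sorted(bs.members) == ["A" * 18, "T" * 18]
        assert bs.min_pairwise_distance == 18

    def test_min_distance_matches_recomputation(self):
        cands = generate_primer_candidates(600, seed=2)
        bs = select_barcode_set(cands, size=24, min_distance=8)
        direct = min(
            edit_distance(a, b) for a, b in itertools.combinations(bs.members, 2)
        )
        assert bs.min_pairwise_distance == direct >= 8

    def test_greedy_beats_random_subsets(self):
        cands = generate_primer_candidates(400, seed=8)
        bs = select_barcode_set(cands, size=24, min_distance=1)
        seqs = [c.sequence for c in cands]
        rng = np.random.default_rng(1)
        wins = 0
        trials = 100
        for _ in range(trials):
            pick = rng.choice(len(seqs), 24, replace=False)
            sub = [seqs[i] for i in pick]
            d = min(edit_distance(a, b) for a, b in itertools.combinations(sub, 2))
            wins += bs.min_pairwise_distance >= d
        assert wins / trials >= 0.99

    def test_unreachable_floor_reports_achievable(self):
        with pytest.raises(ValueError, match="unreachable"):
            select_barcode_set(
                generate_primer_candidates(60, seed=4), size=50, min_distance=14
            )
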