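"""Protein-preserving design: codon optimization, domestication, GC tuning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligopop.codon_tables import arabidopsis_table, uniform_table
from oligopop.designer import (
    DesignConstraints,
    DesignError,
    check_constraints,
    codon_optimize,
    domesticate,
    find_gc_violations,
    find_hairpin_violations,
    find_kmer_violations,
    find_pattern_violations,
    gc_tune,
    sequence_metrics,
)
from oligopop.dna import gc_fraction, revcomp, translate
from oligopop.synth import CODONS_BY_AA, random_cds

TABLE = arabidopsis_table()

random_cds_strategy = st.builds(
    random_cds,
    length_nt=st.integers(50, 160).map(lambda n: 3 * n),
    gc=st.sampled_from([0.40, 0.45, 0.50, 0.55]),
    seed=st.integers(0, 10**6),
)


class TestCodonOptimize:
    def test_best_codon_gives_cai_one(self):
        cds = random_cds(300, 0.5, seed=4)
        out = codon_optimize(cds, TABLE, mode="best_codon")
        assert translate(out) == translate(cds)
        assert sequence_metrics(out, TABLE)["cai"] == pytest.approx(1.0)

    def test_match_usage_approaches_table_frequencies(self):
        # 600-residue protein with many copies per residue
        cds = random_cds(1803, 0.5, seed=9)
        out = codon_optimize(cds, TABLE, mode="match_usage", seed=1)
        protein = translate(out)
        for aa in set(protein[:-1]):
            if protein.count(aa) < 50:
                continue
            codons = CODONS_BY_AA[aa]
            observed = np.array(
                [
                    sum(
                        out[i * 3 : i * 3 + 3] == c
                        for i, p in enumerate(protein)
                        if p == aa
                    )
                    for c in codons
                ],
                dtype=float,
            )
            observed /= observed.sum()
            expected = np.array([TABLE.frequency(c) for c in codons])
            assert np.abs(observed - expected).sum() <= 0.15

    @given(random_cds_strategy)
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_translation_preserved(self, cds):
        for mode in ("best_codon", "match_usage"):
            assert translate(codon_optimize(cds, TABLE, mode=mode, seed=0)) == translate(cds)

    def test_deterministic_given_seed(self):
        cds = random_cds(600, 0.5, seed=2)
        a = codon_optimize(cds, TABLE, mode="match_usage", seed=7)
        b = codon_optimize(cds, TABLE, mode="match_usage", seed=7)
        assert a == b

    def test_internal_stop_rejected(self):
        with pytest.raises(DesignError, match="internal stop"):
            codon_optimize("ATGTAAAAATGA", TABLE)


class TestDomesticate:
    def test_single_site_purged_with_one_codon_change(self):
        cds = random_cds(300, 0.5, seed=11)
        planted = cds[:150] + "GGTCTC" + cds[156:]
        out = domesticate(planted, seed=1)
        assert "GGTCTC" not in out and revcomp("GGTCTC") not in out
        changed_codons = sum(
            planted[i : i + 3] != out[i : i + 3] for i in range(0, len(out), 3)
        )
        assert changed_codons == 1
        assert translate(out) == translate(planted)

    def test_internal_duplication_removed(self):
        cds = random_cds(600, 0.5, seed=3)
        planted = cds[:300] + cds[90:120] + cds[330:]  # exact 30 bp duplication
        if translate(planted):  # protein changed but valid; that's fine
            out = domesticate(planted, seed=2)
            assert not find_kmer_violations(out, DesignConstraints())
            assert translate(out) == translate(planted)

    def test_inverted_repeat_removed(self):
        cds = random_cds(600, 0.5, seed=8)
        arm = cds[150:175]  # 25 bp arm, rc copy 100 bp downstream
        planted = cds[:275] + revcomp(arm)[:24] + cds[299:]
        constraints = DesignConstraints()
        if find_hairpin_violations(planted, constraints):
            out = domesticate(planted, seed=4)
            assert not find_hairpin_violations(out, constraints)
            assert translate(out) == translate(planted)

    def test_compliant_input_unchanged(self):
        cds = random_cds(450, 0.5, seed=13)
        assert domesticate(cds, seed=0) == cds

    def test_output_repasses_all_checkers(self):
        for seed in range(4):
            cds = random_cds(900, 0.45, seed=seed)
            out = domesticate(cds, seed=seed)
            assert check_constraints(out, DesignConstraints()) == []


class TestGcTune:
    CDS = random_cds(900, 0.45, seed=12)

    def test_windowed_floor_met(self):
        out = gc_tune(self.CDS, 0.53, seed=2)
        constraints = DesignConstraints(gc_min=0.53)
        assert gc_fraction(out) >= 0.53
        assert not find_gc_violations(out, constraints, slack=0.02)
        assert translate(out) == translate(self.CDS)

    def test_inactive_floor_equals_usage_only(self):
        tuned = gc_tune(self.CDS, 0, seed=2)
        usage_only = domesticate(
            codon_optimize(self.CDS, TABLE, mode="match_usage", seed=2), seed=2
        )
        assert tuned == usage_only

    def test_monotone_in_floor(self):
        gcs = [gc_fraction(gc_tune(self.CDS, g, seed=2)) for g in (0.45, 0.53, 0.60)]
        assert gcs == sorted(gcs)

    def test_unattainable_floor_names_window(self):
        with pytest.raises(DesignError, match=r"window \[\d+, \d+\)"):
            gc_tune(random_cds(900, 0.45, seed=11), 0.62, seed=2)

    def test_constraints_still_satisfied(self):
        out = gc_tune(self.CDS, 0.55, seed=3)
        assert check_constraints(out, DesignConstraints(gc_min=0.55)) == []


class TestMetrics:
    def test_gc_trivial(self):
        assert gc_fraction("ATGC") == 0.5

    def test_cai_equals_product_oracle(self):
        cds = random_cds(900, 0.5, seed=21)
        got = sequence_metrics(cds, TABLE)["cai"]
        # independent per-codon product oracle
        ws = []
        from oligopop.synth import STOP_CODONS, _AA_OF

        for i in range(0, len(cds), 3):
            c = cds[i : i + 3]
            if c in STOP_CODONS or len(CODONS_BY_AA[_AA_OF[c]]) == 1:
                continue
            best = max(TABLE.frequency(x) for x in CODONS_BY_AA[_AA_OF[c]])
            ws.append(TABLE.frequency(c) / best)
        oracle = float(np.prod(ws) ** (1.0 / len(ws)))
        assert got == pytest.approx(oracle, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            sequence_metrics("", TABLE)

    def test_gc3s_uniform_table_sanity(self):
        cds = codon_optimize(random_cds(300, 0.5, seed=2), uniform_table(), "best_codon")
        m = sequence_metrics(cds, TABLE)
        assert 0 <= m["gc3s"] <= 1


def test_pattern_scan_finds_both_strands():
    seq = "AAA" + "GGTCTC" + "TTT" + revcomp("GAAGAC") + "CCC"
    hits = find_pattern_violations(seq, DesignConstraints())
    found = {h[2] for h in hits}
    assert "GGTCTC" in found and revcomp("GAAGAC") in found
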