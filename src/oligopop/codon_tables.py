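"""Codon usage tables.

A :class:`CodonTable` maps each codon to its amino acid and its relative
frequency among synonymous codons (per-amino-acid frequencies sum to 1).
Tables can be loaded from TSV (columns: codon, amino_acid, frequency) in
the style of Kazusa/CoCoPUTs usage exports; an Arabidopsis thaliana table
is bundled as the default for plant-expression designs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from .synth import CODONS_BY_AA, SENSE_CODONS, STOP_CODONS, _AA_OF


@dataclass
class CodonTable:
    entries: dict[str, tuple[str, float]]
    source_label: str = ""

    def __post_init__(self) -> None:
        expected = set(SENSE_CODONS) | set(STOP_CODONS)
        got = set(self.entries)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValueError(
                f"codon table must list 61 sense + 3 stop codons; "
                f"missing {missing[:3]}, unexpected {extra[:3]}"
            )
        by_aa: dict[str, float] = {}
        for codon, (aa, freq) in self.entries.items():
            expected_aa = _AA_OF.get(codon, "*")
            if aa != expected_aa:
                raise ValueError(
                    f"codon {codon} labeled {aa!r}, standard code says {expected_aa!r}"
                )
            if freq < 0:
                raise ValueError(f"negative frequency for {codon}")
            by_aa[aa] = by_aa.get(aa, 0.0) + freq
        for aa, total in by_aa.items():
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"frequencies for {aa!r} sum to {total:.6f}, expected 1"
                )

    def amino_acid(self, codon: str) -> str:
        return self.entries[codon][0]

    def frequency(self, codon: str) -> float:
        return self.entries[codon][1]

    def codons_for(self, aa: str) -> list[str]:
        if aa == "*":
            return list(STOP_CODONS)
        return CODONS_BY_AA[aa]

    def best_codon(self, aa: str) -> str:
        return max(self.codons_for(aa), key=lambda c: (self.frequency(c), c))

    def relative_adaptiveness(self, codon: str) -> float:
        """w(codon) = f(codon) / f(most frequent synonymous codon)."""
        aa = self.amino_acid(codon)
        best = max(self.frequency(c) for c in self.codons_for(aa))
        return self.frequency(codon) / best if best else 0.0

    @classmethod
    def from_tsv(cls, path, source_label: str | None = None) -> "CodonTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        df["codon"] = df["codon"].str.upper().str.replace("U", "T")
        entries = {}
        for _, row in df.iterrows():
            entries[row["codon"]] = (str(row["amino_acid"]), float(row["frequency"]))
        # renormalize exactly so rounding in published tables is harmless
        sums: dict[str, float] = {}
        for codon, (aa, f) in entries.items():
            sums[aa] = sums.get(aa, 0.0) + f
        entries = {
            c: (aa, f / sums[aa] if sums[aa] else 0.0)
            for c, (aa, f) in entries.items()
        }
        return cls(entries, source_label=source_label or str(path))


def arabidopsis_table() -> CodonTable:
    """The bundled Arabidopsis thaliana codon usage table."""
    path = importlib.resources.files("oligopop").joinpath(
        "data/codon_usage_athaliana.tsv"
    )
    return CodonTable.from_tsv(path, source_label="A. thaliana (bundled)")


def uniform_table() -> CodonTable:
    """Equal-frequency synonymous codons (useful for tests)."""
    entries = {}
    for aa, codons in CODONS_BY_AA.items():
        for c in codons:
            entries[c] = (aa, 1.0 / len(codons))
    for c in STOP_CODONS:
        entries[c] = ("*", 1.0 / len(STOP_CODONS))
    return CodonTable(entries, source_label="uniform")
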