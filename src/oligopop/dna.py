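"""Small DNA helpers shared across the package.

Coordinates are 0-based, half-open throughout. An overhang is the 4-mer of
the 5' single-stranded extension read 5'->3' on the top strand.
"""

from __future__ import annotations

import itertools

from Bio.Seq import Seq

BASES = "ACGT"

#: all 256 4-mers in lexicographic order
ALL_4MERS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(BASES, repeat=4)
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq``."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_palindrome(kmer: str) -> bool:
    """True when a k-mer equals its own reverse complement."""
    return kmer == revcomp(kmer)


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence has no GC content")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def translate(cds: str) -> str:
    """Translate a CDS (length divisible by 3); '*' marks stops."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return str(Seq(cds).translate())


def validate_dna(seq: str, name: str = "sequence") -> str:
    s = seq.upper()
    bad = set(s) - set(BASES)
    if bad:
        raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")
    return s


def find_all(seq: str, motif: str) -> list[int]:
    """Start positions of every (possibly overlapping) occurrence of motif."""
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


# Type IIS enzymes used by the assembly hierarchy. ``spacer`` is the number
# of bases between the recognition site and the top-strand cut; the enzyme
# leaves a 4-nt 5' overhang.
TYPE_IIS_SITES: dict[str, str] = {
    "BsaI": "GGTCTC",
    "BsmBI": "CGTCTC",
    "BbsI": "GAAGAC",
}

TYPE_IIS_SPACER: dict[str, int] = {"BsaI": 1, "BsmBI": 1, "BbsI": 2}

#: motifs that must never occur in a payload, both strands
FORBIDDEN_SITES: tuple[str, ...] = tuple(TYPE_IIS_SITES.values()) + tuple(
    revcomp(s) for s in TYPE_IIS_SITES.values()
)


def has_forbidden_site(seq: str, sites: tuple[str, ...] = FORBIDDEN_SITES) -> bool:
    return any(site in seq for site in sites)
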