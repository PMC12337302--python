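"""Seeded synthetic-data generators.

Everything downstream is testable without external data: random stop-free,
restriction-site-free coding sequences at a requested GC, and Watson-Crick-
dominant ligation-count matrices with a tunable mismatch rate standing in
for experimentally measured all-by-all ligation data.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

from .dna import FORBIDDEN_SITES, gc_fraction, revcomp
from .fidelity import ALL_4MERS, IDX, OverhangMatrix, symmetrize_matrix

_STD = _BioCodonTable.unambiguous_dna_by_id[1]

#: amino acid -> sense codons (standard code)
CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in _STD.forward_table.items():
    CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in CODONS_BY_AA:
    CODONS_BY_AA[_aa].sort()
STOP_CODONS: tuple[str, ...] = tuple(sorted(_STD.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STD.forward_table))

_AA_OF = dict(_STD.forward_table)


def _codon_gc(codon: str) -> int:
    return codon.count("G") + codon.count("C")


def random_cds(length_nt: int, gc: float = 0.5, seed: int = 0) -> str:
    """A random CDS: starts ATG, single terminal stop, no internal stops,
    no BsaI/BsmBI/BbsI site on either strand, global GC within +-2% of ``gc``.

    Deterministic given ``seed``.  Raises if the requested GC is unreachable
    under those constraints at this length.
    """
    if length_nt % 3:
        raise ValueError("length must be divisible by 3")
    if length_nt < 9:
        raise ValueError("length must be at least 9 nt (start + codon + stop)")
    if not 0.2 <= gc <= 0.8:
        raise ValueError("requested GC outside the attainable range [0.2, 0.8]")
    rng = np.random.default_rng(seed)
    n_internal = length_nt // 3 - 2
    codons = ["ATG"] + [
        SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_internal)
    ] + [STOP_CODONS[rng.integers(0, len(STOP_CODONS))]]

    def seq() -> str:
        return "".join(codons)

    for _ in range(40 * len(codons) + 200):
        s = seq()
        site_pos = _first_site(s)
        if site_pos is not None:
            _mutate_span(codons, site_pos, site_pos + 6, rng)
            continue
        dev = gc_fraction(s) - gc
        if abs(dev) <= 0.02:
            return s
        if not _shift_gc(codons, up=dev < 0, rng=rng):
            break
    raise ValueError(
        f"could not reach GC {gc:.2f} +- 0.02 without forbidden sites at "
        f"length {length_nt}"
    )


def _first_site(s: str) -> int | None:
    best = None
    for site in FORBIDDEN_SITES:
        i = s.find(site)
        if i != -1 and (best is None or i < best):
            best = i
    return best


def _mutate_span(codons: list[str], start: int, end: int, rng) -> None:
    """Synonymously change one random mutable codon overlapping [start, end)."""
    lo, hi = start // 3, (end - 1) // 3
    order = list(range(max(lo, 1), min(hi, len(codons) - 2) + 1))
    rng.shuffle(order)
    for ci in order:
        alts = [c for c in CODONS_BY_AA[_AA_OF[codons[ci]]] if c != codons[ci]]
        if alts:
            codons[ci] = alts[rng.integers(0, len(alts))]
            return
    # no synonymous escape in the span: change the amino acid instead
    if order:
        ci = order[0]
        codons[ci] = SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))]


def _shift_gc(codons: list[str], up: bool, rng) -> bool:
    """Swap one random internal codon to a more (or less) GC-rich synonym."""
    order = list(range(1, len(codons) - 1))
    rng.shuffle(order)
    for ci in order:
        cur = codons[ci]
        alts = [
            c
            for c in CODONS_BY_AA[_AA_OF[cur]]
            if (_codon_gc(c) > _codon_gc(cur)) == up and _codon_gc(c) != _codon_gc(cur)
        ]
        if alts:
            codons[ci] = alts[rng.integers(0, len(alts))]
            return True
    return False


#: Hamming-distance-1 neighbours of each 4-mer, precomputed lazily
def _hamming1(kmer: str) -> list[str]:
    out = []
    for i, b in enumerate(kmer):
        for alt in "ACGT":
            if alt != b:
                out.append(kmer[:i] + alt + kmer[i + 1 :])
    return out


def synthetic_ligation_matrix(
    correct_count: int = 1000,
    mismatch_rate: float = 0.05,
    seed: int = 0,
    background_fraction: float = 0.25,
) -> OverhangMatrix:
    """A Watson-Crick-dominant ligation matrix.

    Each overhang ligates its reverse complement exactly ``correct_count``
    times; off-target counts are Poisson draws with expected total mass per
    row of ``mismatch_rate * correct_count``, concentrated on single-
    mismatch partners (Hamming distance 1 from the true partner) with a
    ``background_fraction`` share spread over all other partners — mimicking
    the qualitative structure of measured ligation error.  The result is
    symmetrized and deterministic given ``seed``.
    """
    if not 0 <= mismatch_rate < 1:
        raise ValueError("mismatch_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    counts = np.zeros((256, 256))
    if mismatch_rate > 0:
        lam_bg = background_fraction * mismatch_rate * correct_count / 255
        counts = rng.poisson(lam_bg, size=(256, 256)).astype(float)
    for o in ALL_4MERS:
        partner = revcomp(o)
        counts[IDX[o], IDX[partner]] = correct_count
        if mismatch_rate > 0:
            neighbours = _hamming1(partner)
            lam = (1 - background_fraction) * mismatch_rate * correct_count / len(
                neighbours
            )
            draws = rng.poisson(lam, size=len(neighbours))
            for nb, d in zip(neighbours, draws):
                counts[IDX[o], IDX[nb]] += d
    m = OverhangMatrix(
        counts,
        symmetrized=False,
        source_label=(
            f"synthetic(correct={correct_count}, mismatch_rate={mismatch_rate}, "
            f"seed={seed})"
        ),
    )
    return symmetrize_matrix(m)


def default_ligation_matrix() -> OverhangMatrix:
    """The package's default scoring matrix (synthetic, fixed parameters).

    Used when no experimentally measured matrix is supplied; the bundled
    hingeset library was optimized against this matrix.
    """
    return synthetic_ligation_matrix(correct_count=1000, mismatch_rate=0.05, seed=2024)
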