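"""Orthogonal index primers and edit-distance-separated barcode sets.

Index primers are random 18-mers at exactly 50% GC, free of type IIS
recognition sites on either strand, without homopolymer runs over 4, and
with a nearest-neighbor melting temperature of 60 +- 1.5 degC.  Candidate
sets are thinned by a pairwise cross-hybridization score (longest
complementary run, 3'-anchored duplexes weighted double).  Barcodes are a
maximally separated subset under Levenshtein distance, selected greedily
(farthest pair first, then max-min additions) to a floor of 8 edits over 96
members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from .dna import FORBIDDEN_SITES, gc_fraction, revcomp, validate_dna

#: PCR-like solution conditions for the nearest-neighbor Tm model
TM_CONDITIONS = dict(Na=50, Mg=1.5, dNTPs=0.2, dnac1=500, dnac2=500, saltcorr=7)

PRIMER_LENGTH = 18
TM_SETPOINT = 60.0
TM_TOLERANCE = 1.5
MAX_HOMOPOLYMER = 4

#: cross-hybridization score at or above which a pair is called a dimer risk
DIMER_THRESHOLD = 16.0


def melting_temperature(seq: str, conditions: dict | None = None) -> float:
    """Nearest-neighbor Tm (SantaLucia parameters, Owczarzy salt correction)."""
    seq = validate_dna(seq, "primer")
    if len(seq) < 8:
        raise ValueError("Tm model needs at least 8 nt")
    return float(_mt.Tm_NN(seq, **(conditions or TM_CONDITIONS)))


@dataclass
class PrimerCandidate:
    sequence: str
    gc: float
    tm: float
    hairpin_flag: bool = False
    dimer_flag: bool = False
    cross_hyb_score: float = 0.0


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _self_hairpin(seq: str, stem: int = 5) -> bool:
    """Any >=stem-nt self-complementary stretch (fold-back potential)."""
    rc = revcomp(seq)
    return any(seq[i : i + stem] in rc for i in range(len(seq) - stem + 1))


def generate_primer_candidates(
    n: int, seed: int = 0, length: int = PRIMER_LENGTH
) -> list[PrimerCandidate]:
    """Rejection-sample ``n`` valid index-primer candidates (deterministic)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_gc = length // 2
    n_at = length - n_gc
    out: list[PrimerCandidate] = []
    seen: set[str] = set()
    while len(out) < n:
        g = int(rng.integers(2, n_gc - 1))
        a = int(rng.integers(2, n_at - 1))
        base = np.array(
            ["G"] * g + ["C"] * (n_gc - g) + ["A"] * a + ["T"] * (n_at - a)
        )
        perm = rng.permutation(length)
        seq = "".join(base[perm])
        if seq in seen:
            continue
        if _max_homopolymer(seq) > MAX_HOMOPOLYMER:
            continue
        if any(site in seq for site in FORBIDDEN_SITES):
            continue
        tm = melting_temperature(seq)
        if abs(tm - TM_SETPOINT) > TM_TOLERANCE:
            continue
        hairpin = _self_hairpin(seq)
        if hairpin:
            continue
        seen.add(seq)
        out.append(
            PrimerCandidate(sequence=seq, gc=gc_fraction(seq), tm=tm, hairpin_flag=False)
        )
    return out


def cross_hybridization_score(a: str, b: str) -> float:
    """Length of the longest Watson-Crick complementary run between a and b,
    doubled when the run reaches the 3' terminus of either primer.

    Symmetric: score(a, b) == score(b, a); a against its own reverse
    complement scores the maximal 2 * len.  Appending a base to ``a`` that
    extends a complementary run at its 3' end never decreases the score.
    """
    a, b = a.upper(), b.upper()
    # complementary run <=> common substring of a and revcomp(b)
    rb = revcomp(b)
    best = 0.0
    la, lb = len(a), len(rb)
    prev = [0] * (lb + 1)
    for i in range(1, la + 1):
        cur = [0] * (lb + 1)
        for j in range(1, lb + 1):
            if a[i - 1] == rb[j - 1]:
                run = prev[j - 1] + 1
                cur[j] = run
                # 3' anchored: run reaches a's 3' end (i == la) or b's 3'
                # end (run starts at the beginning of revcomp(b))
                weight = 2.0 if (i == la or j == run) else 1.0
                best = max(best, weight * run)
        prev = cur
    return best


def select_index_set(candidates: list[PrimerCandidate], k: int) -> list[PrimerCandidate]:
    """Keep the ``k`` candidates with the lowest aggregate cross-hybridization.

    Greedy removal of the worst aggregate offender until ``k`` remain; all
    surviving pairs must score below the hard dimer threshold.
    """
    if len(candidates) < k:
        raise ValueError(f"need at least {k} candidates, got {len(candidates)}")
    seqs = [c.sequence for c in candidates]
    n = len(seqs)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = cross_hybridization_score(seqs[i], seqs[j])
            scores[i, j] = scores[j, i] = s
    alive = list(range(n))
    # first clear hard dimer pairs: drop the member with most offences
    while True:
        sub = scores[np.ix_(alive, alive)]
        offences = (sub >= DIMER_THRESHOLD).sum(axis=1)
        if not offences.any():
            break
        order = np.lexsort((sub.sum(axis=1), offences))
        alive.pop(int(order[-1]))
    if len(alive) < k:
        raise ValueError(
            f"only {len(alive)} candidates survive the dimer threshold "
            f"{DIMER_THRESHOLD}; cannot keep {k}"
        )
    while len(alive) > k:
        sub = scores[np.ix_(alive, alive)]
        worst = alive[int(np.argmax(sub.sum(axis=1)))]
        alive.remove(worst)
    out = []
    for i in alive:
        c = candidates[i]
        out.append(
            PrimerCandidate(
                sequence=c.sequence, gc=c.gc, tm=c.tm,
                hairpin_flag=c.hairpin_flag,
                dimer_flag=False,
                cross_hyb_score=float(scores[i, alive].sum()),
            )
        )
    return out


# --------------------------------------------------------------- barcodes

def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def _pairwise_levenshtein(seqs: list[str]) -> np.ndarray:
    """Full pairwise Levenshtein matrix via a batched uint8 DP.

    One query row against all targets at once; O(n * L^2) vectorized over
    n, which keeps thousands of 18-mers tractable.
    """
    codes = {b: i for i, b in enumerate("ACGT")}
    arr = np.array([[codes[c] for c in s] for s in seqs], dtype=np.uint8)
    n, L = arr.shape
    out = np.zeros((n, n), dtype=np.uint8)
    init = np.broadcast_to(np.arange(L + 1, dtype=np.uint8), (n, L + 1))
    for qi in range(n):
        q = arr[qi]
        prev = init.copy()
        for i in range(1, L + 1):
            cur = np.empty_like(prev)
            cur[:, 0] = i
            sub = prev[:, :-1] + (arr != q[i - 1]).astype(np.uint8)
            for j in range(1, L + 1):
                cur[:, j] = np.minimum(
                    np.minimum(cur[:, j - 1] + 1, prev[:, j] + 1), sub[:, j - 1]
                )
            prev = cur
        out[qi] = prev[:, -1]
    return out


@dataclass
class BarcodeSet:
    members: list[str]
    min_pairwise_distance: int
    mean_pairwise_distance: float


def select_barcode_set(
    candidates: list[PrimerCandidate] | list[str],
    size: int = 96,
    min_distance: int = 8,
) -> BarcodeSet:
    """Greedy max-min selection of an edit-distance-separated barcode set.

    Seeds with the globally farthest candidate pair, then repeatedly adds
    the candidate whose minimum Levenshtein distance to the chosen set is
    largest, until ``size`` members are chosen.  Raises when the requested
    floor cannot be met, reporting the best achievable set size.
    """
    seqs = [getattr(c, "sequence", c) for c in candidates]
    seqs = list(dict.fromkeys(seqs))
    if len(seqs) < size:
        raise ValueError(f"need at least {size} distinct candidates")
    dist = _pairwise_levenshtein(seqs).astype(int)
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    chosen = [int(i), int(j)]
    min_to_chosen = np.minimum(dist[i], dist[j])
    while len(chosen) < size:
        min_to_chosen[chosen] = -1
        nxt = int(np.argmax(min_to_chosen))
        if min_to_chosen[nxt] < min_distance:
            raise ValueError(
                f"distance floor {min_distance} unreachable beyond "
                f"{len(chosen)} barcodes (best next candidate at "
                f"{int(min_to_chosen[nxt])})"
            )
        chosen.append(nxt)
        min_to_chosen = np.minimum(min_to_chosen, dist[nxt])
    sub = dist[np.ix_(chosen, chosen)]
    tri = sub[np.triu_indices(len(chosen), k=1)]
    return BarcodeSet(
        members=[seqs[c] for c in chosen],
        min_pairwise_distance=int(tri.min()),
        mean_pairwise_distance=float(tri.mean()),
    )
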