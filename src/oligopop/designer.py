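"""Protein-preserving sequence design.

Domestication removes forbidden motifs (type IIS recognition sites on either
strand), duplicated k-mers and long inverted repeats from a coding sequence
using only synonymous codon substitutions.  GC tuning additionally enforces
a minimum GC content over a sliding window, weighting the GC objective
``gc_boost``-fold against codon-usage match.  The engine is a per-codon
local search: violations are located, and codons overlapping each violating
span are swapped for synonymous alternatives until the checkers pass.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np

from .codon_tables import CodonTable
from .dna import find_all, gc_fraction, revcomp, translate, validate_dna
from .synth import CODONS_BY_AA, STOP_CODONS, _AA_OF

_DEFAULT_PATTERNS = ("GGTCTC", "CGTCTC", "GAAGAC")


@dataclass
class DesignConstraints:
    """Hard design constraints applied by domestication.

    ``avoid_patterns`` are scanned on both strands.  ``unique_kmer_k`` bans
    any duplicated k-mer (either strand).  A hairpin is an inverted repeat
    whose two stems (each >= ``hairpin_stem_min`` nt) both lie within a
    ``hairpin_window`` nt span.  ``gc_min`` (when set) is enforced on every
    ``gc_window`` sliding window, with the GC objective weighted
    ``gc_boost``-fold relative to codon usage.
    """

    avoid_patterns: tuple[str, ...] = _DEFAULT_PATTERNS
    unique_kmer_k: int = 12
    hairpin_stem_min: int = 20
    hairpin_window: int = 250
    gc_min: float | None = None
    gc_window: int = 60
    gc_boost: float = 4.0
    gc_tolerance: float = 0.02

    def __post_init__(self) -> None:
        if self.unique_kmer_k < 8:
            raise ValueError("unique_kmer_k must be >= 8")
        if self.hairpin_window <= self.hairpin_stem_min:
            raise ValueError("hairpin_window must exceed hairpin_stem_min")
        if self.gc_min is not None and not 0 <= self.gc_min < 1:
            raise ValueError("gc_min must be in [0, 1)")

    @property
    def all_patterns(self) -> tuple[str, ...]:
        pats = []
        for p in self.avoid_patterns:
            pats.append(p)
            if revcomp(p) != p:
                pats.append(revcomp(p))
        return tuple(dict.fromkeys(pats))


class DesignError(ValueError):
    """Raised when a constraint cannot be satisfied synonymously."""


# ---------------------------------------------------------------- checkers

def find_pattern_violations(seq: str, constraints: DesignConstraints) -> list[tuple[int, int, str]]:
    """(start, end, pattern) spans of forbidden motifs on either strand."""
    out = []
    for pat in constraints.all_patterns:
        for i in find_all(seq, pat):
            out.append((i, i + len(pat), pat))
    return sorted(out)


def find_kmer_violations(seq: str, constraints: DesignConstraints) -> list[tuple[int, int, str]]:
    """Spans of k-mers repeated elsewhere (either strand, later copy flagged)."""
    k = constraints.unique_kmer_k
    first_seen: dict[str, int] = {}
    out = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        canon = min(kmer, revcomp(kmer))
        j = first_seen.setdefault(canon, i)
        if j != i:
            out.append((i, i + k, f"repeat of {k}-mer at {j}"))
    return out


def find_hairpin_violations(seq: str, constraints: DesignConstraints) -> list[tuple[int, int, str]]:
    """Spans of downstream arms of inverted repeats within the window."""
    stem = constraints.hairpin_stem_min
    window = constraints.hairpin_window
    pos: dict[str, list[int]] = {}
    for i in range(len(seq) - stem + 1):
        pos.setdefault(seq[i : i + stem], []).append(i)
    out = []
    for i in range(len(seq) - stem + 1):
        target = revcomp(seq[i : i + stem])
        hits = pos.get(target)
        if not hits:
            continue
        lo = bisect.bisect_right(hits, i)
        for j in hits[lo:]:
            if j + stem - i > window:
                break
            out.append((j, j + stem, f"inverted repeat of arm at {i}"))
    return sorted(set(out))


def find_gc_violations(seq: str, constraints: DesignConstraints, slack: float = 0.0) -> list[tuple[int, int, str]]:
    """Sliding windows whose GC falls below gc_min - slack."""
    if constraints.gc_min is None or constraints.gc_min <= 0:
        return []
    w = constraints.gc_window
    if len(seq) < w:
        windows = [(0, len(seq))]
    else:
        windows = [(i, i + w) for i in range(0, len(seq) - w + 1)]
    floor = constraints.gc_min - slack
    out = []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8)).astype(int)
    cum = np.concatenate([[0], np.cumsum(is_gc)])
    for a, b in windows:
        gc = (cum[b] - cum[a]) / (b - a)
        if gc < floor - 1e-12:
            out.append((a, b, f"window GC {gc:.3f} < {floor:.3f}"))
    return out


def check_constraints(seq: str, constraints: DesignConstraints, gc_slack: float | None = None) -> list[tuple[int, int, str]]:
    """All hard-constraint violations of ``seq`` (empty list = compliant)."""
    if gc_slack is None:
        gc_slack = constraints.gc_tolerance
    return (
        find_pattern_violations(seq, constraints)
        + find_kmer_violations(seq, constraints)
        + find_hairpin_violations(seq, constraints)
        + find_gc_violations(seq, constraints, slack=gc_slack)
    )


# ------------------------------------------------------------- codon tools

def _split_codons(cds: str) -> list[str]:
    cds = validate_dna(cds, "CDS")
    if len(cds) % 3:
        raise DesignError(f"CDS length {len(cds)} not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for idx, c in enumerate(codons[:-1]):
        if c in STOP_CODONS:
            raise DesignError(f"internal stop codon {c} at codon {idx}")
    return codons

def _synonyms(codon: str) -> list[str]:
    if codon in STOP_CODONS:
        return list(STOP_CODONS)
    return CODONS_BY_AA[_AA_OF[codon]]


def _codon_gc(codon: str) -> int:
    return codon.count("G") + codon.count("C")


def codon_optimize(
    protein_or_cds: str,
    table: CodonTable,
    mode: str = "match_usage",
    seed: int = 0,
) -> str:
    """Recode a protein or CDS under a codon usage table.

    ``best_codon`` uses each amino acid's most frequent codon (CAI = 1).
    ``match_usage`` apportions codons per amino acid to match the table's
    relative frequencies (largest-remainder quotas, seeded placement), the
    strategy behind usage-matching optimizers.  CDS input keeps its stop
    codon and yields an identical translation.
    """
    s = protein_or_cds.upper()
    if set(s) <= set("ACGT") and len(s) % 3 == 0 and len(s) >= 6:
        codons = _split_codons(s)
        protein = [(_AA_OF[c] if c not in STOP_CODONS else "*") for c in codons]
    else:
        protein = list(s)
        if protein[-1] != "*":
            protein = protein + ["*"]
    if mode == "best_codon":
        return "".join(table.best_codon(aa) for aa in protein)
    if mode != "match_usage":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    out: list[str | None] = [None] * len(protein)
    by_aa: dict[str, list[int]] = {}
    for i, aa in enumerate(protein):
        by_aa.setdefault(aa, []).append(i)
    for aa, positions in by_aa.items():
        codons = table.codons_for(aa)
        n = len(positions)
        quotas = np.array([table.frequency(c) * n for c in codons])
        counts = np.floor(quotas).astype(int)
        remainder = quotas - counts
        for idx in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
            counts[idx] += 1
        bag = [c for c, k in zip(codons, counts) for _ in range(k)]
        order = rng.permutation(n)
        for slot, pos_idx in enumerate(order):
            out[positions[pos_idx]] = bag[slot]
    return "".join(out)  # type: ignore[arg-type]


# ------------------------------------------------------------- repair core

def _violating_codon_indices(span: tuple[int, int], n_codons: int) -> list[int]:
    lo = span[0] // 3
    hi = min((span[1] - 1) // 3, n_codons - 1)
    return list(range(lo, hi + 1))


def _local_ok(seq: str, constraints: DesignConstraints, span: tuple[int, int]) -> bool:
    """No forbidden pattern overlapping the edited neighbourhood."""
    a = max(0, span[0] - 8)
    b = min(len(seq), span[1] + 8)
    region = seq[a:b]
    return not any(p in region for p in constraints.all_patterns)


def _structural_violations(seq: str, constraints: DesignConstraints):
    return (
        find_pattern_violations(seq, constraints)
        + find_kmer_violations(seq, constraints)
        + find_hairpin_violations(seq, constraints)
    )


def _repair(
    codons: list[str],
    constraints: DesignConstraints,
    table: CodonTable,
    rng,
    max_rounds: int = 80,
) -> tuple[list[str], int]:
    """Iteratively remove all hard-constraint violations; returns edit count.

    Structural violations (motifs, repeats, hairpins) are fixed one span at
    a time; GC-floor violations are swept window by window toward the full
    ``gc_min``, accepting a window only when it is within ``gc_tolerance``
    and no synonymous swap can improve it further.
    """
    edits = 0
    for _ in range(max_rounds):
        seq = "".join(codons)
        other = _structural_violations(seq, constraints)
        if other:
            span = other[0][:2]
            if not _fix_span(codons, span, constraints, table, rng):
                raise DesignError(
                    f"cannot synonymously resolve constraint in window "
                    f"[{span[0]}, {span[1]}): {other[0][2]}"
                )
            edits += 1
            continue
        if constraints.gc_min is None:
            return codons, edits
        # GC sweep: cheap window recomputation between single-codon swaps
        stuck: set[int] = set()
        for _ in range(8 * len(codons) + 50):
            seq = "".join(codons)
            gc_viols = [
                v for v in find_gc_violations(seq, constraints, slack=0.0)
                if v[0] not in stuck
            ]
            if not gc_viols:
                break
            span = gc_viols[0][:2]
            if _raise_gc_in_window(codons, span, constraints, table, rng):
                edits += 1
                continue
            hard = find_gc_violations(
                seq, constraints, slack=constraints.gc_tolerance
            )
            if any(v[0] == span[0] for v in hard):
                raise DesignError(
                    f"window [{span[0]}, {span[1]}) cannot reach GC >= "
                    f"{constraints.gc_min} with synonymous codons"
                )
            stuck.add(span[0])  # within tolerance, no further gain possible
        else:
            raise DesignError("GC repair did not converge")
        seq = "".join(codons)
        if not _structural_violations(seq, constraints) and not [
            v
            for v in find_gc_violations(seq, constraints, constraints.gc_tolerance)
        ]:
            return codons, edits
    raise DesignError("constraint repair did not converge")


def _fix_span(codons, span, constraints, table, rng) -> bool:
    """Try synonymous swaps of codons overlapping ``span``; True on success."""
    n = len(codons)
    seq_before = "".join(codons)
    region_had = seq_before[max(0, span[0] - 1) : span[1] + 1]
    candidates = _violating_codon_indices(span, n)
    rng.shuffle(candidates)
    for ci in candidates:
        cur = codons[ci]
        alts = [c for c in _synonyms(cur) if c != cur]
        # prefer frequent codons; break ties by GC when a floor is active
        gc_w = constraints.gc_boost if constraints.gc_min else 0.0
        alts.sort(key=lambda c: (table.frequency(c) + gc_w * _codon_gc(c) / 3, c), reverse=True)
        for alt in alts:
            codons[ci] = alt
            seq = "".join(codons)
            # the specific violation must be gone and no motif newly created
            still = any(
                a < span[1] and b > span[0]
                for a, b, _ in check_constraints(seq, replace(constraints, gc_min=None), gc_slack=0)
            )
            if not still and _local_ok(seq, constraints, (ci * 3, ci * 3 + 3)):
                return True
        codons[ci] = cur
    return False


def _raise_gc_in_window(codons, span, constraints, table, rng) -> bool:
    """Greedily swap codons in a low-GC window toward GC-richer synonyms."""
    n = len(codons)
    idxs = _violating_codon_indices(span, n)
    best = None
    for ci in idxs:
        cur = codons[ci]
        for alt in _synonyms(cur):
            gain = _codon_gc(alt) - _codon_gc(cur)
            if gain <= 0:
                continue
            score = constraints.gc_boost * gain / 3 + (
                table.frequency(alt) - table.frequency(cur)
            )
            codons[ci] = alt
            seq = "".join(codons)
            clean = not any(
                a < ci * 3 + 3 + 8 and b > ci * 3 - 8
                for a, b, _ in find_pattern_violations(seq, constraints)
            )
            codons[ci] = cur
            if clean and (best is None or score > best[0]):
                best = (score, ci, alt)
    if best is None:
        return False
    _, ci, alt = best
    codons[ci] = alt
    return True


def domesticate(
    cds: str,
    constraints: DesignConstraints | None = None,
    table: CodonTable | None = None,
    seed: int = 0,
) -> str:
    """Remove forbidden motifs, repeats and hairpins with synonymous edits.

    Only codons inside violating spans are touched, so compliant input is
    returned unchanged.  Raises :class:`DesignError` naming the stuck window
    when no synonymous fix exists.
    """
    from .codon_tables import arabidopsis_table

    constraints = constraints or DesignConstraints()
    table = table or arabidopsis_table()
    if constraints.gc_min:
        constraints = replace(constraints, gc_min=None)
    rng = np.random.default_rng(seed)
    codons = _split_codons(cds)
    before = translate(cds)
    codons, _ = _repair(codons, constraints, table, rng)
    out = "".join(codons)
    assert translate(out) == before
    return out


def gc_tune(
    cds: str,
    gc_min: float,
    constraints: DesignConstraints | None = None,
    table: CodonTable | None = None,
    seed: int = 0,
) -> str:
    """Codon-usage optimize then enforce a windowed minimum GC content.

    Every ``gc_window`` sliding window of the result has GC >= gc_min -
    gc_tolerance; all domestication constraints are preserved.  With
    ``gc_min`` 0 this reduces to usage matching plus domestication.
    """
    from .codon_tables import arabidopsis_table

    constraints = constraints or DesignConstraints()
    table = table or arabidopsis_table()
    constraints = replace(constraints, gc_min=gc_min if gc_min else None)
    before = translate(cds)
    recoded = codon_optimize(cds, table, mode="match_usage", seed=seed)
    rng = np.random.default_rng(seed)
    codons = _split_codons(recoded)
    codons, _ = _repair(codons, constraints, table, rng)
    out = "".join(codons)
    assert translate(out) == before
    return out


# ---------------------------------------------------------------- metrics

def sequence_metrics(cds: str, table: CodonTable) -> dict:
    """GC, GC3s, CAI and a windowed GC profile for a CDS.

    CAI is the geometric mean of each codon's relative adaptiveness
    w = f(codon)/f(best synonym); stops and single-codon amino acids
    (Met, Trp) are excluded, following the standard definition.
    """
    if not cds:
        raise ValueError("empty sequence")
    cds = validate_dna(cds, "CDS")
    codons = _split_codons(cds)
    logs = []
    gc3_count = 0
    gc3_total = 0
    for c in codons:
        if c in STOP_CODONS:
            continue
        syn = CODONS_BY_AA[_AA_OF[c]]
        if len(syn) == 1:
            continue
        gc3_total += 1
        gc3_count += c[2] in "GC"
        w = table.relative_adaptiveness(c)
        if w <= 0:
            w = 1e-4  # absent codon: conventional floor
        logs.append(np.log(w))
    w60 = [
        gc_fraction(cds[i : i + 60]) for i in range(0, max(1, len(cds) - 59))
    ]
    return {
        "gc": gc_fraction(cds),
        "gc3s": gc3_count / gc3_total if gc3_total else float("nan"),
        "cai": float(np.exp(np.mean(logs))) if logs else float("nan"),
        "length_nt": len(cds),
        "length_aa": len(codons) - (codons[-1] in STOP_CODONS),
        "window_gc": w60,
    }
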