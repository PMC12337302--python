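"""Splice-junction prediction and iterative removal ("deintronization").

Coding sequences destined for plant nuclear expression can contain cryptic
splice donor/acceptor junctions.  The default predictor is a log-odds
position-weight model of the canonical plant motifs — donor MAG|GTAAGT and
acceptor polypyrimidine-tract...YAG| — scanned in sliding windows.  Any
scorer with the same call signature can be plugged in instead (e.g. an
adapter around an external ML model); predictions from the default PWM are
a motif-level stand-in, not a reproduction of any particular model's
scores.  Deintronization alternates prediction with synonymous mutation of
the predicted junctions, keeping all domestication constraints satisfied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codon_tables import CodonTable
from .designer import (
    DesignConstraints,
    _repair,
    _split_codons,
    _synonyms,
    check_constraints,
)
from .dna import translate, validate_dna

_B = {b: i for i, b in enumerate("ACGT")}


def _log_odds(rows: list[dict[str, float]]) -> np.ndarray:
    w = np.zeros((len(rows), 4))
    for i, probs in enumerate(rows):
        for b, p in probs.items():
            w[i, _B[b]] = np.log2(max(p, 1e-3) / 0.25)
    return w


# donor: 3 exonic (M A G) | 6 intronic (G T A A G T); GT nearly invariant
_DONOR_PWM = _log_odds(
    [
        {"A": 0.35, "C": 0.35, "G": 0.18, "T": 0.12},
        {"A": 0.60, "C": 0.12, "G": 0.16, "T": 0.12},
        {"A": 0.10, "C": 0.04, "G": 0.80, "T": 0.06},
        {"A": 0.01, "C": 0.01, "G": 0.97, "T": 0.01},
        {"A": 0.01, "C": 0.01, "G": 0.01, "T": 0.97},
        {"A": 0.60, "C": 0.10, "G": 0.15, "T": 0.15},
        {"A": 0.70, "C": 0.08, "G": 0.10, "T": 0.12},
        {"A": 0.07, "C": 0.06, "G": 0.80, "T": 0.07},
        {"A": 0.15, "C": 0.15, "G": 0.15, "T": 0.55},
    ]
)
_DONOR_CUT = 3  # index of the invariant G of GT within the motif

# acceptor: 8 polypyrimidine positions, then Y A G | exonic G-biased base
_PY = {"A": 0.08, "C": 0.42, "G": 0.08, "T": 0.42}
_ACCEPTOR_PWM = _log_odds(
    [_PY] * 8
    + [
        {"A": 0.05, "C": 0.45, "G": 0.05, "T": 0.45},
        {"A": 0.97, "C": 0.01, "G": 0.01, "T": 0.01},
        {"A": 0.01, "C": 0.01, "G": 0.97, "T": 0.01},
        {"A": 0.25, "C": 0.15, "G": 0.45, "T": 0.15},
    ]
)
_ACCEPTOR_CUT = 9  # index of the invariant A of AG


@dataclass
class SpliceSitePrediction:
    position: int  # 0-based index of the motif's invariant dinucleotide
    kind: str  # "donor" | "acceptor"
    score: float
    window_start: int = 0
    window_end: int = 0


class PWMSplicePredictor:
    """Log-odds PWM scorer for donor and acceptor junction motifs.

    ``donor_threshold``/``acceptor_threshold`` are log2-odds scores; the
    defaults flag strong consensus-like sites while leaving a typical
    random coding sequence nearly clean.
    """

    def __init__(self, donor_threshold: float = 9.0, acceptor_threshold: float = 9.0):
        self.donor_threshold = donor_threshold
        self.acceptor_threshold = acceptor_threshold

    def _scan(self, seq: str, pwm: np.ndarray, cut: int, kind: str, threshold: float):
        L, k = len(seq), pwm.shape[0]
        if L < k:
            return
        enc = np.array([_B.get(b, 0) for b in seq])
        for i in range(L - k + 1):
            score = float(pwm[np.arange(k), enc[i : i + k]].sum())
            if score >= threshold:
                yield SpliceSitePrediction(position=i + cut, kind=kind, score=score)

    def __call__(self, seq: str, threshold: float | None = None):
        preds = list(
            self._scan(seq, _DONOR_PWM, _DONOR_CUT, "donor",
                       self.donor_threshold if threshold is None else threshold)
        ) + list(
            self._scan(seq, _ACCEPTOR_PWM, _ACCEPTOR_CUT, "acceptor",
                       self.acceptor_threshold if threshold is None else threshold)
        )
        return sorted(preds, key=lambda p: (p.position, p.kind))


def predict_splice_sites(
    seq: str,
    predictor: PWMSplicePredictor | None = None,
    window: int = 200,
    threshold: float | None = None,
) -> list[SpliceSitePrediction]:
    """All donor/acceptor predictions with score >= threshold.

    The sequence is processed in overlapping ``window``-bp panes (recorded
    on each prediction); the calls are identical to a whole-sequence scan.
    """
    seq = validate_dna(seq)
    predictor = predictor or PWMSplicePredictor()
    preds = predictor(seq, threshold)
    for p in preds:
        p.window_start = max(0, (p.position // window) * window)
        p.window_end = min(len(seq), p.window_start + window)
    return preds


def _disrupt_site(codons, pred: SpliceSitePrediction, constraints, table, rng) -> bool:
    """Synonymously mutate a codon inside the predicted motif to kill the call."""
    if pred.kind == "donor":
        m_start, m_end = pred.position - _DONOR_CUT, pred.position - _DONOR_CUT + len(_DONOR_PWM)
    else:
        m_start, m_end = pred.position - _ACCEPTOR_CUT, pred.position - _ACCEPTOR_CUT + len(_ACCEPTOR_PWM)
    targets = list(range(max(0, m_start // 3), min(len(codons) - 1, (m_end - 1) // 3) + 1))
    predictor = PWMSplicePredictor()
    n = len(codons)
    for ci in targets:
        if ci < 0 or ci >= n:
            continue
        cur = codons[ci]
        alts = [c for c in _synonyms(cur) if c != cur]
        alts.sort(key=lambda c: (table.frequency(c), c), reverse=True)
        for alt in alts:
            codons[ci] = alt
            seq = "".join(codons)
            lo, hi = max(0, m_start - 12), min(len(seq), m_end + 12)
            still = any(p.kind == pred.kind for p in predictor(seq[lo:hi]))
            nearby_pattern = any(
                pat in seq[max(0, ci * 3 - 8) : ci * 3 + 11]
                for pat in constraints.all_patterns
            )
            if not still and not nearby_pattern:
                return True
        codons[ci] = cur
    return False


def deintronize(
    cds: str,
    constraints: DesignConstraints | None = None,
    table: CodonTable | None = None,
    predictor: PWMSplicePredictor | None = None,
    max_iterations: int = 4,
    seed: int = 0,
    n_seeds: int = 3,
) -> tuple[str, list[SpliceSitePrediction]]:
    """Iteratively purge predicted splice junctions with synonymous edits.

    Runs up to ``max_iterations`` predict-and-mutate passes; when residual
    sites remain, retries from additional seeds and returns the best run
    (fewest residual sites, then fewest edits).  Translation and all
    domestication constraints are preserved.
    """
    from .codon_tables import arabidopsis_table

    constraints = constraints or DesignConstraints()
    table = table or arabidopsis_table()
    predictor = predictor or PWMSplicePredictor()
    before = translate(cds)

    best: tuple[int, int, str, list] | None = None
    for attempt in range(max(1, n_seeds)):
        rng = np.random.default_rng(seed + attempt)
        codons = _split_codons(cds)
        edits = 0
        for _ in range(max_iterations):
            preds = predictor("".join(codons))
            if not preds:
                break
            progressed = False
            for pred in preds:
                if _disrupt_site(codons, pred, constraints, table, rng):
                    edits += 1
                    progressed = True
            codons, extra = _repair(codons, constraints, table, rng)
            edits += extra
            if not progressed:
                break
        residual = predictor("".join(codons))
        key = (len(residual), edits, "".join(codons), residual)
        if best is None or key[:2] < best[:2]:
            best = key
        if not residual:
            break
    assert best is not None
    out, residual = best[2], best[3]
    assert translate(out) == before
    return out, residual
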