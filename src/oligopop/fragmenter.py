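"""Fragmentation of a designed sequence at hingeset-constrained junctions.

A target (prepared so its first four bases are the 5' terminal overhang and
its last four the 3' terminal overhang, e.g. AATG...GCTT for a coding
sequence) is cut into the minimal number of fragments fitting the oligo
payload budget.  Each internal junction's 4-mer must be drawn from the
constraining hingeset, be distinct and reverse-complement-distinct from all
other junctions in the plan, and lie within a radius of the ideal
equidistant cut position.  Because every admissible plan's overhangs are a
subset of the hingeset, a plan's predicted fidelity is always at least the
constraining set's fidelity; among admissible plans the search maximizes
predicted fidelity, breaking ties toward ideal positions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .dna import is_palindrome, revcomp, validate_dna
from .fidelity import OverhangMatrix, overhang_list_fidelity
from .hingesets import Hingeset

DEFAULT_TERMINALS = ("AATG", "GCTT")

#: exhaustive-search budget; larger junction spaces fall back to guided DFS
_ENUM_CAP = 20000


class FragmentationError(ValueError):
    pass


@dataclass
class FragmentPlan:
    target_id: str
    cut_positions: list[int]  # internal junctions; overhang occupies [p, p+4)
    overhangs: list[str]  # terminal 5', internals..., terminal 3'
    fragments: list[str]  # payloads, neighbours overlap by exactly 4 nt
    predicted_fidelity: float
    constraining_set: Hingeset | None = None
    max_payload: int = 198

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def assembled(self) -> str:
        """Collapse the 4-nt overlaps; must reproduce the input target."""
        out = self.fragments[0]
        for frag in self.fragments[1:]:
            assert out[-4:] == frag[:4], "junction overhang mismatch"
            out += frag[4:]
        return out

    def validate(self, target: str) -> list[str]:
        problems = []
        if self.assembled() != target:
            problems.append("fragments do not reassemble the target")
        pool = set()
        for o in self.overhangs:
            if o in pool or revcomp(o) in pool:
                problems.append(f"overhang {o} collides within the plan")
            pool.add(o)
        for i, frag in enumerate(self.fragments):
            if len(frag) > self.max_payload:
                problems.append(f"fragment {i} exceeds payload budget")
        return problems

    def to_json(self) -> str:
        return json.dumps(
            {
                "target_id": self.target_id,
                "cut_positions": self.cut_positions,
                "overhangs": self.overhangs,
                "fragments": self.fragments,
                "predicted_fidelity": self.predicted_fidelity,
                "max_payload": self.max_payload,
                "constraining_set": (
                    self.constraining_set.members if self.constraining_set else None
                ),
            },
            indent=2,
        )


def prepare_cds(cds: str, terminals: tuple[str, str] = DEFAULT_TERMINALS) -> str:
    """Add terminal-overhang context to a CDS: A + cds + GCTT.

    The AATG overhang embeds the start codon (standard coding-sequence part
    syntax); GCTT follows the stop.
    """
    cds = validate_dna(cds, "CDS")
    if not cds.startswith("ATG"):
        raise ValueError("CDS must start with ATG")
    prepared = "A" + cds + "GCTT"
    assert prepared[:4] == terminals[0] and prepared[-4:] == terminals[1]
    return prepared


def candidate_junctions(
    seq: str,
    ideal_pos: int,
    radius: int,
    allowed,
    taken=(),
) -> list[tuple[int, str]]:
    """Admissible (position, overhang) pairs within ``radius`` of ``ideal_pos``.

    The 4-mer at each position must belong to ``allowed`` and be distinct
    from and non-reverse-complementary to everything in ``taken``.  Sorted
    by distance from the ideal position (then position).
    """
    if not 0 <= ideal_pos < len(seq):
        raise ValueError("ideal_pos outside the sequence")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    allowed_set = set(getattr(allowed, "members", allowed))
    taken_set = set(getattr(taken, "members", taken))
    blocked = taken_set | {revcomp(t) for t in taken_set}
    out = []
    for p in range(max(0, ideal_pos - radius), min(len(seq) - 4, ideal_pos + radius) + 1):
        o = seq[p : p + 4]
        if o in allowed_set and o not in blocked and not is_palindrome(o):
            out.append((p, o))
    return sorted(out, key=lambda po: (abs(po[0] - ideal_pos), po[0]))


def minimal_fragment_count(length: int, max_payload: int) -> int:
    """Smallest n with (length + 4*(n-1)) / n <= max_payload."""
    if length <= max_payload:
        return 1
    return math.ceil((length - 4) / (max_payload - 4))


def _search(seq, n, hingeset_members, terminals, max_payload, radius, matrix):
    """Enumerate admissible junction assignments for a fixed fragment count.

    Returns (cuts, overhangs) of the fidelity-optimal assignment or None.
    Exhaustive when the candidate space is small, otherwise a guided DFS
    (candidates nearest the ideal positions first) followed by a
    coordinate-improvement pass; both deterministic.
    """
    L = len(seq)
    ideals = [round(i * L / n) for i in range(1, n)]
    allowed = [m for m in hingeset_members if m not in terminals
               and revcomp(m) not in terminals]
    base_taken = list(terminals)
    per_junction = [
        candidate_junctions(seq, ip, radius, allowed, base_taken) for ip in ideals
    ]
    if any(not c for c in per_junction):
        bad = per_junction.index([])
        raise FragmentationError(
            f"no admissible junction within radius {radius} of position "
            f"{ideals[bad]}; increase the radius or use a larger hingeset"
        )

    space = 1
    for c in per_junction:
        space *= len(c)

    def payload_ok(prev_cut, cut, junction_index):
        if cut + 4 - prev_cut > max_payload:
            return False
        remaining = n - (junction_index + 1)
        return (L - cut) + 0 <= remaining * max_payload - 4 * (remaining - 1)

    def feasible_next(junction_index, prev_cut, used):
        for p, o in per_junction[junction_index]:
            if p <= prev_cut:
                continue
            if o in used or revcomp(o) in used:
                continue
            if not payload_ok(prev_cut, p, junction_index):
                continue
            yield p, o

    solutions: list[tuple[list[int], list[str]]] = []

    def dfs_all(ji, prev_cut, used, cuts, ovs):
        if ji == n - 1:
            if L - prev_cut <= max_payload:
                solutions.append((cuts[:], ovs[:]))
            return
        for p, o in feasible_next(ji, prev_cut, used):
            used |= {o}
            dfs_all(ji + 1, p, used, cuts + [p], ovs + [o])
            used -= {o}

    def score(cuts, ovs):
        fid = overhang_list_fidelity(list(terminals) + ovs, matrix)
        offsets = sum(abs(c - i) for c, i in zip(cuts, ideals))
        return (fid, -offsets, tuple(sorted(ovs)))

    if space <= _ENUM_CAP:
        dfs_all(0, 0, set(terminals) | {revcomp(t) for t in terminals}, [], [])
        if not solutions:
            return None
        return max(solutions, key=lambda s: score(*s))

    # guided DFS: first feasible solution, candidates nearest ideal first
    def dfs_first(ji, prev_cut, used, cuts, ovs):
        if ji == n - 1:
            return (cuts, ovs) if L - prev_cut <= max_payload else None
        for p, o in feasible_next(ji, prev_cut, used):
            got = dfs_first(ji + 1, p, used | {o}, cuts + [p], ovs + [o])
            if got:
                return got
        return None

    first = dfs_first(0, 0, set(terminals) | {revcomp(t) for t in terminals}, [], [])
    if first is None:
        return None
    cuts, ovs = first
    improved = True
    while improved:
        improved = False
        for j in range(n - 1):
            prev_cut = cuts[j - 1] if j else 0
            next_cut = cuts[j + 1] if j + 1 < n - 1 else L - max_payload + 0
            used = set(ovs) - {ovs[j]} | {revcomp(o) for o in set(ovs) - {ovs[j]}}
            used |= set(terminals) | {revcomp(t) for t in terminals}
            for p, o in per_junction[j]:
                if p <= prev_cut or (j + 1 < n - 1 and p >= cuts[j + 1]):
                    continue
                if o in used or revcomp(o) in used:
                    continue
                if p + 4 - prev_cut > max_payload:
                    continue
                nxt = cuts[j + 1] + 4 if j + 1 < n - 1 else L
                if nxt - p > max_payload:
                    continue
                trial_c, trial_o = cuts[:], ovs[:]
                trial_c[j], trial_o[j] = p, o
                if score(trial_c, trial_o) > score(cuts, ovs):
                    cuts, ovs = trial_c, trial_o
                    improved = True
    return cuts, ovs


def fragment_sequence(
    seq: str,
    hingeset: Hingeset,
    m: OverhangMatrix,
    max_payload: int = 198,
    radius: int = 30,
    terminal_overhangs: tuple[str, str] = DEFAULT_TERMINALS,
    target_id: str = "target",
) -> FragmentPlan:
    """Cut ``seq`` into the fewest budget-fitting fragments at hingeset junctions.

    ``seq`` must begin with the 5' terminal overhang and end with the 3'
    one.  Fragment payload spans include both flanking overhangs, so n
    fragments carry length + 4*(n-1) payload in total.  If no junction
    assignment exists at the minimal n, n is incremented (the payload
    budget permitting) before giving up.
    """
    seq = validate_dna(seq)
    t5, t3 = terminal_overhangs
    if seq[:4] != t5 or seq[-4:] != t3:
        raise FragmentationError(
            f"sequence must start with {t5} and end with {t3} "
            "(use prepare_cds for coding sequences)"
        )
    n0 = minimal_fragment_count(len(seq), max_payload)
    last_err = None
    for n in range(n0, n0 + 4):
        if n == 1:
            return FragmentPlan(
                target_id=target_id,
                cut_positions=[],
                overhangs=[t5, t3],
                fragments=[seq],
                predicted_fidelity=overhang_list_fidelity([t5, t3], m),
                constraining_set=hingeset,
                max_payload=max_payload,
            )
        try:
            got = _search(seq, n, hingeset.members, terminal_overhangs,
                          max_payload, radius, m)
        except FragmentationError as err:
            got, last_err = None, err
        if got is None:
            continue
        cuts, ovs = got
        bounds = [0] + cuts
        fragments = [
            seq[a : (cuts[i] + 4 if i < len(cuts) else len(seq))]
            for i, a in enumerate(bounds)
        ]
        plan = FragmentPlan(
            target_id=target_id,
            cut_positions=cuts,
            overhangs=[t5] + ovs + [t3],
            fragments=fragments,
            predicted_fidelity=overhang_list_fidelity([t5] + ovs + [t3], m),
            constraining_set=hingeset,
            max_payload=max_payload,
        )
        assert not plan.validate(seq)
        return plan
    if last_err:
        raise last_err
    raise FragmentationError(
        f"no admissible fragmentation of {target_id} within radius {radius}"
    )
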