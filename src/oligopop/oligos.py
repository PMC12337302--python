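"""Oligo layout, in-silico type IIS digestion and ligation, pool tables.

Each fragment payload (which carries its 4-nt junction overhangs at both
ends) is wrapped into a synthesizable oligo:

    fwd_index(18) + recognition + spacer + payload
        + rc(spacer) appended as rc, i.e. ... + rc(spacer+recognition-unit)
        + rc(rev_index)(18)

so that digesting the oligo with the run's enzyme releases exactly the
payload with its designed 5' overhangs.  With 18-mer indexes and BbsI
(6-nt site, 2-nt spacer) the per-oligo overhead is 52 nt, leaving 198 nt of
payload inside a 250-nt synthesis budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dna import TYPE_IIS_SITES, TYPE_IIS_SPACER, find_all, revcomp
from .fragmenter import FragmentPlan

#: default spacer bases between recognition site and cut (per side); swapped
#: for an alternative when the junction context would recreate a site
_DEFAULT_SPACERS = {1: "A", 2: "TT"}
_FALLBACK_SPACERS = {1: "T", 2: "AA"}

DEFAULT_OLIGO_ENZYME = "BbsI"
OLIGO_BUDGET = 250


class LayoutError(ValueError):
    pass


@dataclass
class OligoRecord:
    target_id: str
    fragment_index: int
    full_sequence: str
    payload_span: tuple[int, int]
    fwd_index: str
    rev_index: str
    enzyme: str

    @property
    def payload(self) -> str:
        a, b = self.payload_span
        return self.full_sequence[a:b]

    @property
    def overhead(self) -> int:
        return len(self.full_sequence) - len(self.payload)


def _flanks(enzyme: str, payload: str) -> tuple[str, str]:
    site = TYPE_IIS_SITES[enzyme]
    sp_len = TYPE_IIS_SPACER[enzyme]
    for spacers in (_DEFAULT_SPACERS, _FALLBACK_SPACERS):
        sp = spacers[sp_len]
        left = site + sp
        right = revcomp(site + sp)  # -> rc(sp) + rc(site) downstream of payload
        probe = left + payload + right
        # the flanks must contribute exactly one site each, correctly oriented
        if len(find_all(probe, site)) == 1 and len(find_all(probe, revcomp(site))) == 1:
            return left, right
    raise LayoutError(
        f"payload context recreates a {enzyme} site with either spacer choice"
    )


def layout_oligos(
    plan: FragmentPlan,
    enzyme: str = DEFAULT_OLIGO_ENZYME,
    index_pair: tuple[str, str] = ("", ""),
    budget: int = OLIGO_BUDGET,
) -> list[OligoRecord]:
    """One indexed, enzyme-flanked oligo per fragment of ``plan``."""
    fwd, rev = index_pair
    records = []
    for i, payload in enumerate(plan.fragments):
        left, right = _flanks(enzyme, payload)
        full = fwd + left + payload + right + revcomp(rev)
        if len(full) > budget:
            raise LayoutError(
                f"fragment {i} of {plan.target_id}: oligo length {len(full)} "
                f"exceeds the {budget}-nt budget"
            )
        a = len(fwd) + len(left)
        released = [f for f in digest(full, enzyme) if f.left_sticky and f.right_sticky]
        if len(released) != 1 or released[0].seq != payload:
            raise LayoutError(
                f"fragment {i} of {plan.target_id}: digest does not release "
                "the payload cleanly (index/flank junction recreates a site?)"
            )
        records.append(
            OligoRecord(
                target_id=plan.target_id,
                fragment_index=i,
                full_sequence=full,
                payload_span=(a, a + len(payload)),
                fwd_index=fwd,
                rev_index=rev,
                enzyme=enzyme,
            )
        )
    return records


# ----------------------------------------------------------- digestion

@dataclass
class DsFragment:
    """A double-stranded piece in extended-top-span form.

    When an end is sticky, the terminal 4 nt of ``seq`` on that side are the
    single-stranded 5' extension (top strand on the left end, bottom strand
    on the right end).  Two fragments ligate when the right end's 4-mer
    equals the left end's 4-mer of the next piece.
    """

    seq: str
    left_sticky: bool
    right_sticky: bool

    def rc(self) -> "DsFragment":
        return DsFragment(revcomp(self.seq), self.right_sticky, self.left_sticky)


def digest(sequence: str, enzyme: str) -> list[DsFragment]:
    """Cut a linear dsDNA at every recognition site of ``enzyme``.

    Cuts expose 4-nt 5' overhangs at recognition+spacer offset; molecule
    ends are blunt.  Fragments are returned left to right.
    """
    site = TYPE_IIS_SITES[enzyme]
    sp = TYPE_IIS_SPACER[enzyme]
    boundaries = []  # (right_fragment_start, left_fragment_end)
    for i in find_all(sequence, site):  # enzyme on top strand, cuts rightward
        start = i + len(site) + sp
        boundaries.append((start, start + 4))
    for i in find_all(sequence, revcomp(site)):  # bottom strand, cuts leftward
        end = i - sp
        boundaries.append((end - 4, end))
    boundaries = sorted(set(boundaries))
    frags = []
    prev_start, prev_sticky = 0, False
    for start, end in boundaries:
        if start < prev_start or end > len(sequence):
            continue  # site too close to an end to cut
        frags.append(DsFragment(sequence[prev_start:end], prev_sticky, True))
        prev_start, prev_sticky = start, True
    frags.append(DsFragment(sequence[prev_start:], prev_sticky, False))
    return frags


@dataclass
class AssemblyResult:
    products: list[str]  # strand-canonical: min(seq, revcomp(seq))
    complete: bool
    circular: bool = False
    diagnostics: dict = field(default_factory=dict)

    def matches(self, target: str) -> bool:
        """True when the unique product equals ``target`` on either strand."""
        return self.complete and self.products == [min(target, revcomp(target))]


def digest_ligate(sequences: list[str], enzyme: str) -> AssemblyResult:
    """Simulate one-pot digestion and exhaustive sticky-end ligation.

    Fragments with two sticky ends are the assembly parts; flank debris
    (one sticky end at most) is ignored.  Returns the unique full-length
    product when the overhang graph admits a single chain using every part;
    otherwise flags ambiguity (several products) or dead ends.
    """
    parts: list[DsFragment] = []
    for s in sequences:
        for f in digest(s.upper(), enzyme):
            if f.left_sticky and f.right_sticky:
                parts.append(f)
    diagnostics: dict = {"n_parts": len(parts)}
    if not parts:
        return AssemblyResult([], False, diagnostics={**diagnostics, "error": "no sticky fragments"})

    # canonical orientation: every part may enter a chain in either sense
    chains: list[str] = []

    def extend(chain_seq: str, used: frozenset[int]):
        if len(used) == len(parts):
            chains.append(chain_seq)
            return
        end = chain_seq[-4:]
        moves = []
        for idx, p in enumerate(parts):
            if idx in used:
                continue
            for orient in (p, p.rc()):
                if orient.seq[:4] == end:
                    moves.append((idx, orient))
        if not moves:
            diagnostics.setdefault("dead_ends", []).append(end)
            chains.append(chain_seq)  # maximal but incomplete
            return
        if len(moves) > 1:
            diagnostics.setdefault("ambiguous_overhangs", []).append(end)
        for idx, orient in moves:
            extend(chain_seq + orient.seq[4:], used | {idx})

    # starts: parts whose left overhang no other part's right end can feed
    right_ends = set()
    for p in parts:
        for orient in (p, p.rc()):
            right_ends.add(orient.seq[-4:])
    started = False
    for idx, p in enumerate(parts):
        for orient in (p, p.rc()):
            if orient.seq[:4] not in right_ends:
                started = True
                extend(orient.seq, frozenset({idx}))
    if not started:  # circular assembly: start anywhere, canonical part 0
        p = parts[0]
        extend(p.seq, frozenset({0}))
        full = [c for c in chains if c[-4:] == c[:4] and _uses_all(c, parts)]
        full = sorted({min(c, revcomp(c)) for c in full})
        return AssemblyResult(full, bool(full), circular=True, diagnostics=diagnostics)

    full = sorted({min(c, revcomp(c)) for c in chains if _uses_all(c, parts)})
    if not full:
        partial = sorted({min(c, revcomp(c)) for c in chains}, key=len, reverse=True)
        diagnostics["longest_partial_nt"] = len(partial[0]) if partial else 0
        return AssemblyResult(partial[:3], False, diagnostics=diagnostics)
    diagnostics["ambiguous"] = len(full) > 1
    return AssemblyResult(full, len(full) == 1, diagnostics=diagnostics)


def _uses_all(chain: str, parts: list[DsFragment]) -> bool:
    return len(chain) == sum(len(p.seq) - 4 for p in parts) + 4


# ----------------------------------------------------------- pool tables

@dataclass
class PoolTable:
    frame: pd.DataFrame
    pool_id: str = "pool-1"

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def oligo_fasta(self) -> str:
        return "".join(
            f">{r.target_id}_frag{r.fragment_index}\n{r.oligo_sequence}\n"
            for r in self.frame.itertuples()
        )


class IndexExhaustionError(ValueError):
    pass


def build_pool_table(
    plans: list[FragmentPlan],
    indexset: list[str],
    enzyme: str = DEFAULT_OLIGO_ENZYME,
    pool_id: str = "pool-1",
) -> PoolTable:
    """Assign one index-primer pair per target and lay out every oligo.

    All fragments of a target share the pair so they amplify together from
    the pool in one reaction.
    """
    if len(indexset) < 2 * len(plans):
        raise IndexExhaustionError(
            f"{len(plans)} targets need {2 * len(plans)} index primers, "
            f"only {len(indexset)} available"
        )
    rows = []
    for t, plan in enumerate(plans):
        pair = (indexset[2 * t], indexset[2 * t + 1])
        for rec in layout_oligos(plan, enzyme=enzyme, index_pair=pair):
            rows.append(
                {
                    "pool_id": pool_id,
                    "target_id": rec.target_id,
                    "fragment_index": rec.fragment_index,
                    "oligo_sequence": rec.full_sequence,
                    "oligo_length": len(rec.full_sequence),
                    "fwd_index": rec.fwd_index,
                    "rev_index": rec.rev_index,
                    "left_overhang": rec.payload[:4],
                    "right_overhang": rec.payload[-4:],
                    "payload_length": len(rec.payload),
                    "enzyme": rec.enzyme,
                }
            )
    columns = [
        "pool_id", "target_id", "fragment_index", "oligo_sequence",
        "oligo_length", "fwd_index", "rev_index", "left_overhang",
        "right_overhang", "payload_length", "enzyme",
    ]
    return PoolTable(pd.DataFrame(rows, columns=columns), pool_id=pool_id)
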