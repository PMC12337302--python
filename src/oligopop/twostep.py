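"""Hierarchical two-step assembly planning for multi-kilobase targets.

Large coding sequences are first prepared with terminal AATG/GCTT overhang
context and BsaI adapters next to the start/stop codons (standard level-0
coding-sequence syntax), then split into ~1 kb "step-one" blocks at
hingeset junctions.  Each block is flanked with BsmBI sites exposing its
junction overhangs, and is itself synthesized from BbsI-flanked indexed
oligos.  Step one assembles oligos into blocks (BbsI); step two assembles
the sequence-verified blocks into the final part (BsmBI), which remains
BsaI-compatible for downstream reuse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dna import TYPE_IIS_SITES, TYPE_IIS_SPACER, revcomp, validate_dna
from .fidelity import OverhangMatrix, overhang_list_fidelity
from .fragmenter import (
    DEFAULT_TERMINALS,
    FragmentPlan,
    FragmentationError,
    _search,
    fragment_sequence,
    prepare_cds,
)
from .hingesets import Hingeset
from .oligos import AssemblyResult, DEFAULT_OLIGO_ENZYME, digest_ligate, layout_oligos

STEP_TWO_ENZYME = "BsmBI"
DOWNSTREAM_ENZYME = "BsaI"


@dataclass
class BlockRecord:
    index: int
    span: tuple[int, int]  # payload span within the prepared sequence
    payload: str  # includes its terminal 4-nt junction overhangs
    flanked_sequence: str  # payload wrapped in step-two (BsmBI) flanks


@dataclass
class TwoStepPlan:
    target_id: str
    prepared_sequence: str
    bsa_adapted_sequence: str
    blocks: list[BlockRecord]
    per_block_fragment_plans: list[FragmentPlan]
    predicted_block_fidelity: float
    block_overhangs: list[str]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def _bsmbi_flanks(payload: str) -> str:
    site = TYPE_IIS_SITES[STEP_TWO_ENZYME]
    sp = "A" * TYPE_IIS_SPACER[STEP_TWO_ENZYME]
    flanked = site + sp + payload + revcomp(site + sp)
    return flanked


def add_bsa_adapters(prepared: str) -> str:
    """Wrap a prepared AATG...GCTT part in BsaI adapters for downstream reuse."""
    site = TYPE_IIS_SITES[DOWNSTREAM_ENZYME]
    sp = "A" * TYPE_IIS_SPACER[DOWNSTREAM_ENZYME]
    return site + sp + prepared + revcomp(site + sp)


def plan_two_step(
    cds: str,
    hingeset: Hingeset,
    m: OverhangMatrix,
    target_block_length: int = 1050,
    oligo_budget: int = 250,
    radius: int = 30,
    target_id: str = "target",
    already_prepared: bool = False,
) -> TwoStepPlan:
    """Split a large CDS into ~``target_block_length`` bp step-one blocks.

    Block count is the nearest integer to length / target_block_length
    (minimum 1); block junctions are chosen by the same hingeset-constrained
    search used at oligo scale, then each block payload is fragmented into
    BbsI-layout oligos.  Deterministic.
    """
    seq = cds if already_prepared else prepare_cds(cds)
    validate_dna(seq)
    L = len(seq)
    n = max(1, round(L / target_block_length))
    t5, t3 = DEFAULT_TERMINALS
    if seq[:4] != t5 or seq[-4:] != t3:
        raise FragmentationError("prepared sequence must carry AATG/GCTT termini")

    if n == 1:
        cuts, ovs = [], []
    else:
        block_budget = max(target_block_length, -(-L // n)) + 2 * radius + 4
        got = _search(seq, n, hingeset.members, (t5, t3), block_budget, radius, m)
        if got is None:
            raise FragmentationError(
                f"no admissible block junctions for {target_id} with radius {radius}"
            )
        cuts, ovs = got
    bounds = [0] + cuts
    payloads = [
        seq[a : (cuts[i] + 4 if i < len(cuts) else L)] for i, a in enumerate(bounds)
    ]
    block_overhangs = [t5] + ovs + [t3]
    blocks = []
    plans = []
    max_payload = oligo_budget - 52  # 18-mer indexes + BbsI flanks per side
    for i, payload in enumerate(payloads):
        start = bounds[i]
        blocks.append(
            BlockRecord(
                index=i,
                span=(start, start + len(payload)),
                payload=payload,
                flanked_sequence=_bsmbi_flanks(payload),
            )
        )
        plans.append(
            fragment_sequence(
                payload,
                hingeset,
                m,
                max_payload=max_payload,
                radius=radius,
                terminal_overhangs=(payload[:4], payload[-4:]),
                target_id=f"{target_id}_block{i}",
            )
        )
    return TwoStepPlan(
        target_id=target_id,
        prepared_sequence=seq,
        bsa_adapted_sequence=add_bsa_adapters(seq),
        blocks=blocks,
        per_block_fragment_plans=plans,
        predicted_block_fidelity=overhang_list_fidelity(block_overhangs, m),
        block_overhangs=block_overhangs,
    )


def simulate_two_step(
    plan: TwoStepPlan, index_pairs: list[tuple[str, str]] | None = None
) -> tuple[str, dict]:
    """Digital round trip of both assembly steps.

    Step one: each block's oligos (BbsI layout) are digested and ligated;
    the product must equal the block payload.  Step two: the BsmBI-flanked
    blocks are digested and ligated; the product must equal the prepared
    sequence.  Raises AssertionError-free diagnostics on failure.
    """
    diagnostics: dict = {"blocks": []}
    for i, fplan in enumerate(plan.per_block_fragment_plans):
        pair = index_pairs[i] if index_pairs else ("GTACAGCTTGACCTGAAG", "CAGTTGGACTCAAGTGTC")
        oligos = [
            r.full_sequence
            for r in layout_oligos(fplan, enzyme=DEFAULT_OLIGO_ENZYME, index_pair=pair)
        ]
        res = digest_ligate(oligos, DEFAULT_OLIGO_ENZYME)
        ok = res.complete and res.products == [
            min(plan.blocks[i].payload, revcomp(plan.blocks[i].payload))
        ]
        diagnostics["blocks"].append(
            {"block": i, "ok": ok, "n_oligos": len(oligos), **res.diagnostics}
        )
        if not ok:
            diagnostics["failed_step"] = 1
            diagnostics["failed_block"] = i
            return "", diagnostics
    res2 = digest_ligate([b.flanked_sequence for b in plan.blocks], STEP_TWO_ENZYME)
    want = min(plan.prepared_sequence, revcomp(plan.prepared_sequence))
    if not (res2.complete and res2.products == [want]):
        diagnostics["failed_step"] = 2
        diagnostics["step_two"] = res2.diagnostics
        products = res2.products or [""]
        return products[0], diagnostics
    diagnostics["ok"] = True
    return plan.prepared_sequence, diagnostics
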