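"""YAML run configuration.

A single schema covers every stage; unknown keys are rejected so typos
fail loudly, and each run writes its fully resolved configuration next to
its outputs for reproducibility.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .designer import DesignConstraints


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "oligopop_out"
    # sequence design
    codon_table: str = "arabidopsis"  # or a TSV path
    gc_min: float | None = None
    deintronize: bool = False
    unique_kmer_k: int = 12
    hairpin_stem_min: int = 20
    hairpin_window: int = 250
    gc_window: int = 60
    gc_boost: float = 4.0
    # fragmentation / layout
    hingeset_size: int = 30
    hingeset_path: str | None = None
    matrix_path: str | None = None
    oligo_budget: int = 250
    max_payload: int = 198
    radius: int = 30
    oligo_enzyme: str = "BbsI"
    # two-step routing
    two_step_threshold: int = 2000
    target_block_length: int = 1050
    # primers / barcodes
    n_primer_candidates: int = 500
    barcode_set_size: int = 96
    barcode_min_distance: int = 8
    # read simulation / validation
    substitution_rate: float = 0.02
    insertion_rate: float = 0.005
    deletion_rate: float = 0.005
    reads_per_clone: int = 20
    min_reads: int = 5
    coverage_floor: float = 0.98
    demux_max_distance: int = 3

    def constraints(self) -> DesignConstraints:
        return DesignConstraints(
            unique_kmer_k=self.unique_kmer_k,
            hairpin_stem_min=self.hairpin_stem_min,
            hairpin_window=self.hairpin_window,
            gc_min=self.gc_min,
            gc_window=self.gc_window,
            gc_boost=self.gc_boost,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
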