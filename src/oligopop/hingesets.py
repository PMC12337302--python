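"""Genetic-algorithm construction of high-fidelity overhang sets ("hingesets").

A hingeset is a fixed-size set of mutually compatible 4-nt overhangs with a
high predicted ligation fidelity under a given ligation-count matrix.  Every
set contains the terminal coding-sequence overhangs AATG and GCTT.  Sets are
used downstream to constrain junction placement when fragmenting targets.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dna import ALL_4MERS, revcomp
from .fidelity import (
    DEFAULT_FIXED_MEMBERS,
    OverhangMatrix,
    OverhangSet,
    admissible_overhangs,
    set_fidelity,
)


@dataclass
class GAConfig:
    population_size: int = 50
    generations_max: int = 500
    mutation_rate: float = 0.3
    elitism: int = 2
    tournament_size: int = 3
    stagnation_limit: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 < self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in (0, 1)")
        if self.elitism >= self.population_size:
            raise ValueError("elitism must be smaller than the population")


@dataclass
class Hingeset:
    set: OverhangSet
    size: int
    fidelity: float
    generations_run: int = 0
    seed: int = 0

    @property
    def members(self) -> list[str]:
        return self.set.members


def _admissible_pool(
    alphabet: tuple[str, ...], fixed: tuple[str, ...]
) -> list[str]:
    """Candidate members: non-palindromic, not rc of a fixed member."""
    fixed_rc = {revcomp(f) for f in fixed}
    return [
        k
        for k in admissible_overhangs(alphabet)
        if k not in fixed and k not in fixed_rc
    ]


def _random_set(size, fixed, pool, rng) -> tuple[str, ...]:
    members = list(fixed)
    blocked = set(fixed) | {revcomp(f) for f in fixed}
    order = rng.permutation(len(pool))
    for i in order:
        if len(members) == size:
            break
        k = pool[i]
        if k not in blocked:
            members.append(k)
            blocked.add(k)
            blocked.add(revcomp(k))
    if len(members) < size:
        raise ValueError(
            f"cannot build a set of size {size}: only {len(members)} "
            "admissible overhangs available"
        )
    return tuple(sorted(members))


def random_valid_set(
    size: int,
    seed: int,
    fixed_members: tuple[str, ...] = DEFAULT_FIXED_MEMBERS,
    alphabet: tuple[str, ...] = ALL_4MERS,
) -> OverhangSet:
    """A uniformly sampled valid overhang set (baseline for the GA)."""
    rng = np.random.default_rng(seed)
    pool = _admissible_pool(alphabet, fixed_members)
    return OverhangSet(
        list(_random_set(size, fixed_members, pool, rng)),
        fixed_members=fixed_members,
    )


def _fill_to_size(members, size, fixed, pool, rng) -> tuple[str, ...]:
    """Down-sample (never dropping fixed) or top up a candidate member pool."""
    deduped = []
    taken = set()
    for m in dict.fromkeys(members):
        if m in taken or revcomp(m) in taken:
            continue
        deduped.append(m)
        taken.add(m)
    members = deduped
    free = [m for m in members if m not in fixed]
    while len(fixed) + len(free) > size:
        free.pop(rng.integers(0, len(free)))
    members = list(fixed) + free
    blocked = set(members) | {revcomp(m) for m in members}
    order = rng.permutation(len(pool))
    for i in order:
        if len(members) == size:
            break
        k = pool[i]
        if k not in blocked:
            members.append(k)
            blocked.add(k)
            blocked.add(revcomp(k))
    return tuple(sorted(members))


def optimize_hingeset(
    size: int,
    m: OverhangMatrix,
    cfg: GAConfig | None = None,
    fixed_members: tuple[str, ...] = DEFAULT_FIXED_MEMBERS,
    alphabet: tuple[str, ...] = ALL_4MERS,
) -> Hingeset:
    """Search for a size-``size`` overhang set maximizing predicted fidelity.

    Genome = the member set.  Tournament selection, uniform set-crossover
    (child sampled from the union of its parents, fixed members forced),
    point mutation replacing one non-fixed member with a random admissible
    4-mer, elitism.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or GAConfig()
    if size < len(fixed_members):
        raise ValueError(f"size {size} smaller than the {len(fixed_members)} fixed members")
    pool = _admissible_pool(alphabet, fixed_members)
    # admissible capacity: one member per rc-pair plus the fixed members
    capacity = len(fixed_members) + len({frozenset((k, revcomp(k))) for k in pool})
    if size > capacity:
        raise ValueError(f"size {size} infeasible: at most {capacity} compatible overhangs")
    rng = np.random.default_rng(cfg.seed)
    fixed = tuple(fixed_members)

    def fitness(members: tuple[str, ...]) -> float:
        return set_fidelity(OverhangSet(list(members), fixed_members=fixed), m)

    if size == len(fixed):
        only = tuple(sorted(fixed))
        return Hingeset(
            OverhangSet(list(only), fixed_members=fixed),
            size,
            fitness(only),
            generations_run=0,
            seed=cfg.seed,
        )

    population = [_random_set(size, fixed, pool, rng) for _ in range(cfg.population_size)]
    cache: dict[tuple[str, ...], float] = {}

    def fit(g):
        if g not in cache:
            cache[g] = fitness(g)
        return cache[g]

    best_g, best_f = max(((g, fit(g)) for g in population), key=lambda x: x[1])
    stagnant = 0
    gen = 0
    for gen in range(1, cfg.generations_max + 1):
        ranked = sorted(population, key=fit, reverse=True)
        nxt = ranked[: cfg.elitism]
        while len(nxt) < cfg.population_size:
            parents = []
            for _ in range(2):
                contenders = [
                    population[i]
                    for i in rng.integers(0, len(population), cfg.tournament_size)
                ]
                parents.append(max(contenders, key=fit))
            union = list(dict.fromkeys(parents[0] + parents[1]))
            child = _fill_to_size(union, size, fixed, pool, rng)
            if rng.random() < cfg.mutation_rate:
                child = _mutate(child, fixed, pool, rng)
            nxt.append(child)
        population = nxt
        gen_best = max(population, key=fit)
        if fit(gen_best) > best_f + 1e-15:
            best_g, best_f = gen_best, fit(gen_best)
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= cfg.stagnation_limit:
                break
    return Hingeset(
        OverhangSet(list(best_g), fixed_members=fixed),
        size,
        best_f,
        generations_run=gen,
        seed=cfg.seed,
    )


def _mutate(members, fixed, pool, rng) -> tuple[str, ...]:
    members = list(members)
    free_idx = [i for i, m in enumerate(members) if m not in fixed]
    if not free_idx:
        return tuple(members)
    i = free_idx[rng.integers(0, len(free_idx))]
    blocked = set(members) | {revcomp(m) for m in members}
    choices = [k for k in pool if k not in blocked]
    if choices:
        members[i] = choices[rng.integers(0, len(choices))]
    return tuple(sorted(members))


def validate_hingeset(h: Hingeset, m: OverhangMatrix) -> list[str]:
    """Re-check all set invariants and the stored fidelity; [] means valid."""
    violations = list(h.set.violations())
    if h.size != len(h.set.members):
        violations.append(f"size field {h.size} != member count {len(h.set.members)}")
    if not violations:
        actual = set_fidelity(h.set, m)
        if abs(actual - h.fidelity) > 1e-9:
            violations.append(
                f"fidelity mismatch: stored {h.fidelity:.6f}, recomputed {actual:.6f}"
            )
    return violations


def hingesets_to_frame(sets: list[Hingeset]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "size": [h.size for h in sets],
            "fidelity": [h.fidelity for h in sets],
            "members": [",".join(h.members) for h in sets],
            "seed": [h.seed for h in sets],
        }
    )


def load_hingeset_library(path=None) -> list[Hingeset]:
    """Load a hingeset TSV (size, fidelity, members, seed).

    Without ``path``, loads the library bundled with the package (optimized
    against :func:`oligopop.synth.default_ligation_matrix`).
    """
    if path is None:
        path = importlib.resources.files("oligopop").joinpath("data/hingesets.tsv")
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        members = row["members"].split(",")
        out.append(
            Hingeset(
                OverhangSet(members),
                size=int(row["size"]),
                fidelity=float(row["fidelity"]),
                seed=int(row["seed"]),
            )
        )
    return out


def default_hingeset(size: int = 30) -> Hingeset:
    """The bundled hingeset of the requested size."""
    for h in load_hingeset_library():
        if h.size == size:
            return h
    raise KeyError(f"no bundled hingeset of size {size}")
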