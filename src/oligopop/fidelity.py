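"""Ligation-fidelity model for 4-nt Golden Gate overhangs.

The substrate is an all-by-all 256x256 matrix of observed ligation counts
between 4-mer overhangs (rows and columns are the overhang read 5'->3' on
the strand carrying the extension).  A junction contributes both its top
overhang ``o`` and the bottom-strand ``rc(o)`` to the ligation pool, so the
predicted fidelity of a junction within a pool of overhangs P is

    f(o) = (counts[o, rc(o)] + counts[rc(o), o])
           / sum_{p in P} (counts[o, p] + counts[rc(o), p])

with P = members U rc(members), and the fidelity of an overhang set is the
product of f over its members.  Adding overhangs to a set can only add
mismatch mass to the denominators, so the set fidelity is monotonically
non-increasing in set size.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dna import ALL_4MERS, is_palindrome, revcomp

IDX: dict[str, int] = {k: i for i, k in enumerate(ALL_4MERS)}

#: canonical terminal overhangs for coding-sequence parts (MoClo/GoldenBraid
#: CDS syntax: AATG embeds the start codon, GCTT follows the stop).
DEFAULT_FIXED_MEMBERS: tuple[str, str] = ("AATG", "GCTT")

_RC_PERM = np.array([IDX[revcomp(k)] for k in ALL_4MERS])


class MatrixFormatError(ValueError):
    """Raised when a ligation-count file is malformed."""


@dataclass
class OverhangMatrix:
    """256x256 non-negative ligation counts, lexicographically indexed."""

    counts: np.ndarray
    symmetrized: bool = False
    source_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (256, 256):
            raise MatrixFormatError(
                f"expected a 256x256 matrix, got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise MatrixFormatError(
                f"negative count at [{ALL_4MERS[i]}][{ALL_4MERS[j]}]"
            )

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.counts[IDX[a], IDX[b]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=ALL_4MERS, columns=ALL_4MERS)

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path)


@dataclass
class OverhangSet:
    """A set of mutually compatible 4-nt overhangs.

    Members must be unique, non-palindromic, and pairwise non-reverse-
    complementary; ``fixed_members`` (default AATG/GCTT) must be included.
    """

    members: list[str]
    fixed_members: tuple[str, ...] = DEFAULT_FIXED_MEMBERS

    def __post_init__(self) -> None:
        self.members = [m.upper() for m in self.members]
        self.fixed_members = tuple(m.upper() for m in self.fixed_members)
        for v in self.violations():
            raise ValueError(v)

    def violations(self) -> list[str]:
        out = []
        seen = set()
        for m in self.members:
            if len(m) != 4 or m not in IDX:
                out.append(f"invalid overhang {m!r}")
                continue
            if m in seen:
                out.append(f"duplicate member {m}")
            seen.add(m)
            if is_palindrome(m):
                out.append(f"palindromic member {m}")
        for m in self.members:
            if revcomp(m) in seen and revcomp(m) != m and IDX.get(m, 0) < IDX.get(revcomp(m), 0):
                out.append(f"members {m} and {revcomp(m)} are reverse complements")
        missing = set(self.fixed_members) - seen
        if missing:
            out.append(f"missing fixed members {sorted(missing)}")
        return out

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return item in self.members


def admissible_overhangs(alphabet: tuple[str, ...] = ALL_4MERS) -> list[str]:
    """Non-palindromic 4-mers from ``alphabet`` (120 rc-pairs over all 256)."""
    return [k for k in alphabet if not is_palindrome(k)]


def load_ligation_matrix(path: str | os.PathLike) -> OverhangMatrix:
    """Load a labeled 256x256 ligation-count CSV/TSV.

    The first column and the header row are 4-mer labels; comma or tab
    delimited.  Rows and columns are reordered lexicographically.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str).str.upper()
    df.columns = df.columns.astype(str).str.upper()
    for axis, labels in (("row", df.index), ("column", df.columns)):
        if labels.duplicated().any():
            dup = labels[labels.duplicated()][0]
            raise MatrixFormatError(f"duplicate {axis} label {dup}")
        missing = set(ALL_4MERS) - set(labels)
        if missing:
            raise MatrixFormatError(
                f"missing overhang {sorted(missing)[0]} ({axis}s)"
            )
        extra = set(labels) - set(ALL_4MERS)
        if extra:
            raise MatrixFormatError(f"unexpected {axis} label {sorted(extra)[0]}")
    df = df.loc[list(ALL_4MERS), list(ALL_4MERS)]
    values = df.to_numpy()
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise MatrixFormatError(f"non-numeric count in matrix: {exc}") from exc
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise MatrixFormatError(
            f"non-numeric count at [{ALL_4MERS[i]}][{ALL_4MERS[j]}]"
        )
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise MatrixFormatError(
            f"negative count at [{ALL_4MERS[i]}][{ALL_4MERS[j]}]"
        )
    return OverhangMatrix(values, symmetrized=False, source_label=str(path))


def symmetrize_matrix(m: OverhangMatrix) -> OverhangMatrix:
    """Average the matrix with its reverse-complement transpose.

    counts'[a][b] = (counts[a][b] + counts[rc(b)][rc(a)]) / 2.  The raw data
    is strand-asymmetric; scoring uses the symmetrized form.  Idempotent.
    """
    c = m.counts
    sym = 0.5 * (c + c[np.ix_(_RC_PERM, _RC_PERM)].T)
    return OverhangMatrix(sym, symmetrized=True, source_label=m.source_label)


def junction_fidelity(o: str, s: OverhangSet, m: OverhangMatrix) -> float:
    """Predicted fraction of correct ligations at junction ``o`` within set ``s``."""
    o = o.upper()
    if o not in s.members:
        raise ValueError(f"overhang {o} is not a member of the set")
    pool = sorted({p for x in s.members for p in (x, revcomp(x))})
    pool_idx = [IDX[p] for p in pool]
    i, ri = IDX[o], IDX[revcomp(o)]
    correct = m.counts[i, ri] + m.counts[ri, i]
    total = m.counts[i, pool_idx].sum() + m.counts[ri, pool_idx].sum()
    if total == 0:
        raise ValueError(f"overhang {o} has no ligation signal")
    return float(correct / total)


def set_fidelity(s: OverhangSet, m: OverhangMatrix) -> float:
    """Product of junction fidelities over all members; empty set -> 1.0."""
    f = 1.0
    for o in s.members:
        f *= junction_fidelity(o, s, m)
    return f


def overhang_list_fidelity(
    overhangs: list[str], m: OverhangMatrix
) -> float:
    """set_fidelity for a plain list of overhangs (no fixed-member check)."""
    s = OverhangSet(list(dict.fromkeys(overhangs)), fixed_members=())
    return set_fidelity(s, m)
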