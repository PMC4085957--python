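"""Alignment and sequence containers.

Thin, immutable-ish containers holding rows as plain strings; the
likelihood engine converts them to integer state matrices on demand.
Codon sites are 1-based, as are nucleotide positions within a codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

DNA_CHARS = set("ACGTUacgtuNRYSWKMBDHVn-.?")
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def detect_alphabet(seq: str) -> str:
    """Guess 'dna' or 'protein' from the characters of a sequence."""
    stripped = set(seq) - set("-.?*")
    if stripped and stripped <= set("ACGTUNacgtun"):
        return "dna"
    if stripped <= DNA_CHARS and sum(c in "ACGTUacgtu" for c in seq) >= 0.8 * max(
        len(seq), 1
    ):
        return "dna"
    return "protein"


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence with an explicit alphabet."""

    id: str
    seq: str
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @classmethod
    def auto(cls, id: str, seq: str) -> "SequenceRecord":
        return cls(id, seq, detect_alphabet(seq))


class _BaseAlignment:
    """Rectangular alignment over named rows."""

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        ids = list(ids)
        rows = [r.upper().replace("U", "T").replace(".", "-").replace("?", "-") for r in rows]
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in length")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids")
        if rows and len({len(r) for r in rows}) != 1:
            raise ValueError("alignment rows must have equal length")
        self.ids = ids
        self.rows = rows

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    def reorder(self, ids: Sequence[str]):
        idx = {t: i for i, t in enumerate(self.ids)}
        return type(self)([t for t in ids], [self.rows[idx[t]] for t in ids])

    def __eq__(self, other) -> bool:
        return (
            type(self) is type(other)
            and self.ids == other.ids
            and self.rows == other.rows
        )


class NucleotideAlignment(_BaseAlignment):
    """Aligned nucleotide rows; gap '-' and ambiguity codes allowed."""

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def state_matrix(self) -> np.ndarray:
        """(n_taxa, n_sites) int8 matrix; A,C,G,T -> 0..3, everything else -1."""
        out = np.full((self.n_taxa, self.n_sites), -1, dtype=np.int16)
        for i, row in enumerate(self.rows):
            out[i] = [_NT_INDEX.get(c, -1) for c in row]
        return out

    def add_row(self, rid: str, row: str) -> "NucleotideAlignment":
        if len(row) != self.n_sites:
            raise ValueError("new row length does not match alignment")
        return NucleotideAlignment(self.ids + [rid], self.rows + [row])


class CodonAlignment(_BaseAlignment):
    """Aligned in-frame coding rows; every cell is a codon or '---'."""

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        super().__init__(ids, rows)
        if self.rows and len(self.rows[0]) % 3:
            raise ValueError("codon alignment length must be a multiple of 3")
        if self.n_sites < 1:
            raise ValueError("codon alignment needs at least one site")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def codon(self, rid: str, site: int) -> str:
        """Codon of taxon ``rid`` at 1-based codon site ``site``."""
        return self.row(rid)[3 * (site - 1) : 3 * site]

    def to_nucleotide(self) -> NucleotideAlignment:
        return NucleotideAlignment(list(self.ids), list(self.rows))

    def state_matrix(self, code) -> np.ndarray:
        """(n_taxa, n_sites) int16 matrix of sense-codon indices, -1 = missing.

        Gaps, stop codons and codons containing ambiguity codes are all
        treated as missing data in likelihood computation.
        """
        out = np.full((self.n_taxa, self.n_sites), -1, dtype=np.int16)
        idx = code.codon_index
        for i, row in enumerate(self.rows):
            out[i] = [
                idx.get(row[3 * k : 3 * k + 3], -1) for k in range(self.n_sites)
            ]
        return out
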