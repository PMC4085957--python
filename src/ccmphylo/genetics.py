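"""Genetic-code utilities and codon-aware sequence operations.

The unit of analysis throughout the package is the in-frame codon: coding
sequences are translated, aligned at the protein level, and the protein
alignment is then back-translated into a codon alignment so that every
alignment column corresponds to one amino-acid position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

from .alignment import CodonAlignment, NucleotideAlignment, SequenceRecord

NUCLEOTIDES = "TCAG"
GAP_CODON = "---"
#: IUPAC nucleotide ambiguity codes (anything outside ACGT- is ambiguous).
UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True, eq=False)  # identity hash: usable as a cache key
class GeneticCode:
    """A codon -> amino-acid table over the DNA alphabet.

    ``table`` maps every one of the 64 codons to an amino-acid symbol or
    ``'*'`` for stop.  ``sense_codons`` fixes the state order used by all
    codon rate matrices and likelihood computations.
    """

    name: str
    table: Mapping[str, str]
    sense_codons: tuple[str, ...]
    stop_codons: tuple[str, ...]
    codon_index: Mapping[str, int] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError("genetic code must map all 64 codons")
        if self.codon_index is None:
            object.__setattr__(
                self, "codon_index", {c: i for i, c in enumerate(self.sense_codons)}
            )

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def is_stop(self, codon: str) -> bool:
        return self.table.get(codon) == "*"

    def translate_codon(self, codon: str) -> str:
        """Translate one codon; ambiguity codes give 'X', stops give '*'."""
        codon = codon.upper().replace("U", "T")
        if not UNAMBIGUOUS.issuperset(codon):
            return "-" if codon == GAP_CODON else "X"
        return self.table[codon]


@lru_cache(maxsize=None)
def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (61 sense codons, 3 stops)."""
    bio = CodonTable.unambiguous_dna_by_id[1]
    table = {}
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                codon = a + b + c
                table[codon] = "*" if codon in bio.stop_codons else bio.forward_table[codon]
    sense = tuple(c for c in sorted(table) if table[c] != "*")
    stops = tuple(c for c in sorted(table) if table[c] == "*")
    assert len(sense) == 61 and len(stops) == 3
    return GeneticCode("standard", table, sense, stops)


def iter_codons(cds: str) -> Iterable[str]:
    for i in range(0, len(cds), 3):
        yield cds[i : i + 3]


def translate_cds(
    cds: str,
    code: GeneticCode | None = None,
    mask_internal_stops: bool = True,
) -> str:
    """Translate an in-frame coding sequence into protein.

    Internal stop codons become ``'X'`` when ``mask_internal_stops`` is true
    (pseudogenes with premature stops are retained in gene-family screens),
    otherwise they raise.  A single terminal stop codon is dropped.
    Ambiguity codons translate to ``'X'``.
    """
    if not cds:
        raise ValueError("empty coding sequence")
    if len(cds) % 3:
        raise ValueError(f"sequence length {len(cds)} not divisible by 3")
    code = code or standard_code()
    cds = cds.upper().replace("U", "T")
    aas = [code.translate_codon(c) for c in iter_codons(cds)]
    if aas and aas[-1] == "*":
        aas.pop()
    out = []
    for i, aa in enumerate(aas):
        if aa == "*":
            if not mask_internal_stops:
                raise ValueError(f"internal stop at codon {i + 1}")
            aa = "X"
        out.append(aa)
    return "".join(out)


def back_translate_alignment(
    protein_aln: Sequence[SequenceRecord] | Mapping[str, str],
    cds_map: Mapping[str, str],
    code: GeneticCode | None = None,
) -> CodonAlignment:
    """Replace each aligned protein row by its coding sequence, codon-wise.

    Every protein gap becomes a three-column codon gap; the concatenated
    non-gap codons reproduce the input CDS exactly (minus a terminal stop).
    The CDS must translate to the ungapped protein row; the first
    disagreeing residue is reported otherwise.
    """
    code = code or standard_code()
    if isinstance(protein_aln, Mapping):
        rows = [(k, v) for k, v in protein_aln.items()]
    else:
        rows = [(r.id, r.seq) for r in protein_aln]
    ids, codon_rows = [], []
    for rid, prot in rows:
        if rid not in cds_map:
            raise KeyError(f"no coding sequence for alignment row {rid!r}")
        cds = cds_map[rid].upper().replace("U", "T")
        translated = translate_cds(cds, code)
        ungapped = prot.replace("-", "")
        if translated != ungapped:
            for i, (a, b) in enumerate(zip(translated, ungapped)):
                if a != b:
                    raise ValueError(
                        f"translation mismatch for {rid!r} at residue {i + 1}: "
                        f"CDS gives {a!r}, alignment has {b!r}"
                    )
            raise ValueError(
                f"translation length mismatch for {rid!r}: "
                f"{len(translated)} vs {len(ungapped)} residues"
            )
        # drop a trailing stop codon so codon count matches residue count
        codons = list(iter_codons(cds))[: len(translated)] if translated else []
        it = iter(codons)
        codon_rows.append(
            "".join(GAP_CODON if aa == "-" else next(it) for aa in prot)
        )
        ids.append(rid)
    return CodonAlignment(ids, codon_rows)


def extract_codon_positions(
    aln: CodonAlignment, positions: Iterable[int]
) -> NucleotideAlignment:
    """Pull out nucleotide columns at given within-codon positions (1..3).

    Output columns are ordered by codon site then position; ``{3}`` gives
    the third-position alignment used to infer topologies free of
    convergent protein-level signal.
    """
    pos = sorted(set(positions))
    if not pos:
        raise ValueError("empty position set")
    if not all(p in (1, 2, 3) for p in pos):
        raise ValueError(f"positions must be within a codon (1..3), got {pos}")
    offs = [p - 1 for p in pos]
    rows = []
    for row in aln.rows:
        rows.append(
            "".join(row[i + o] for i in range(0, len(row), 3) for o in offs)
        )
    return NucleotideAlignment(list(aln.ids), rows)


def _contains(longer: str, shorter: str) -> bool:
    return shorter in longer


def dedupe_keep_longest(seqs: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Collapse groups of identical/contained sequences, keeping the longest.

    Two sequences are duplicates when one is a substring of the other
    (identical over their full overlap); within each group only the longest
    survives, ties broken by lexicographically smallest id.  Input order of
    survivors is preserved.
    """
    n = len(seqs)
    alive = [True] * n
    order = sorted(range(n), key=lambda i: (-len(seqs[i].seq), seqs[i].id))
    for a_pos, i in enumerate(order):
        if not alive[i]:
            continue
        for j in order[a_pos + 1 :]:
            if alive[j] and _contains(seqs[i].seq, seqs[j].seq):
                alive[j] = False
    return [s for s, keep in zip(seqs, alive) if keep]
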