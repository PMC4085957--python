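"""Diagnostic-residue screening on a reference protein numbering.

PEPC proteins co-opted into C4 or CAM pathways recurrently substitute a
small set of residues; the best characterised is the alanine-to-serine
change at the position homologous to position 780 of the maize PEPC
(GenBank CAA33317 numbering).  Serine at that position marks
C4/CAM-associated enzyme forms, the ancestral alanine marks forms not
involved in a carbon-concentrating mechanism.

Queries are mapped onto the reference numbering by global protein
alignment; positions are 1-based on the ungapped reference.  Residues at
the other recurrently substituted positions (e.g. 531, 572, 665, 761)
are reported descriptively, without classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_POSITIONS = (780,)
CLASS_CCM = "C4/CAM-associated"
CLASS_NON_CCM = "non-CCM-like"
CLASS_OTHER = "other"

_DIAGNOSTIC = {780: {"S": CLASS_CCM, "A": CLASS_NON_CCM}}


@dataclass(frozen=True)
class MappedPosition:
    """One reference position seen through the pairwise alignment."""

    reference_position: int
    reference_residue: str
    query_residue: str  # '-' for a gap
    query_position: int | None  # 1-based on the ungapped query
    classification: str | None = None


@dataclass
class ResidueReport:
    query_id: str
    positions: tuple[MappedPosition, ...]
    identity: float
    low_identity: bool

    def __getitem__(self, ref_pos: int) -> MappedPosition:
        for p in self.positions:
            if p.reference_position == ref_pos:
                return p
        raise KeyError(ref_pos)


def _global_aligner():
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def map_reference_positions(
    query: str, reference: str
) -> tuple[list[tuple[str, int | None]], float]:
    """Align query to reference and map every reference position.

    Returns (mapping, identity): ``mapping[i]`` is (query residue or '-',
    1-based query index or None) for reference position i+1; identity is
    the fraction of aligned reference positions with matching residues.
    """
    if not query or not reference:
        raise ValueError("query and reference must be nonempty")
    query, reference = query.upper(), reference.upper()
    aligner = _global_aligner()
    aln = aligner.align(query, reference)[0]
    mapping: list[tuple[str, int | None]] = [("-", None)] * len(reference)
    matches = 0
    for (qs, qe), (rs, re_) in zip(aln.aligned[0], aln.aligned[1]):
        for off in range(qe - qs):
            q_i, r_i = qs + off, rs + off
            mapping[r_i] = (query[q_i], q_i + 1)
            matches += query[q_i] == reference[r_i]
    identity = matches / len(reference)
    return mapping, identity


def diagnose_residues(
    query: str,
    reference: str,
    positions: Sequence[int] = DEFAULT_POSITIONS,
    query_id: str = "query",
    min_identity: float = 0.30,
) -> ResidueReport:
    """Report the query residue at each reference position.

    Position 780 is classified (Ser -> C4/CAM-associated, Ala ->
    non-CCM-like, anything else or a gap -> other); other positions are
    reported without classification.  A report with alignment identity
    below ``min_identity`` is flagged as unreliable numbering.
    """
    for p in positions:
        if not 1 <= p <= len(reference):
            raise ValueError(
                f"position {p} outside reference (length {len(reference)})"
            )
    mapping, identity = map_reference_positions(query, reference)
    out = []
    for p in positions:
        q_res, q_pos = mapping[p - 1]
        rules = _DIAGNOSTIC.get(p)
        cls = rules.get(q_res, CLASS_OTHER) if rules else None
        out.append(
            MappedPosition(p, reference[p - 1], q_res, q_pos, cls)
        )
    return ResidueReport(query_id, tuple(out), identity, identity < min_identity)
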