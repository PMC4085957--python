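"""Reading and writing FASTA and relaxed-PHYLIP files (via biopython)."""

from __future__ import annotations

import io
from typing import Sequence

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .alignment import (
    CodonAlignment,
    NucleotideAlignment,
    SequenceRecord,
    detect_alphabet,
)


def read_fasta(path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, auto-detecting the alphabet
    unless one is given."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        records.append(
            SequenceRecord(rec.id, seq, alphabet or detect_alphabet(seq))
        )
    return records


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _to_bio(ids, rows) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        [BioSeqRecord(Seq(r), id=i, description="") for i, r in zip(ids, rows)]
    )


def read_alignment(path, fmt: str = "fasta", codon: bool = False):
    """Read an alignment ('fasta' or 'phylip-relaxed'); returns a
    CodonAlignment when ``codon`` is set, else a NucleotideAlignment."""
    aln = AlignIO.read(str(path), fmt)
    ids = [r.id for r in aln]
    rows = [str(r.seq) for r in aln]
    cls = CodonAlignment if codon else NucleotideAlignment
    return cls(ids, rows)


def write_alignment(aln, path, fmt: str = "fasta") -> None:
    """Write a Codon/NucleotideAlignment as FASTA or relaxed PHYLIP."""
    bio = _to_bio(aln.ids, aln.rows)
    if fmt == "fasta":
        write_fasta(
            [SequenceRecord(i, r) for i, r in zip(aln.ids, aln.rows)], path
        )
    else:
        with open(path, "w") as fh:
            AlignIO.write(bio, fh, fmt)


def alignment_from_string(text: str, fmt: str = "fasta", codon: bool = False):
    aln = AlignIO.read(io.StringIO(text), fmt)
    cls = CodonAlignment if codon else NucleotideAlignment
    return cls([r.id for r in aln], [str(r.seq) for r in aln])
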