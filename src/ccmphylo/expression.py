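"""Transcript abundance per gene lineage, in reads per million (rpm).

rpm normalises a contig's read count by the sample's total alignable
reads; summing the rpm of all contigs assigned to a gene lineage gives
the lineage's transcript abundance.  The per-sample grand total is
conserved exactly: lineages + the unassigned bucket always add up to the
summed contig rpm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .placement import ContigAssignment

UNASSIGNED = "unassigned"


def compute_rpm(counts: Mapping[str, float], total_alignable: float) -> dict[str, float]:
    """reads-per-million: count / total_alignable * 1e6 per contig."""
    if total_alignable <= 0:
        raise ValueError("total alignable reads must be positive")
    s = sum(counts.values())
    if s > total_alignable:
        raise ValueError("counts exceed the total of alignable reads")
    return {k: v / total_alignable * 1e6 for k, v in counts.items()}


@dataclass
class ExpressionTable:
    """Gene-lineage x sample rpm matrix with per-sample metadata."""

    table: pd.DataFrame  # rows: lineages (+ 'unassigned'), cols: samples
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.table.values < 0).any():
            raise ValueError("rpm values must be nonnegative")
        if (self.table.sum(axis=0) > 1e6 + 1e-6).any():
            raise ValueError("per-sample rpm totals cannot exceed 1e6")

    @property
    def lineages(self) -> list[str]:
        return [r for r in self.table.index if r != UNASSIGNED]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g")


def aggregate_lineage_abundance(
    assignments: Iterable[ContigAssignment],
    samples: pd.DataFrame | None = None,
    lineages: Iterable[str] | None = None,
) -> ExpressionTable:
    """Sum contig rpm per (lineage, sample); unassigned rpm is kept in its
    own row so each sample's total is conserved exactly."""
    rows = [
        {"lineage": a.lineage, "sample": a.sample, "rpm": a.rpm} for a in assignments
    ]
    if not rows:
        raise ValueError("no assignments to aggregate")
    df = pd.DataFrame(rows)
    if samples is not None:
        unknown = set(df["sample"]) - set(samples.index)
        if unknown:
            raise KeyError(f"assignments reference unknown samples: {sorted(unknown)}")
    table = df.pivot_table(
        index="lineage", columns="sample", values="rpm", aggfunc="sum", fill_value=0.0
    )
    if lineages is not None:
        known = set(lineages) | {UNASSIGNED}
        unknown = set(table.index) - known
        if unknown:
            raise KeyError(f"unknown lineage labels: {sorted(unknown)}")
        order = list(lineages)  # requested lineages appear even when empty
    else:
        order = sorted(l for l in table.index if l != UNASSIGNED)
    if UNASSIGNED in table.index:
        order = order + [UNASSIGNED]
    table = table.reindex(index=order, fill_value=0.0)
    if samples is not None:
        table = table.reindex(columns=list(samples.index), fill_value=0.0)
    table.columns.name = "sample"
    return ExpressionTable(table, samples)
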