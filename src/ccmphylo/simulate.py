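"""Forward simulation of every input the analysis pipeline consumes.

Generators for: random labelled trees; codon alignments evolved under
site/branch-site omega mixtures (with per-site true class labels, so
parameter-recovery tests close the simulate->fit loop); nucleotide
reference panels with nested, monophyletic gene-lineage clades; and
diel/drought expression experiments producing contig FASTA plus read
counts whose expected rpm equals a planted design matrix.

Every generator is a pure function of its arguments and a seed; the same
seed reproduces identical output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import CodonAlignment, NucleotideAlignment, SequenceRecord
from .genetics import GeneticCode, standard_code
from .likelihood import SiteClassMixture, codon_mixture_spectral
from .ratematrix import (
    CodonModelParams,
    GTRGammaParams,
    SpectralMatrix,
    discrete_gamma_rates,
    gtr_rate_matrix,
)
from .tree import LabeledTree

_NT = np.array(list("ACGT"))

#: Planted diel/drought expression design (rpm): gene-lineage rows by
#: (individual, time, watering) samples.  One lineage is day-high under
#: frequent watering (the C4-like profile) and one is night-induced under
#: occasional watering (the CAM-like profile); the remaining lineages sit
#: at low, roughly constant abundance.
DIEL_SAMPLES = pd.DataFrame(
    {
        "sample": ["d1", "d2", "n1", "n2", "d3", "d4", "n3", "n4"],
        "individual": [1, 2, 1, 2, 3, 4, 3, 4],
        "time": ["day", "day", "night", "night", "day", "day", "night", "night"],
        "watering": ["frequent"] * 4 + ["occasional"] * 4,
    }
).set_index("sample")

DEFAULT_DIEL_DESIGN = pd.DataFrame(
    [
        [13, 14, 6, 1, 5, 30, 7, 17],
        [44, 41, 40, 29, 14, 10, 5, 14],
        [131, 139, 157, 192, 167, 196, 185, 173],
        [0, 1, 0, 7, 6, 18, 0, 0],
        [3, 0, 820, 1180, 277, 338, 7602, 6823],
        [9916, 4697, 6710, 6052, 7339, 1868, 1421, 869],
    ],
    index=["ppc-2", "ppc-1E2", "ppc-1E1a", "ppc-1E1b", "ppc-1E1c", "ppc-1E1a'"],
    columns=DIEL_SAMPLES.index,
    dtype=float,
)


@dataclass
class SimulationConfig:
    """Bundled configuration for the CLI `simulate` subcommands."""

    seed: int = 0
    n_taxa: int = 8
    n_sites: int = 300
    length_range: tuple[float, float] = (0.02, 0.3)
    foreground: tuple[str, ...] = ()
    design: pd.DataFrame | None = None


def _categorical_rows(P: np.ndarray, parents: np.ndarray, rng) -> np.ndarray:
    """Draw child states from rows of a transition matrix, vectorised."""
    cum = np.cumsum(P[parents], axis=1)
    u = rng.random(len(parents))
    return (u[:, None] < cum).argmax(axis=1)


def simulate_tree(
    n: int,
    seed: int = 0,
    length_range: tuple[float, float] = (0.02, 0.3),
    names: Sequence[str] | None = None,
) -> LabeledTree:
    """A random rooted binary tree with uniform branch lengths.

    Topology grows by splitting a uniformly chosen pendant edge, which
    yields the uniform ("Yule-ish") shapes used throughout the test
    simulations.  Branch lengths are iid Uniform(length_range).
    """
    if n < 2:
        raise ValueError("need at least 2 taxa")
    lo, hi = length_range
    if not 0 < lo <= hi:
        raise ValueError("branch-length range must be positive")
    rng = np.random.default_rng(seed)
    names = list(names) if names is not None else [f"t{i+1}" for i in range(n)]
    if len(names) != n:
        raise ValueError("need one name per taxon")
    # parent pointers; node 0 is the root; grow by splitting pendant edges
    parent = [-1, 0, 0]
    leaves = [1, 2]
    for _ in range(2, n):
        target = leaves[rng.integers(len(leaves))]
        new_int = len(parent)
        parent.append(parent[target])  # new internal under target's parent
        parent[target] = new_int
        new_leaf = len(parent)
        parent.append(new_int)
        leaves.append(new_leaf)
    lengths = rng.uniform(lo, hi, size=len(parent))
    lengths[0] = 0.0
    labels: list[str | None] = [None] * len(parent)
    for name, node in zip(names, sorted(leaves)):
        labels[node] = name
    return LabeledTree(parent, lengths, labels)


def simulate_codon_alignment(
    tree: LabeledTree,
    mixture: SiteClassMixture,
    params: CodonModelParams,
    n_sites: int,
    seed: int = 0,
    code: GeneticCode | None = None,
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve codon sites down the tree under a site-class mixture.

    Root codons are drawn from pi; each site keeps its class along the
    whole tree, and on foreground-flagged branches the class's foreground
    omega applies.  Returns the alignment and the true per-site class
    indices.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    code = code or standard_code()
    rng = np.random.default_rng(seed)
    classes = mixture.classes
    site_class = rng.choice(len(classes), size=n_sites, p=mixture.proportions)
    # one spectral generator per distinct omega, on the mixture's shared scale
    spectral = codon_mixture_spectral(mixture, params, code)
    states = {tree.root: rng.choice(61, size=n_sites, p=params.pi)}
    for node in reversed(tree.postorder()):
        for child in tree.children[node]:
            t = tree.lengths[child]
            fg = bool(tree.foreground[child])
            child_states = np.empty(n_sites, dtype=np.int64)
            for ci, (_, wb, wf) in enumerate(classes):
                mask = site_class == ci
                if not mask.any():
                    continue
                P = spectral[wf if fg else wb].probability(t)
                child_states[mask] = _categorical_rows(P, states[node][mask], rng)
            states[child] = child_states
    codons = np.array(code.sense_codons)
    ids, rows = [], []
    for node in tree.leaf_indices:
        ids.append(tree.labels[node])
        rows.append("".join(codons[states[node]]))
    return CodonAlignment(ids, rows), site_class


def simulate_nucleotide_alignment(
    tree: LabeledTree,
    params: GTRGammaParams,
    n_sites: int,
    seed: int = 0,
) -> NucleotideAlignment:
    """Evolve nucleotide sites under GTR+Gamma (per-site random rate
    category)."""
    rng = np.random.default_rng(seed)
    sm = SpectralMatrix(gtr_rate_matrix(params), params.base_freqs)
    rates = discrete_gamma_rates(params.alpha, params.ncat)
    site_rate = rates[rng.integers(len(rates), size=n_sites)]
    states = {tree.root: rng.choice(4, size=n_sites, p=params.base_freqs)}
    for node in reversed(tree.postorder()):
        for child in tree.children[node]:
            t = tree.lengths[child]
            child_states = np.empty(n_sites, dtype=np.int64)
            for r in np.unique(site_rate):
                mask = site_rate == r
                P = sm.probability(t * r)
                child_states[mask] = _categorical_rows(P, states[node][mask], rng)
            states[child] = child_states
    ids = [tree.labels[i] for i in tree.leaf_indices]
    rows = ["".join(_NT[states[i]]) for i in tree.leaf_indices]
    return NucleotideAlignment(ids, rows)


def simulate_reference_panel(
    n_lineages: int = 5,
    taxa_per_lineage: int = 3,
    n_sites: int = 600,
    seed: int = 0,
    between_divergence: float = 0.4,
    within_divergence: float = 0.06,
    lineage_names: Sequence[str] | None = None,
    gtr: GTRGammaParams | None = None,
):
    """A gene-family reference panel with nested monophyletic lineages.

    Builds a backbone tree over lineage ancestors (long branches), hangs a
    small subtree of ``taxa_per_lineage`` members under each (short
    branches), evolves a nucleotide alignment under GTR+Gamma, and labels
    each lineage clade on the tree.  Returns (ReferencePanel, truth)
    where truth maps each panel taxon to its lineage.
    """
    from .placement import ReferencePanel  # local import avoids a cycle

    if n_lineages < 2:
        raise ValueError("need at least 2 lineages")
    if within_divergence <= 0 or between_divergence <= 0:
        raise ValueError("divergence levels must be positive")
    rng = np.random.default_rng(seed)
    names = (
        list(lineage_names)
        if lineage_names is not None
        else [f"L{i+1}" for i in range(n_lineages)]
    )
    if len(names) != n_lineages:
        raise ValueError("need one name per lineage")
    # backbone over lineage ancestors
    backbone = simulate_tree(
        n_lineages,
        seed=int(rng.integers(2**31)),
        length_range=(0.6 * between_divergence, 1.4 * between_divergence),
        names=names,
    )
    parent = list(backbone.parent)
    lengths = list(backbone.lengths)
    labels: list[str | None] = [None] * len(parent)
    clades: dict[str, list[str]] = {}
    for li, anchor in enumerate(backbone.leaf_indices):
        sub = simulate_tree(
            max(taxa_per_lineage, 2),
            seed=int(rng.integers(2**31)),
            length_range=(0.5 * within_divergence, 1.5 * within_divergence),
            names=[f"{names[li]}_{j+1}" for j in range(max(taxa_per_lineage, 2))],
        )
        offset = len(parent)
        # graft: the subtree root replaces the backbone leaf `anchor`
        for i in range(1, len(sub.parent)):  # skip sub root, merged into anchor
            parent.append(offset + sub.parent[i] - 1 if sub.parent[i] != 0 else anchor)
            lengths.append(sub.lengths[i])
            labels.append(sub.labels[i])
        clades[names[li]] = [n for n in sub.leaf_names]
    # taxa_per_lineage == 1 would leave the anchor a labelled leaf; the
    # minimum of 2 above keeps every lineage a proper clade
    tree = LabeledTree(parent, lengths, labels, clades=clades)
    gtr = gtr or GTRGammaParams(
        np.array([1.0, 2.5, 0.8, 1.1, 2.8, 1.0]),
        np.array([0.30, 0.20, 0.22, 0.28]),
        alpha=0.8,
    )
    aln = simulate_nucleotide_alignment(tree, gtr, n_sites, seed=int(rng.integers(2**31)))
    truth = {taxon: lin for lin, members in clades.items() for taxon in members}
    return ReferencePanel(aln, tree, gtr), truth


def simulate_diel_experiment(
    panel,
    design: pd.DataFrame | None = None,
    samples: pd.DataFrame | None = None,
    contigs_per_lineage: int = 3,
    seed: int = 0,
    library_size: int = 1_000_000,
    mutation_rate: float = 0.02,
    fragment_length: tuple[float, float] = (400.0, 150.0),
    min_fragment: int = 200,
):
    """Contigs + read counts for a day/night x watering-regime experiment.

    For every sample and lineage with planted rpm > 0, fragments of a
    randomly chosen lineage source sequence become contigs (uniform start,
    clamped-normal length, point mutations at ``mutation_rate``); read
    counts are multinomial with per-contig probabilities chosen so the
    expected summed rpm of a lineage equals the design cell.  Reads not
    allotted to panel lineages form an off-target remainder, so per-sample
    totals behave like real alignable-read totals.

    Returns (contigs, counts, truth): SequenceRecords per sample, a tidy
    counts table (contig, sample, count, total_alignable) and a truth
    table mapping each contig to its source lineage.
    """
    design = DEFAULT_DIEL_DESIGN if design is None else design
    samples = DIEL_SAMPLES.loc[design.columns] if samples is None else samples
    if (design.values < 0).any():
        raise ValueError("planted rpm must be nonnegative")
    if (design.values.sum(axis=0) == 0).any():
        raise ValueError("every sample needs nonzero planted abundance")
    if (design.values.sum(axis=0) > library_size).any():
        raise ValueError("per-sample design exceeds the library size")
    unknown = set(design.index) - set(panel.tree.clades)
    if unknown:
        raise KeyError(f"design lineages missing from panel: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    source = {
        lin: [panel.alignment.row(t).replace("-", "") for t in sorted(members)]
        for lin, members in panel.tree.clades.items()
    }
    mu, sd = fragment_length
    contigs: list[SequenceRecord] = []
    count_rows = []
    truth_rows = []
    for sample in design.columns:
        probs, contig_ids = [], []
        for lineage in design.index:
            rpm = float(design.loc[lineage, sample])
            if rpm <= 0:
                continue
            seqs = source[lineage]
            for j in range(contigs_per_lineage):
                src = seqs[rng.integers(len(seqs))]
                length = int(np.clip(rng.normal(mu, sd), min_fragment, len(src)))
                start = int(rng.integers(0, max(len(src) - length, 0) + 1))
                frag = np.array(list(src[start : start + length]))
                nmut = rng.binomial(len(frag), mutation_rate)
                if nmut:
                    pos = rng.choice(len(frag), size=nmut, replace=False)
                    frag[pos] = _NT[rng.integers(4, size=nmut)]
                cid = f"{sample}_{lineage}_c{j+1}"
                contigs.append(SequenceRecord(cid, "".join(frag), "dna"))
                truth_rows.append({"contig": cid, "sample": sample, "lineage": lineage})
                contig_ids.append(cid)
                probs.append(rpm / library_size / contigs_per_lineage)
        probs = np.array(probs)
        off_target = max(0.0, 1.0 - probs.sum())
        draws = rng.multinomial(library_size, np.append(probs, off_target))
        for cid, cnt in zip(contig_ids, draws[:-1]):
            count_rows.append(
                {
                    "contig": cid,
                    "sample": sample,
                    "count": int(cnt),
                    "total_alignable": library_size,
                }
            )
    counts = pd.DataFrame(count_rows)
    truth = pd.DataFrame(truth_rows)
    truth.attrs["design"] = design
    return contigs, counts, truth
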