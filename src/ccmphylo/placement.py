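"""Phylogenetic annotation of transcriptome contigs.

A contig is annotated in four steps against a *reference panel* (a fixed
nucleotide alignment, a reference tree whose named clades are the gene
lineages, and GTR+Gamma parameters):

1. extract its longest homologous segment (k-mer seeded local alignment,
   both strands), discarding matches at or below a minimum length;
2. align the segment to the reference alignment's frozen columns
   (query-only insertions are dropped);
3. attach the query to the midpoint of every branch of the reference
   tree, optimising the pendant branch length under GTR+Gamma, and keep
   the best-scoring branch with its likelihood weight ratio (lwr);
4. assign the contig to a gene lineage iff the best branch lies strictly
   inside the lineage's clade (not on its stem) and the lwr clears a
   confidence threshold — the operational form of "clearly nested
   within" a lineage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio import Align
from numba import njit
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import NucleotideAlignment, SequenceRecord
from .ratematrix import GTRGammaParams, SpectralMatrix, discrete_gamma_rates, gtr_rate_matrix
from .likelihood import TreePruner
from .tree import LabeledTree

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferencePanel:
    """Reference alignment + lineage-labelled tree + GTR+Gamma parameters."""

    alignment: NucleotideAlignment
    tree: LabeledTree
    gtr: GTRGammaParams

    def __post_init__(self) -> None:
        if set(self.alignment.ids) != set(self.tree.leaf_names):
            raise ValueError("panel tree leaves must equal alignment taxa")
        if not self.tree.clades:
            raise ValueError("panel tree must name at least one lineage clade")
        for name in self.tree.clades:
            if not self.tree.is_monophyletic(name):
                raise ValueError(f"lineage {name!r} is not monophyletic")

    @property
    def lineages(self) -> list[str]:
        return sorted(self.tree.clades)


@dataclass(frozen=True)
class MatchedRegion:
    """Homologous stretch of a contig, 1-based inclusive forward coordinates."""

    start: int
    end: int
    strand: str  # '+' or '-'
    ref_id: str
    score: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Placement:
    """Best attachment of one query on the reference tree."""

    query_id: str
    branch_scores: dict[str, float]
    pendant_lengths: dict[str, float]
    best_branch: str
    lwr: float


@dataclass
class ContigAssignment:
    contig: str
    sample: str
    region: tuple[int, int] | None
    lineage: str
    rpm: float
    lwr: float = float("nan")


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _local_aligner(match: float, mismatch: float, open_: float, extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_
    aligner.extend_gap_score = extend
    return aligner


def find_homologous_segment(
    contig: str | SequenceRecord,
    panel: ReferencePanel,
    min_len: int = 50,
    check_reverse: bool = True,
    word_size: int = 12,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> MatchedRegion | None:
    """Longest local match of a contig against any reference sequence.

    Exact ``word_size``-mers seed candidate references; candidates are
    scored by affine local alignment and the longest matching region on
    the contig is kept when strictly longer than ``min_len`` bases.  The
    reverse strand is searched when flagged; coordinates are always
    reported on the forward contig with a strand flag.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = contig.seq if isinstance(contig, SequenceRecord) else contig
    seq = seq.upper()
    aligner = _local_aligner(match, mismatch, gap_open, gap_extend)
    refs = {
        rid: row.replace("-", "") for rid, row in zip(panel.alignment.ids, panel.alignment.rows)
    }
    best: MatchedRegion | None = None
    strands = [("+", seq)] + ([("-", reverse_complement(seq))] if check_reverse else [])
    for strand, s in strands:
        if len(s) < word_size:
            continue
        words = _kmers(s, word_size)
        for rid, ref in refs.items():
            if not words & _kmers(ref, word_size):
                continue
            alns = aligner.align(s, ref)
            if len(alns) == 0:
                continue
            aln = alns[0]
            blocks = aln.aligned[0]
            if len(blocks) == 0:
                continue
            qs, qe = int(blocks[0][0]), int(blocks[-1][1])  # [qs, qe) on s
            if strand == "+":
                start, end = qs + 1, qe
            else:
                start, end = len(seq) - qe + 1, len(seq) - qs
            cand = MatchedRegion(start, end, strand, rid, float(aln.score))
            if (
                best is None
                or cand.length > best.length
                or (cand.length == best.length and cand.score > best.score)
            ):
                best = cand
    if best is None or best.length <= min_len:
        return None
    return best


# -- profile alignment ---------------------------------------------------

_MATCH_STATE, _DEL_STATE, _INS_STATE = 0, 1, 2


@njit(cache=True)
def _profile_dp(scores, gap_open, gap_extend, ins_open, ins_extend):  # pragma: no cover
    m, n = scores.shape  # query length x profile columns
    NEG = -1e30
    M = np.full((m + 1, n + 1), NEG)
    D = np.full((m + 1, n + 1), NEG)  # gap in query (profile column skipped)
    I = np.full((m + 1, n + 1), NEG)  # insertion in query (column absent)
    ptrM = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrD = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrI = np.zeros((m + 1, n + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for j in range(1, n + 1):
        D[0, j] = 0.0  # free leading reference columns
        ptrD[0, j] = _DEL_STATE
    for i in range(1, m + 1):
        I[i, 0] = ins_open + (i - 1) * ins_extend
        ptrI[i, 0] = _INS_STATE if i > 1 else _MATCH_STATE
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = scores[i - 1, j - 1]
            bm, bd, bi = M[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1]
            if bm >= bd and bm >= bi:
                M[i, j] = bm + s
                ptrM[i, j] = _MATCH_STATE
            elif bd >= bi:
                M[i, j] = bd + s
                ptrM[i, j] = _DEL_STATE
            else:
                M[i, j] = bi + s
                ptrM[i, j] = _INS_STATE
            od, cd = M[i, j - 1] + gap_open, D[i, j - 1] + gap_extend
            if od >= cd:
                D[i, j] = od
                ptrD[i, j] = _MATCH_STATE
            else:
                D[i, j] = cd
                ptrD[i, j] = _DEL_STATE
            oi, ci = M[i - 1, j] + ins_open, I[i - 1, j] + ins_extend
            if oi >= ci:
                I[i, j] = oi
                ptrI[i, j] = _MATCH_STATE
            else:
                I[i, j] = ci
                ptrI[i, j] = _INS_STATE
    # free trailing reference columns: best cell in row m
    best_j, best_state, best_score = n, _MATCH_STATE, NEG
    for j in range(n + 1):
        if M[m, j] >= best_score:
            best_j, best_state, best_score = j, _MATCH_STATE, M[m, j]
        if I[m, j] > best_score:
            best_j, best_state, best_score = j, _INS_STATE, I[m, j]
    # traceback
    path = np.zeros(m + n + 2, dtype=np.int8)
    cols = np.zeros(m + n + 2, dtype=np.int64)
    steps = 0
    i, j, state = m, best_j, best_state
    while i > 0 or j > 0:
        path[steps] = state
        cols[steps] = j
        if state == _MATCH_STATE:
            if i == 0:
                state = _DEL_STATE
                continue
            prev = ptrM[i, j]
            i -= 1
            j -= 1
            state = prev
        elif state == _DEL_STATE:
            prev = ptrD[i, j]
            j -= 1
            state = prev
        else:
            prev = ptrI[i, j]
            i -= 1
            state = prev
        steps += 1
    return path[:steps][::-1], cols[:steps][::-1], best_score


def profile_align_query(
    segment: str | SequenceRecord,
    ref_alignment: NucleotideAlignment,
    query_id: str = "query",
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
    max_insertion_fraction: float = 0.8,
):
    """Align a segment to the frozen columns of a reference alignment.

    The reference columns never change: the query's bases are distributed
    over them by affine-gap dynamic programming against position-specific
    nucleotide frequencies; query-only insertions are discarded and their
    count returned.  Raises when more than ``max_insertion_fraction`` of
    the query's bases cannot be placed in reference columns.

    Returns (augmented_alignment, n_dropped_insertions).
    """
    if isinstance(segment, SequenceRecord):
        query_id, seq = segment.id, segment.seq
    else:
        seq = segment
    seq = seq.upper()
    if not seq:
        raise ValueError("empty query segment")
    n_cols = ref_alignment.n_sites
    freqs = np.zeros((n_cols, 5))
    for row in ref_alignment.rows:
        for j, ch in enumerate(row):
            freqs[j, _NT_INDEX.get(ch, 4)] += 1
    freqs /= len(ref_alignment.rows)
    qidx = np.array([_NT_INDEX.get(c, -1) for c in seq], dtype=np.int64)
    # expected match/mismatch score of each base against each column
    scores = np.zeros((len(seq), n_cols))
    for b in range(4):
        col_score = match * freqs[:, b] + mismatch * (
            1.0 - freqs[:, b] - freqs[:, 4]
        )
        scores[qidx == b] = col_score
    path, cols, _ = _profile_dp(
        scores, gap_open, gap_extend, gap_open, gap_extend
    )
    out = ["-"] * n_cols
    qi = 0
    dropped = 0
    for state, j in zip(path, cols):
        if state == _MATCH_STATE:
            out[j - 1] = seq[qi]
            qi += 1
        elif state == _INS_STATE:
            dropped += 1
            qi += 1
    if dropped > max_insertion_fraction * len(seq):
        raise ValueError(
            f"query {query_id!r} is unalignable: {dropped}/{len(seq)} bases "
            "fall outside reference columns"
        )
    return ref_alignment.add_row(query_id, "".join(out)), dropped


# -- likelihood placement ------------------------------------------------


def place_query(
    aug_alignment: NucleotideAlignment,
    panel: ReferencePanel,
    max_pendant: float = 5.0,
) -> Placement:
    """Attach the query to every branch midpoint and score by GTR+Gamma.

    The pendant branch length is optimised per branch (Brent); the best
    branch is the argmax of the optimised log-likelihood, ties broken by
    shorter pendant then branch id.  The likelihood weight ratio (lwr) is
    the softmax weight of the best branch over all branches.
    """
    tree = panel.tree
    query_ids = [t for t in aug_alignment.ids if t not in set(tree.leaf_names)]
    if len(query_ids) != 1:
        raise ValueError("augmented alignment must contain exactly one query row")
    qid = query_ids[0]
    states = aug_alignment.state_matrix()
    qrow = states[aug_alignment.ids.index(qid)]
    pruner = TreePruner(
        tree,
        np.vstack([states[[i for i, t in enumerate(aug_alignment.ids) if t != qid]], qrow[None, :]]),
        [t for t in aug_alignment.ids if t != qid],
        4,
        allow_extra=True,
    )
    qstates = pruner.pattern_states[-1]
    qpart = np.ones((pruner.n_patterns, 4))
    obs = qstates >= 0
    qpart[obs] = 0.0
    qpart[np.flatnonzero(obs), qstates[obs]] = 1.0
    if not obs.any():
        raise ValueError(f"query {qid!r} has no unambiguous characters")

    sm = SpectralMatrix(gtr_rate_matrix(panel.gtr), panel.gtr.base_freqs)
    rates = discrete_gamma_rates(panel.gtr.alpha, panel.gtr.ncat)
    w = pruner.weights
    channels = []
    for r in rates:
        P = sm.probabilities(tree.lengths * r)
        down, dscale, G, gscale = pruner.messages(P, panel.gtr.base_freqs)
        channels.append((r, down, dscale, G, gscale))
    # one of two root edges duplicates the same unrooted attachment
    edges = [n for n in tree.postorder() if n != tree.root]
    if len(tree.children[tree.root]) == 2:
        edges.remove(tree.children[tree.root][1])
    logw = -np.log(len(rates))
    scores: dict[str, float] = {}
    pendants: dict[str, float] = {}
    for v in edges:
        half = tree.lengths[v] / 2.0
        mids = []
        for r, down, dscale, G, gscale in channels:
            Ph = sm.probability(half * r)
            m_down = down[v] @ Ph.T
            m_up = G[v] @ Ph
            mids.append((r, m_up * m_down, dscale[v] + gscale[v]))

        def neg(tp: float) -> float:
            logs = []
            for r, H, const in mids:
                Pq = sm.probability(tp * r)
                lik = (H * (qpart @ Pq.T)).sum(axis=1)
                logs.append(np.log(np.maximum(lik, 1e-300)) + const)
            site = logsumexp(np.stack(logs) + logw, axis=0)
            return -float(w @ site)

        res = minimize_scalar(
            neg, bounds=(1e-9, max_pendant), method="bounded", options={"xatol": 1e-5}
        )
        bid = tree.branch_ids[v]
        scores[bid] = -res.fun
        pendants[bid] = float(res.x)
    ids = sorted(scores, key=lambda b: (-scores[b], pendants[b], b))
    best = ids[0]
    all_scores = np.array(list(scores.values()))
    lwr = float(np.exp(scores[best] - logsumexp(all_scores)))
    return Placement(qid, scores, pendants, best, lwr)


def assign_lineage(
    placement: Placement, panel: ReferencePanel, lwr_threshold: float = 0.8
) -> str:
    """Lineage of the placement's best branch, or ``"unassigned"``.

    Assigned iff the best branch lies strictly inside a lineage clade
    (the stem branch does not count) and the placement's lwr reaches the
    threshold.
    """
    if not 0 < lwr_threshold <= 1:
        raise ValueError("lwr threshold must lie in (0, 1]")
    if placement.lwr < lwr_threshold:
        return "unassigned"
    node = panel.tree.node_of_branch(placement.best_branch)
    for name in panel.lineages:
        if panel.tree.strictly_within_clade(node, name):
            return name
    return "unassigned"


def annotate_contigs(
    contigs: Iterable[SequenceRecord],
    panel: ReferencePanel,
    counts,
    min_len: int = 50,
    lwr_threshold: float = 0.8,
    check_reverse: bool = True,
) -> list[ContigAssignment]:
    """Run the full per-contig pipeline: segment -> profile -> placement
    -> lineage, joining read counts into rpm values.

    ``counts`` is a tidy table with columns contig, sample, count,
    total_alignable (one row per contig per sample).
    """
    from .expression import compute_rpm

    by_contig = {rec.id: rec for rec in contigs}
    out: list[ContigAssignment] = []
    cache: dict[str, tuple] = {}
    for _, row in counts.iterrows():
        cid, sample = row["contig"], row["sample"]
        rpm = compute_rpm({cid: row["count"]}, row["total_alignable"])[cid]
        if cid not in cache:
            cache[cid] = _annotate_one(
                by_contig[cid], panel, min_len, lwr_threshold, check_reverse
            )
        region, lineage, lwr = cache[cid]
        out.append(ContigAssignment(cid, sample, region, lineage, rpm, lwr))
    return out


def _annotate_one(rec, panel, min_len, lwr_threshold, check_reverse):
    region = find_homologous_segment(
        rec, panel, min_len=min_len, check_reverse=check_reverse
    )
    if region is None:
        return None, "unassigned", float("nan")
    seg = rec.seq[region.start - 1 : region.end]
    if region.strand == "-":
        seg = reverse_complement(seg)
    try:
        aug, _ = profile_align_query(seg, panel.alignment, query_id=rec.id)
    except ValueError:
        return (region.start, region.end), "unassigned", float("nan")
    placement = place_query(aug, panel)
    lineage = assign_lineage(placement, panel, lwr_threshold)
    return (region.start, region.end), lineage, placement.lwr
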