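"""Homology search, profile alignment and likelihood placement."""

import numpy as np
import pytest
from Bio import Align

import ccmphylo as cp
from ccmphylo.alignment import NucleotideAlignment
from ccmphylo.placement import (
    MatchedRegion,
    assign_lineage,
    find_homologous_segment,
    place_query,
    profile_align_query,
    reverse_complement,
)


class TestFindHomologousSegment:
    def test_exact_copy_matches_full_length(self, panel5):
        panel, _ = panel5
        ref = panel.alignment.rows[0].replace("-", "")
        region = find_homologous_segment(ref, panel, min_len=50)
        assert region.strand == "+"
        assert (region.start, region.end) == (1, len(ref))

    def test_short_match_below_min_len_rejected(self, panel5):
        panel, _ = panel5
        ref = panel.alignment.rows[0].replace("-", "")
        contig = ref[:40]
        assert find_homologous_segment(contig, panel, min_len=50) is None
        assert find_homologous_segment(contig, panel, min_len=30) is not None

    def test_reverse_complement_found_with_forward_coordinates(self, panel5):
        """A reverse-complemented insert must be located on the forward
        contig, with coordinates agreeing with a Smith-Waterman oracle."""
        panel, _ = panel5
        ref = panel.alignment.rows[3].replace("-", "")
        insert = reverse_complement(ref[100:400])
        contig = "TTTTT" + insert + "GGGGG"
        region = find_homologous_segment(contig, panel, min_len=50)
        assert region.strand == "-"
        # oracle: plain local alignment of the rc-contig against that ref
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score, aligner.mismatch_score = 1, -2
        aligner.open_gap_score, aligner.extend_gap_score = -5, -2
        aln = aligner.align(reverse_complement(contig), ref)[0]
        qs, qe = aln.aligned[0][0][0], aln.aligned[0][-1][1]
        expect = (len(contig) - qe + 1, len(contig) - qs)
        assert (region.start, region.end) == expect

    def test_unrelated_sequence_returns_none(self, panel5):
        panel, _ = panel5
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), size=200))
        region = find_homologous_segment(junk, panel, min_len=50)
        assert region is None or region.length <= 60


class TestProfileAlign:
    def test_reference_columns_frozen(self, panel5):
        panel, _ = panel5
        seg = panel.alignment.rows[2].replace("-", "")[50:300]
        aug, dropped = profile_align_query(seg, panel.alignment)
        assert aug.n_sites == panel.alignment.n_sites
        assert aug.rows[: panel.alignment.n_taxa] == panel.alignment.rows

    def test_identical_row_reproduces_gap_pattern(self):
        ref = NucleotideAlignment(
            ["r1", "r2"], ["ACGT--ACGTAC", "ACGTTTACGTAC"]
        )
        aug, dropped = profile_align_query("ACGTACGTAC", ref, query_id="q")
        assert aug.row("q") == "ACGT--ACGTAC"
        assert dropped == 0

    def test_deletion_placed_consistently_with_exhaustive_scan(self):
        """A 3 bp deletion must land where an exhaustive single-gap scan of
        the same scoring function puts it."""
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("ACGT"), size=60))
        ref = NucleotideAlignment(["r1", "r2", "r3"], [base] * 3)
        cut = 25
        query = base[:cut] + base[cut + 3 :]
        aug, dropped = profile_align_query(query, ref, query_id="q")
        row = aug.row("q")
        assert dropped == 0
        assert row.count("-") == 3
        # oracle: try every contiguous 3-gap placement, score by matches
        best_score, best_rows = -1, []
        for g in range(len(base) - 2):
            cand = query[:g] + "---" + query[g:]
            cand = cand[: len(base)]
            score = sum(a == b for a, b in zip(cand, base) if a != "-")
            if score > best_score:
                best_score, best_rows = score, [cand]
            elif score == best_score:
                best_rows.append(cand)
        assert sum(a == b for a, b in zip(row, base) if a != "-") == best_score

    def test_empty_query_rejected(self, panel5):
        panel, _ = panel5
        with pytest.raises(ValueError):
            profile_align_query("", panel.alignment)


class TestPlacement:
    def test_reference_leaf_places_on_its_own_branch(self, panel5):
        panel, truth = panel5
        leaf = panel.alignment.ids[4]
        aug = panel.alignment.add_row("query", panel.alignment.row(leaf))
        placement = place_query(aug, panel)
        assert placement.best_branch == leaf
        assert 0 < placement.lwr <= 1
        assert assign_lineage(placement, panel, 0.5) == truth[leaf]

    def test_scores_invariant_to_reference_taxon_order(self, panel5):
        panel, _ = panel5
        leaf = panel.alignment.ids[0]
        row = panel.alignment.row(leaf)
        aug1 = panel.alignment.add_row("query", row)
        perm = list(reversed(panel.alignment.ids))
        aug2 = panel.alignment.reorder(perm).add_row("query", row)
        p1 = place_query(aug1, panel)
        p2 = place_query(aug2, panel)
        assert p1.best_branch == p2.best_branch
        for b in p1.branch_scores:
            assert np.isclose(p1.branch_scores[b], p2.branch_scores[b], atol=1e-6)

    def test_all_missing_query_rejected(self, panel5):
        panel, _ = panel5
        aug = panel.alignment.add_row("query", "-" * panel.alignment.n_sites)
        with pytest.raises(ValueError):
            place_query(aug, panel)


class TestAssignLineage:
    def test_backbone_placement_unassigned(self, panel5):
        panel, _ = panel5
        # fabricate a placement on a lineage stem: strictly-within fails
        tree = panel.tree
        stem = tree.mrca(tree.clades[panel.lineages[0]])
        pl = cp.Placement("q", {tree.branch_ids[stem]: -1.0}, {tree.branch_ids[stem]: 0.1},
                          tree.branch_ids[stem], 0.99)
        assert assign_lineage(pl, panel, 0.8) == "unassigned"

    def test_rule_application_inside_clade(self, panel5):
        panel, _ = panel5
        lin = panel.lineages[0]
        member = sorted(panel.tree.clades[lin])[0]
        pl = cp.Placement("q", {member: -1.0}, {member: 0.1}, member, 0.95)
        assert assign_lineage(pl, panel, 0.8) == lin
        assert assign_lineage(pl, panel, 0.96) == "unassigned"

    def test_threshold_sweep_is_monotone(self, panel5):
        """Raising the lwr threshold can only shrink the assigned set."""
        panel, truth = panel5
        rng = np.random.default_rng(12)
        placements = []
        for leaf in panel.alignment.ids[:6]:
            row = panel.alignment.row(leaf)
            # light mutation so lwr varies
            chars = list(row)
            idx = [i for i, c in enumerate(chars) if c != "-"]
            for i in rng.choice(idx, size=30, replace=False):
                chars[i] = "ACGT"[rng.integers(4)]
            aug = panel.alignment.add_row("query", "".join(chars))
            placements.append(place_query(aug, panel))
        prev = None
        for thr in [0.2, 0.5, 0.8, 0.95, 1.0]:
            assigned = {
                p.query_id + p.best_branch
                for p in placements
                if assign_lineage(p, panel, thr) != "unassigned"
            }
            if prev is not None:
                assert assigned <= prev
            prev = assigned
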