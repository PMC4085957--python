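"""Pruning engine vs exhaustive enumeration, closed forms, invariances."""

import numpy as np
import pytest

import ccmphylo as cp
from ccmphylo.alignment import CodonAlignment, NucleotideAlignment
from ccmphylo.likelihood import (
    SiteClassMixture,
    TreePruner,
    codon_channel_set,
    gtr_channel_set,
    gtr_gamma_log_likelihood,
    pruning_log_likelihood,
)
from ccmphylo.ratematrix import CodonModelParams, GTRGammaParams
from ccmphylo.tree import LabeledTree

from conftest import brute_force_mixture_loglik


def random_mixture(rng):
    kind = rng.integers(4)
    p0 = rng.uniform(0.3, 0.8)
    w0 = rng.uniform(0.02, 0.8)
    if kind == 0:
        return SiteClassMixture.m0(rng.uniform(0.05, 3.0))
    if kind == 1:
        return SiteClassMixture.m1a(p0, w0)
    p1 = rng.uniform(0.0, 1 - p0)
    w2 = rng.uniform(1.0, 6.0)
    if kind == 2:
        return SiteClassMixture.m2a(p0, p1, w0, w2)
    return SiteClassMixture.model_a(p0, max(p1, 0.05), w0, w2)


class TestSiteClassMixture:
    def test_model_a_class_partition(self):
        mix = SiteClassMixture.model_a(0.6, 0.232, 0.1, 1.5)
        props = mix.proportions
        assert np.isclose(props.sum(), 1.0)
        # p2a : p2b keeps the p0 : p1 ratio
        assert np.isclose(props[2] / props[3], 0.6 / 0.232)
        assert np.isclose(props[2] + props[3], 1 - 0.6 - 0.232)

    def test_invalid_mixtures_rejected(self):
        with pytest.raises(ValueError):
            SiteClassMixture.m1a(1.4, 0.1)
        with pytest.raises(ValueError):
            SiteClassMixture.m1a(0.5, 1.2)  # omega0 must be <= 1
        with pytest.raises(ValueError):
            SiteClassMixture.m2a(0.7, 0.5, 0.1, 2.0)  # p0+p1 > 1
        with pytest.raises(ValueError):
            SiteClassMixture.model_a(0.5, 0.3, 0.1, 0.5)  # omega2 < 1


class TestPruningBasics:
    def test_single_taxon_single_site_is_log_pi(self, code, uniform_pi):
        tree = LabeledTree([-1], [0.0], ["a"])
        codon = code.sense_codons[17]
        aln = CodonAlignment(["a"], [codon])
        params = CodonModelParams(2.0, 0.5, uniform_pi)
        lnl = pruning_log_likelihood(aln, tree, SiteClassMixture.m0(0.5), params)
        assert np.isclose(lnl, np.log(uniform_pi[17]))

    def test_degenerate_mixture_equals_m0(self, tree8, uniform_pi):
        params = CodonModelParams(2.0, 1.0, uniform_pi)
        aln, _ = cp.simulate_codon_alignment(
            tree8, SiteClassMixture.m0(0.3), params, 40, seed=4
        )
        one_class = SiteClassMixture(((1.0, 0.3, 0.3),), "M0")
        a = pruning_log_likelihood(aln, tree8, SiteClassMixture.m0(0.3), params)
        b = pruning_log_likelihood(aln, tree8, one_class, params)
        assert np.isclose(a, b, atol=1e-10)

    def test_missing_taxon_raises(self, tree8, uniform_pi):
        aln = CodonAlignment(["nobody"], ["ATG"])
        with pytest.raises(KeyError):
            pruning_log_likelihood(
                aln, tree8, SiteClassMixture.m0(1.0), CodonModelParams(2.0, 1.0, uniform_pi)
            )

    def test_branch_site_requires_foreground(self, tree8, uniform_pi):
        params = CodonModelParams(2.0, 1.0, uniform_pi)
        aln, _ = cp.simulate_codon_alignment(
            tree8, SiteClassMixture.m0(0.3), params, 5, seed=4
        )
        with pytest.raises(ValueError, match="foreground"):
            pruning_log_likelihood(
                aln, tree8, SiteClassMixture.model_a(0.5, 0.3, 0.1, 2.0), params
            )


class TestPruningVsEnumeration:
    """The engine must agree with explicit summation over all internal
    states on every small instance, for all model families."""

    @pytest.mark.parametrize("instance", range(12))
    def test_codon_models_match_enumeration(self, instance, code):
        rng = np.random.default_rng(100 + instance)
        n_taxa = int(rng.integers(2, 5))
        n_sites = int(rng.integers(1, 6))
        tree = cp.simulate_tree(n_taxa, seed=int(rng.integers(2**31)))
        if rng.random() < 0.7:
            fg_pool = [i for i in range(len(tree.parent)) if i != tree.root]
            tree.foreground[rng.choice(fg_pool)] = True
        pi = rng.dirichlet(np.ones(61) * 10)
        params = CodonModelParams(float(rng.uniform(1, 5)), 1.0, pi)
        mixture = random_mixture(rng)
        if mixture.is_branch_site and not tree.foreground.any():
            tree.foreground[tree.leaf_indices[0]] = True
        aln, _ = cp.simulate_codon_alignment(
            tree, mixture, params, n_sites, seed=int(rng.integers(2**31))
        )
        # knock a few cells to missing
        rows = [list(r) for r in aln.rows]
        if rng.random() < 0.5:
            rows[0][:3] = "---"
        aln = CodonAlignment(list(aln.ids), ["".join(r) for r in rows])
        lnl = pruning_log_likelihood(aln, tree, mixture, params, code)
        channels = codon_channel_set(tree, mixture, params, code)
        expected = brute_force_mixture_loglik(
            tree, aln.state_matrix(code), list(aln.ids), channels, 61
        )
        assert np.isclose(lnl, expected, atol=1e-8)

    @pytest.mark.parametrize("instance", range(6))
    def test_gtr_gamma_matches_enumeration(self, instance):
        rng = np.random.default_rng(300 + instance)
        n_taxa = int(rng.integers(2, 5))
        tree = cp.simulate_tree(n_taxa, seed=int(rng.integers(2**31)))
        params = GTRGammaParams(
            rng.uniform(0.5, 3.0, size=6), rng.dirichlet(np.ones(4) * 8),
            alpha=float(rng.uniform(0.3, 3.0)),
        )
        aln = cp.simulate_nucleotide_alignment(
            tree, params, int(rng.integers(2, 10)), seed=int(rng.integers(2**31))
        )
        lnl = gtr_gamma_log_likelihood(aln, tree, params)
        channels = gtr_channel_set(tree, params)
        expected = brute_force_mixture_loglik(
            tree, aln.state_matrix(), list(aln.ids), channels, 4
        )
        assert np.isclose(lnl, expected, atol=1e-8)


class TestClosedForms:
    def test_two_taxon_jukes_cantor_limit(self):
        """GTR+Gamma with equal rates/frequencies and alpha -> inf equals
        the closed-form JC69 two-sequence likelihood."""
        t1, t2 = 0.13, 0.21
        tree = LabeledTree([-1, 0, 0], [0.0, t1, t2], [None, "a", "b"])
        aln = NucleotideAlignment(["a", "b"], ["ACGTAC", "ACGTTA"])
        params = GTRGammaParams.jukes_cantor_like(alpha=1e7)
        lnl = gtr_gamma_log_likelihood(aln, tree, params)
        d = t1 + t2
        p_same = 0.25 + 0.75 * np.exp(-4 * d / 3)
        p_diff = (1 - p_same) / 3
        n_same, n_diff = 4, 2
        expected = n_same * np.log(0.25 * p_same) + n_diff * np.log(0.25 * p_diff)
        assert np.isclose(lnl, expected, atol=1e-6)


@pytest.fixture(scope="module")
def setup(uniform_pi):
    tree = cp.simulate_tree(6, seed=9)
    params = CodonModelParams(2.5, 1.0, uniform_pi)
    mixture = SiteClassMixture.m1a(0.6, 0.2)
    aln, _ = cp.simulate_codon_alignment(tree, mixture, params, 30, seed=10)
    return tree, params, mixture, aln


class TestInvariances:
    def test_row_order_invariance(self, setup):
        tree, params, mixture, aln = setup
        shuffled = aln.reorder(list(reversed(aln.ids)))
        a = pruning_log_likelihood(aln, tree, mixture, params)
        b = pruning_log_likelihood(shuffled, tree, mixture, params)
        assert np.isclose(a, b, atol=1e-10)

    def test_zero_length_branch_is_neutral(self, setup):
        tree, params, mixture, aln = setup
        a = pruning_log_likelihood(aln, tree, mixture, params)
        # graft a zero-length edge above an arbitrary leaf
        leaf = tree.leaf_indices[0]
        parent = list(tree.parent) + [int(tree.parent[leaf])]
        new = len(parent) - 1
        parent[leaf] = new
        lengths = list(tree.lengths) + [float(tree.lengths[leaf])]
        lengths[leaf] = 0.0
        labels = list(tree.labels) + [None]
        tree2 = LabeledTree(parent, lengths, labels)
        b = pruning_log_likelihood(aln, tree2, mixture, params)
        assert np.isclose(a, b, atol=1e-10)

    def test_reroot_invariance_under_reversibility(self, setup):
        tree, params, mixture, aln = setup
        # reroot at the first child of the root: likelihood must not change
        a = pruning_log_likelihood(aln, tree, mixture, params)
        import dendropy

        dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        node = dt.seed_node.child_nodes()[0]
        if node.is_leaf():
            node = dt.seed_node.child_nodes()[1]
        dt.reroot_at_node(node, update_bipartitions=False)
        tree2 = LabeledTree.from_newick(dt.as_string(schema="newick"))
        b = pruning_log_likelihood(aln, tree2, mixture, params)
        assert np.isclose(a, b, atol=1e-8)
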