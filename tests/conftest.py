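"""Shared fixtures: small trees, uniform codon frequencies, a reference
panel, and an independent exhaustive-enumeration likelihood oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import ccmphylo as cp
from ccmphylo.genetics import standard_code

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def uniform_pi():
    return np.full(61, 1 / 61)


@pytest.fixture(scope="session")
def tree8():
    return cp.simulate_tree(8, seed=1)


@pytest.fixture(scope="session")
def panel5():
    """A 5-lineage reference panel shared by placement tests."""
    panel, truth = cp.simulate_reference_panel(
        n_lineages=5, taxa_per_lineage=3, n_sites=600, seed=11
    )
    return panel, truth


def brute_force_mixture_loglik(tree, states, taxa, channels, n_states):
    """Exhaustive-enumeration log-likelihood, independent of the pruning
    engine.

    Builds, per site and site class, the full joint tensor over all
    internal-node states by explicit broadcasting (one axis per internal
    node) and sums it — no recursion, no partials, no rescaling.
    ``channels`` is a list of (proportion, P_by_node, pi).
    """
    post = tree.postorder()
    internals = [n for n in post if tree.children[n]]
    axis = {n: i for i, n in enumerate(internals)}
    row_of = {t: i for i, t in enumerate(taxa)}
    n_sites = states.shape[1]
    total = 0.0
    for site in range(n_sites):
        site_lik = 0.0
        for prop, P, pi in channels:
            if prop == 0:
                continue
            shape = [1] * len(internals)
            shape[axis[tree.root]] = n_states
            arr = pi.reshape(shape).copy()
            for v in post:
                if v == tree.root:
                    continue
                p_ax = axis[tree.parent[v]]
                if tree.children[v]:  # internal edge: full factor
                    sh = [1] * len(internals)
                    sh[p_ax], sh[axis[v]] = n_states, n_states
                    # reshape maps the matrix's row axis onto the earlier
                    # tensor axis, so orient rows to the parent first
                    mat = P[v] if p_ax < axis[v] else P[v].T
                    arr = arr * mat.reshape(sh)
                else:  # leaf edge: collapse onto the parent axis
                    s = states[row_of[tree.labels[v]], site]
                    vec = P[v][:, s] if s >= 0 else np.ones(n_states)
                    sh = [1] * len(internals)
                    sh[p_ax] = n_states
                    arr = arr * vec.reshape(sh)
            site_lik += prop * arr.sum()
        total += np.log(site_lik)
    return total
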