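"""Felsenstein pruning over codon and nucleotide alignments.

Site-class mixtures (M0/M1a/M2a and branch-site model A) are expressed as
lists of classes, each a triple (proportion, background omega, foreground
omega); per branch the class uses the foreground omega iff the branch is
flagged foreground.  Gaps, stop codons and ambiguity codons are missing
data and contribute all-ones partial vectors.  Alignment columns are
compressed to unique patterns before any computation, and partials are
rescaled per node so long alignments do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alignment import CodonAlignment, NucleotideAlignment
from .genetics import GeneticCode, standard_code
from .ratematrix import (
    CodonModelParams,
    GTRGammaParams,
    SpectralMatrix,
    codon_rate_components,
    discrete_gamma_rates,
    gtr_rate_matrix,
)
from .tree import LabeledTree

_TINY = 1e-300


@dataclass(frozen=True)
class SiteClassMixture:
    """Site classes of a codon model: (proportion, omega_bg, omega_fg).

    Background omega applies on ordinary branches, foreground omega on
    branches flagged foreground; for site models the two coincide.
    """

    classes: tuple[tuple[float, float, float], ...]
    model_tag: str

    def __post_init__(self) -> None:
        props = np.array([c[0] for c in self.classes])
        if len(props) == 0:
            raise ValueError("mixture needs at least one class")
        if np.any(props < -1e-12) or abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("class proportions must be >= 0 and sum to 1")

    @property
    def proportions(self) -> np.ndarray:
        return np.array([c[0] for c in self.classes])

    @property
    def is_branch_site(self) -> bool:
        return any(abs(b - f) > 0 for _, b, f in self.classes)

    # -- canonical model families ---------------------------------------

    @classmethod
    def m0(cls, omega: float) -> "SiteClassMixture":
        return cls(((1.0, omega, omega),), "M0")

    @classmethod
    def m1a(cls, p0: float, omega0: float) -> "SiteClassMixture":
        _check_unit("p0", p0)
        _check_purifying(omega0)
        return cls(((p0, omega0, omega0), (1 - p0, 1.0, 1.0)), "M1a")

    @classmethod
    def m2a(cls, p0: float, p1: float, omega0: float, omega2: float) -> "SiteClassMixture":
        _check_simplex(p0, p1)
        _check_purifying(omega0)
        if omega2 < 1:
            raise ValueError("positive-selection class needs omega2 >= 1")
        return cls(
            ((p0, omega0, omega0), (p1, 1.0, 1.0), (1 - p0 - p1, omega2, omega2)),
            "M2a",
        )

    @classmethod
    def model_a(
        cls, p0: float, p1: float, omega0: float, omega2: float, null: bool = False
    ) -> "SiteClassMixture":
        """Branch-site model A: classes 0/1 purifying/neutral everywhere,
        classes 2a/2b switch to omega2 on foreground branches only; their
        proportions derive from p0,p1 by the standard partition."""
        _check_simplex(p0, p1)
        _check_purifying(omega0)
        if omega2 < 1:
            raise ValueError("foreground class needs omega2 >= 1")
        p2 = 1 - p0 - p1
        denom = p0 + p1
        if denom <= 0:
            raise ValueError("p0 + p1 must be positive in model A")
        p2a = p2 * p0 / denom
        p2b = p2 * p1 / denom
        return cls(
            (
                (p0, omega0, omega0),
                (p1, 1.0, 1.0),
                (p2a, omega0, omega2),
                (p2b, 1.0, omega2),
            ),
            "modelA_null" if null else "modelA",
        )


def _check_unit(name: str, p: float) -> None:
    if not 0 <= p <= 1:
        raise ValueError(f"{name} must lie in [0, 1]")


def _check_simplex(p0: float, p1: float) -> None:
    if p0 < 0 or p1 < 0 or p0 + p1 > 1 + 1e-12:
        raise ValueError("proportions must be >= 0 with p0 + p1 <= 1")


def _check_purifying(omega0: float) -> None:
    if not 0 <= omega0 <= 1:
        raise ValueError("conserved-class omega0 must lie in [0, 1]")


class TreePruner:
    """Pruning engine bound to one (tree, alignment) pair.

    Handles any state count (61 codon states or 4 nucleotides).  Leaves of
    the tree absent from the alignment carry all-missing data.
    """

    def __init__(
        self,
        tree: LabeledTree,
        states: np.ndarray,
        taxa: list[str],
        n_states: int,
        allow_extra: bool = False,
    ):
        tree_leaves = set(tree.leaf_names)
        missing = [t for t in taxa if t not in tree_leaves]
        if missing:
            raise KeyError(f"alignment taxa not in tree: {missing}")
        if not allow_extra and states.shape[0] != len(taxa):
            raise ValueError("one state row per taxon expected")
        self.tree = tree
        self.n_states = n_states
        # compress columns into unique patterns
        cols = np.ascontiguousarray(states.T)
        patterns, inverse, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        self.pattern_states = patterns.T  # (n_taxa, n_patterns)
        self.pattern_index = inverse.ravel()
        self.weights = counts.astype(float)
        self.n_patterns = patterns.shape[0]
        # leaf partials, indexed by tree node; one-hot rows are also kept
        # as state indices so "partial @ P.T" reduces to a row gather
        self.leaf_partials: dict[int, np.ndarray] = {}
        self.leaf_state: dict[int, np.ndarray] = {}
        row_of = {t: i for i, t in enumerate(taxa)}
        for node in tree.leaf_indices:
            name = tree.labels[node]
            part = np.ones((self.n_patterns, n_states))
            st = np.full(self.n_patterns, -1, dtype=np.int64)
            if name in row_of:
                st = self.pattern_states[row_of[name]].astype(np.int64)
                obs = st >= 0
                part[obs] = 0.0
                part[np.flatnonzero(obs), st[obs]] = 1.0
            self.leaf_partials[node] = part
            self.leaf_state[node] = st
        self._postorder = tree.postorder()
        self._internal = [n for n in self._postorder if tree.children[n]]

    # -- core passes ----------------------------------------------------

    def class_site_loglik(self, P: np.ndarray, pi: np.ndarray) -> np.ndarray:
        """Per-pattern log site likelihood for one site class.

        ``P`` is (n_nodes, S, S), indexed by the child node of each branch.
        """
        root = self.tree.root
        if self.tree.is_leaf(root):  # single-taxon tree
            return np.log(np.maximum(self.leaf_partials[root] @ pi, _TINY))
        down, dscale = {}, {}
        for node in self._internal:
            prod = np.ones((self.n_patterns, self.n_states))
            scale = np.zeros(self.n_patterns)
            for c in self.tree.children[node]:
                if c in self.leaf_state:
                    prod *= self._leaf_message(c, P[c])
                else:
                    prod *= down.pop(c) @ P[c].T
                    scale += dscale.pop(c)
            mx = prod.max(axis=1)
            np.maximum(mx, _TINY, out=mx)
            prod /= mx[:, None]
            down[node] = prod
            dscale[node] = scale + np.log(mx)
        lik = down[root] @ pi
        return np.log(np.maximum(lik, _TINY)) + dscale[root]

    def mixture_loglik(
        self,
        channels: list[tuple[float, np.ndarray, np.ndarray]],
        return_site: bool = False,
    ):
        """Total log-likelihood of a mixture.

        ``channels`` is a list of (proportion, P, pi); proportions may be
        mixture-class proportions or gamma-category weights.
        """
        props = np.array([c[0] for c in channels])
        keep = props > 0
        logp = np.log(props[keep])
        per_class = np.stack(
            [
                self.class_site_loglik(P, pi)
                for (w, P, pi), use in zip(channels, keep)
                if use
            ]
        )
        site = logsumexp(per_class + logp[:, None], axis=0)
        total = float(self.weights @ site)
        if return_site:
            return total, site[self.pattern_index]
        return total

    def _leaf_message(self, node: int, P: np.ndarray) -> np.ndarray:
        """(one-hot leaf partial) @ P.T as a row gather; missing -> ones."""
        st = self.leaf_state[node]
        PT = np.vstack([P.T, np.ones(self.n_states)])
        return PT[st]  # st == -1 picks the all-ones row

    # -- messages for per-edge work (branch optimization, placement) ----

    def messages(self, P: np.ndarray, pi: np.ndarray):
        """Down partials and rest-of-tree messages for every node.

        Returns (down, dscale, G, gscale): ``down[v]`` is the conditional
        likelihood of the subtree below v; ``G[v]`` is the likelihood
        message of everything outside v's subtree, evaluated at v's parent
        (root frequencies included), so the per-site likelihood is
        sum_x G[v][x] * (P_v(t_v) @ down[v])[x] for any branch v.
        """
        n = len(self.tree.parent)
        down = [None] * n
        dscale = np.zeros((n, self.n_patterns))
        for node in self._postorder:
            if self.tree.is_leaf(node):
                down[node] = self.leaf_partials[node]
                continue
            prod = np.ones((self.n_patterns, self.n_states))
            scale = np.zeros(self.n_patterns)
            for c in self.tree.children[node]:
                if c in self.leaf_state:
                    prod *= self._leaf_message(c, P[c])
                else:
                    prod *= down[c] @ P[c].T
                    scale += dscale[c]
            mx = np.maximum(prod.max(axis=1), _TINY)
            prod /= mx[:, None]
            down[node] = prod
            dscale[node] = scale + np.log(mx)
        G = [None] * n
        gscale = np.zeros((n, self.n_patterns))
        A = [None] * n
        ascale = np.zeros((n, self.n_patterns))
        A[self.tree.root] = np.broadcast_to(pi, (self.n_patterns, self.n_states))
        for node in reversed(self._postorder):  # preorder
            kids = self.tree.children[node]
            if not kids:
                continue
            ms = [
                self._leaf_message(c, P[c])
                if c in self.leaf_state
                else down[c] @ P[c].T
                for c in kids
            ]
            for i, c in enumerate(kids):
                g = A[node].copy()
                sc = ascale[node].copy()
                for j, m in enumerate(ms):
                    if j != i:
                        g = g * m
                        sc = sc + dscale[kids[j]]
                mx = np.maximum(g.max(axis=1), _TINY)
                g /= mx[:, None]
                G[c] = g
                gscale[c] = sc + np.log(mx)
                a = g @ P[c]
                mx2 = np.maximum(a.max(axis=1), _TINY)
                A[c] = a / mx2[:, None]
                ascale[c] = gscale[c] + np.log(mx2)
        return down, dscale, G, gscale


# -- high-level assembly -------------------------------------------------


def codon_mixture_spectral(
    mixture: SiteClassMixture,
    params: CodonModelParams,
    code: GeneticCode | None = None,
) -> dict[float, SpectralMatrix]:
    """One spectral generator per distinct omega of a mixture.

    All classes share a single scale factor — the mixture-averaged
    substitution rate under the *background* omegas — so branch lengths
    are expected substitutions per codon averaged over site classes, and
    a foreground class with omega2 > 1 adds substitutions rather than
    merely recomposing them (the codeml convention).
    """
    code = code or standard_code()
    A, B, a, b = codon_rate_components(params.kappa, params.pi, code)
    scale = sum(prop * (a + b * w_bg) for prop, w_bg, _ in mixture.classes)
    if scale <= 0:
        raise ValueError("degenerate mixture: zero mean substitution rate")
    omegas = {w for _, wb, wf in mixture.classes for w in (wb, wf)}
    return {
        w: SpectralMatrix((A + w * B) / scale, params.pi) for w in sorted(omegas)
    }


def codon_channel_set(
    tree: LabeledTree,
    mixture: SiteClassMixture,
    params: CodonModelParams,
    code: GeneticCode | None = None,
) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Per-class transition-probability stacks for a codon mixture.

    Spectral decompositions are shared across classes with equal omega;
    foreground branches get the class's foreground omega.
    """
    code = code or standard_code()
    if mixture.is_branch_site and not tree.foreground.any():
        raise ValueError("branch-site mixture requires foreground branches on the tree")
    lengths = tree.lengths
    spectral = codon_mixture_spectral(mixture, params, code)
    stacks: dict[float, np.ndarray] = {}

    def P_for(omega: float) -> np.ndarray:
        if omega not in stacks:
            stacks[omega] = spectral[omega].probabilities(lengths)
        return stacks[omega]

    fg = tree.foreground
    channels = []
    for prop, w_bg, w_fg in mixture.classes:
        P = P_for(w_bg)
        if w_fg != w_bg and fg.any():
            P = P.copy()
            P[fg] = P_for(w_fg)[fg]
        channels.append((prop, P, params.pi))
    return channels


def pruning_log_likelihood(
    aln: CodonAlignment,
    tree: LabeledTree,
    mixture: SiteClassMixture,
    params: CodonModelParams,
    code: GeneticCode | None = None,
    return_site: bool = False,
):
    """Log-likelihood of a codon alignment under a site/branch-site mixture."""
    code = code or standard_code()
    pruner = TreePruner(tree, aln.state_matrix(code), list(aln.ids), code.n_states)
    channels = codon_channel_set(tree, mixture, params, code)
    return pruner.mixture_loglik(channels, return_site=return_site)


def gtr_channel_set(
    tree: LabeledTree, params: GTRGammaParams
) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Per-gamma-category transition stacks under GTR+Gamma."""
    Q = gtr_rate_matrix(params)
    sm = SpectralMatrix(Q, params.base_freqs)
    rates = discrete_gamma_rates(params.alpha, params.ncat)
    w = 1.0 / len(rates)
    return [
        (w, sm.probabilities(tree.lengths * r), params.base_freqs) for r in rates
    ]


def gtr_gamma_log_likelihood(
    aln: NucleotideAlignment,
    tree: LabeledTree,
    params: GTRGammaParams,
    return_site: bool = False,
):
    """Log-likelihood of a nucleotide alignment under GTR+Gamma."""
    pruner = TreePruner(tree, aln.state_matrix(), list(aln.ids), 4)
    return pruner.mixture_loglik(gtr_channel_set(tree, params), return_site=return_site)
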