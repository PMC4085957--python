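"""Phylogenies with branch labels, foreground flags and named lineage clades.

Branch-site codon models need two annotations on top of topology and
branch lengths: per-branch *foreground* flags (the branches hypothesised a
priori to be under adaptive evolution, marked ``#1`` in Newick as in
codeml) and named *gene-lineage* clades used for foreground-set expansion
and for the "nested within a lineage" contig-assignment rule.

Internally a tree is a flat array structure (parent pointers, child lists,
branch lengths indexed by child node); every non-root node identifies the
branch above it.  Newick parsing/writing is delegated to dendropy.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

FOREGROUND_MARK = "#1"


class LabeledTree:
    """Rooted tree; every non-root node indexes the branch above it."""

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        labels: Sequence[str | None],
        clades: Mapping[str, Iterable[str]] | None = None,
        foreground: Sequence[bool] | None = None,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        n = len(self.parent)
        if not (len(self.lengths) == len(self.labels) == n):
            raise ValueError("parent/lengths/labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        if np.any(~np.isfinite(self.lengths)) or np.any(self.lengths < 0):
            raise ValueError("branch lengths must be finite and >= 0")
        leaf_names = [self.labels[i] for i in range(n) if not self.children[i]]
        if any(name is None for name in leaf_names):
            raise ValueError("every leaf must be named")
        if len(set(leaf_names)) != len(leaf_names):
            raise ValueError("leaf names must be unique")
        self.foreground = (
            np.zeros(n, dtype=bool)
            if foreground is None
            else np.asarray(foreground, dtype=bool).copy()
        )
        self.clades: dict[str, frozenset[str]] = {}
        leafset = set(leaf_names)
        for name, members in (clades or {}).items():
            members = frozenset(members)
            if not members <= leafset:
                raise ValueError(f"clade {name!r} references unknown leaves")
            self.clades[name] = members
        self._assign_branch_ids()

    # -- construction ---------------------------------------------------

    def _assign_branch_ids(self) -> None:
        # Leaf branches take the leaf name, labelled internal branches their
        # label, the rest get stable postorder-numbered ids.
        self.branch_ids: list[str | None] = [None] * len(self.parent)
        k = 0
        for i in self.postorder():
            if i == self.root:
                continue
            if self.labels[i] is not None:
                self.branch_ids[i] = self.labels[i]
            else:
                self.branch_ids[i] = f"n{k}"
                k += 1

    @classmethod
    def from_newick(
        cls, source: str, clades: Mapping[str, Iterable[str]] | None = None
    ) -> "LabeledTree":
        """Parse a Newick string; ``#1`` suffixes on labels set foreground."""
        try:
            dtree = dendropy.Tree.get(
                data=source,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise ValueError(f"invalid Newick input: {exc}") from exc
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, lengths, labels, fg = [], [], [], []
        for nd in nodes:
            parent.append(-1 if nd.parent_node is None else index[id(nd.parent_node)])
            lengths.append(nd.edge.length or 0.0)
            raw = nd.taxon.label if nd.taxon else nd.label
            is_fg = False
            if raw is not None:
                raw = raw.strip()
                if raw.endswith(FOREGROUND_MARK):
                    raw = raw[: -len(FOREGROUND_MARK)].strip()
                    is_fg = True
                raw = raw or None
            labels.append(raw)
            fg.append(is_fg)
        return cls(parent, lengths, labels, clades=clades, foreground=fg)

    def to_newick(self, mark_foreground: bool = True) -> str:
        def render(i: int) -> str:
            lab = self.labels[i] or ""
            if mark_foreground and self.foreground[i]:
                lab += " " + FOREGROUND_MARK if lab else FOREGROUND_MARK
            if self.children[i]:
                inner = ",".join(render(c) for c in self.children[i])
                core = f"({inner}){lab}"
            else:
                core = lab
            if i == self.root:
                return core
            return f"{core}:{self.lengths[i]:.10g}"

        return render(self.root) + ";"

    def copy(self) -> "LabeledTree":
        return LabeledTree(
            self.parent.copy(),
            self.lengths.copy(),
            list(self.labels),
            clades=self.clades,
            foreground=self.foreground.copy(),
        )

    # -- structure queries ----------------------------------------------

    def __len__(self) -> int:
        return len(self.parent)

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def leaf_indices(self) -> list[int]:
        return [i for i in range(len(self.parent)) if not self.children[i]]

    @property
    def leaf_names(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_indices]

    @property
    def n_branches(self) -> int:
        return len(self.parent) - 1

    def postorder(self) -> list[int]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(self.children[node])
        out.reverse()
        return out

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def node_of_branch(self, branch_id: str) -> int:
        try:
            return self.branch_ids.index(branch_id)
        except ValueError:
            raise KeyError(f"no branch {branch_id!r} in tree") from None

    def leaves_below(self, i: int) -> frozenset[str]:
        out, stack = [], [i]
        while stack:
            node = stack.pop()
            if self.is_leaf(node):
                out.append(self.labels[node])
            else:
                stack.extend(self.children[node])
        return frozenset(out)

    def mrca(self, leaf_names: Iterable[str]) -> int:
        want = set(leaf_names)
        if not want:
            raise ValueError("mrca of empty leaf set")
        counts = np.zeros(len(self.parent), dtype=np.int64)
        name_to_leaf = {self.labels[i]: i for i in self.leaf_indices}
        for nm in want:
            if nm not in name_to_leaf:
                raise KeyError(f"leaf {nm!r} not in tree")
        for i in self.postorder():
            if self.is_leaf(i):
                counts[i] = self.labels[i] in want
            else:
                counts[i] = sum(counts[c] for c in self.children[i])
        node = self.root
        target = len(want)
        while True:
            nxt = [c for c in self.children[node] if counts[c] == target]
            if not nxt:
                return node
            node = nxt[0]

    def is_monophyletic(self, clade: str) -> bool:
        members = self.clades[clade]
        return self.leaves_below(self.mrca(members)) == members

    def clade_branches(self, clade: str, include_stem: bool = True) -> list[int]:
        """Nodes whose branch lies in a named clade (stem = branch above the
        clade's MRCA)."""
        members = self.clades[clade]
        if not self.is_monophyletic(clade):
            raise ValueError(f"clade {clade!r} is not monophyletic in this tree")
        top = self.mrca(members)
        out, stack = [], list(self.children[top])
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(self.children[node])
        if include_stem and top != self.root:
            out.append(top)
        return sorted(out)

    def strictly_within_clade(self, node: int, clade: str) -> bool:
        """True when the branch above ``node`` is inside the clade but is not
        its stem branch."""
        members = self.clades[clade]
        top = self.mrca(members)
        p = self.parent[node]
        while p >= 0:
            if p == top:
                return True
            p = self.parent[p]
        return False

    # -- foreground handling --------------------------------------------

    def with_foreground(
        self,
        branches: Iterable[str] = (),
        clades: Iterable[str] = (),
        include_stem: bool = True,
    ) -> "LabeledTree":
        """A copy with foreground flags set on named branches and/or on all
        branches of named clades (entire gene lineages)."""
        tree = self.copy()
        tree.foreground[:] = False
        for bid in branches:
            tree.foreground[tree.node_of_branch(bid)] = True
        for name in clades:
            for node in tree.clade_branches(name, include_stem=include_stem):
                tree.foreground[node] = True
        if tree.foreground[tree.root]:
            tree.foreground[tree.root] = False
        return tree

    @property
    def foreground_branch_ids(self) -> list[str]:
        return [
            self.branch_ids[i]
            for i in range(len(self.parent))
            if self.foreground[i] and i != self.root
        ]
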