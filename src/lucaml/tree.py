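"""Rooted species trees with branch lengths.

The species tree is a fixed input of the ancestral-content reconstruction:
its root represents the last universal common ancestor (LUCA) whose gene
states are inferred, and its branch lengths (substitutions per site) are the
times at which the gain/loss Markov chain is evaluated.  Trees are parsed
from Newick with :mod:`dendropy` and re-indexed into flat arrays so that the
pruning recursion can run vectorized over many genes at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "PhylogeneticTree",
    "TreeValidationReport",
    "parse_newick",
    "validate_tree",
]


class TreeError(ValueError):
    """Raised for malformed or invalid species trees."""


@dataclass(frozen=True)
class TreeValidationReport:
    """Summary statistics produced by :func:`validate_tree`."""

    n_leaves: int
    n_internal: int
    max_depth: int
    min_branch_length: float
    max_branch_length: float
    mean_branch_length: float
    median_branch_length: float


class PhylogeneticTree:
    """A rooted tree with named leaves and per-branch lengths.

    Nodes are indexed ``0 .. n_nodes-1`` in postorder (root last).  The
    parent edge of every non-root node carries a nonnegative, finite branch
    length; a branch length on the root, if present in the input, is ignored
    (the root is the inference target, nothing evolves into it).  Polytomies
    are accepted: the pruning recursion works for any out-degree.

    Attributes
    ----------
    parent : ndarray of int
        Parent index per node; ``-1`` for the root.
    branch_length : ndarray of float
        Length of the parent edge per node; ``0.0`` for the root.
    children : list of list of int
        Child indices per node (empty for leaves).
    postorder : ndarray of int
        Node indices in postorder (children before parents, root last).
    leaf_names : list of str
        Names of the leaves, in leaf-node index order.
    """

    def __init__(
        self,
        parent: np.ndarray,
        branch_length: np.ndarray,
        names: list[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=int)
        self.branch_length = np.asarray(branch_length, dtype=float)
        self.n_nodes = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                self.children[p].append(i)
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._names = list(names)
        self.leaf_nodes = [i for i in range(self.n_nodes) if not self.children[i]]
        self.leaf_names = [self._names[i] for i in self.leaf_nodes]
        if any(n is None for n in self.leaf_names):
            raise TreeError("every leaf must be named")
        self.leaf_index = {name: i for name, i in zip(self.leaf_names, self.leaf_nodes)}
        self.postorder = self._compute_postorder()
        self._validate_structure()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhylogeneticTree":
        """Parse a single Newick statement into a tree.

        Raises :class:`TreeError` on malformed input (the dendropy message,
        which names the offending position, is preserved) and on a missing
        branch length on any non-root edge.
        """
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            raise TreeError(f"Newick parse error: {exc}") from exc
        return cls._from_dendropy(dtree)

    @classmethod
    def from_file(cls, path: str) -> "PhylogeneticTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @classmethod
    def _from_dendropy(cls, dtree: dendropy.Tree) -> "PhylogeneticTree":
        dnodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(dnodes)}
        parent = np.full(len(dnodes), -1, dtype=int)
        blen = np.zeros(len(dnodes), dtype=float)
        names: list[str | None] = [None] * len(dnodes)
        for nd in dnodes:
            i = index[id(nd)]
            if nd.taxon is not None:
                names[i] = nd.taxon.label
            elif nd.label is not None:
                names[i] = nd.label
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise TreeError(
                        "missing branch length on a non-root edge "
                        f"(node {names[i] or i})"
                    )
                blen[i] = float(nd.edge.length)
        return cls(parent, blen, names)

    # -- structure ---------------------------------------------------------

    def _compute_postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return np.asarray(order, dtype=int)

    def _validate_structure(self) -> None:
        if len(self.leaf_nodes) < 2:
            raise TreeError("tree must have at least 2 leaves")
        if len(set(self.leaf_names)) != len(self.leaf_names):
            dupes = sorted(
                {n for n in self.leaf_names if self.leaf_names.count(n) > 1}
            )
            raise TreeError(f"duplicate leaf names: {dupes}")
        nonroot = np.arange(self.n_nodes) != self.root
        bl = self.branch_length[nonroot]
        if not np.all(np.isfinite(bl)):
            raise TreeError("non-finite branch length")
        if np.any(bl < 0):
            raise TreeError("negative branch length")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_nodes)

    def depth(self, node: int) -> int:
        d = 0
        while self.parent[node] >= 0:
            node = self.parent[node]
            d += 1
        return d

    def leaves_under(self, node: int) -> list[int]:
        """Leaf node indices in the clade rooted at ``node`` (inclusive)."""
        if not 0 <= node < self.n_nodes:
            raise TreeError(f"unknown node id {node}")
        out, stack = [], [node]
        while stack:
            nd = stack.pop()
            if not self.children[nd]:
                out.append(nd)
            stack.extend(self.children[nd])
        return out

    def mrca(self, leaf_names: list[str]) -> int:
        """Most recent common ancestor of the named leaves."""
        try:
            nodes = [self.leaf_index[n] for n in leaf_names]
        except KeyError as exc:
            raise TreeError(f"unknown leaf name {exc.args[0]!r}") from exc
        if not nodes:
            raise TreeError("mrca of an empty leaf set")
        paths = []
        for nd in nodes:
            path = [nd]
            while self.parent[path[-1]] >= 0:
                path.append(self.parent[path[-1]])
            paths.append(set(path))
        common = set.intersection(*paths)
        # deepest common ancestor
        return max(common, key=self.depth)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if not self.children[node]:
                body = self._names[node]
            else:
                body = "(" + ",".join(render(c) for c in self.children[node]) + ")"
            if self.parent[node] >= 0:
                return f"{body}:{self.branch_length[node]:.12g}"
            return body

        return render(self.root) + ";"

    def median_branch_length(self) -> float:
        nonroot = np.arange(self.n_nodes) != self.root
        return float(np.median(self.branch_length[nonroot]))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhylogeneticTree {self.n_leaves} leaves, {self.n_nodes} nodes>"


def parse_newick(text: str) -> PhylogeneticTree:
    """Parse a Newick string into a :class:`PhylogeneticTree`."""
    return PhylogeneticTree.from_newick(text)


def validate_tree(tree: PhylogeneticTree) -> TreeValidationReport:
    """Validate invariants and summarize the tree.

    The report includes the median branch length — the branch length at
    which per-model transition-probability summaries are evaluated by
    default.  Raises :class:`TreeError` on any invariant violation; never
    mutates the tree.
    """
    tree._validate_structure()
    nonroot = np.arange(tree.n_nodes) != tree.root
    bl = tree.branch_length[nonroot]
    max_depth = max(tree.depth(i) for i in tree.leaf_nodes)
    return TreeValidationReport(
        n_leaves=tree.n_leaves,
        n_internal=tree.n_nodes - tree.n_leaves,
        max_depth=max_depth,
        min_branch_length=float(bl.min()),
        max_branch_length=float(bl.max()),
        mean_branch_length=float(bl.mean()),
        median_branch_length=float(np.median(bl)),
    )
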