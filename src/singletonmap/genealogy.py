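"""Rooted binary genealogies with branch lengths.

A :class:`Genealogy` stores a coalescent tree in flat parent/length arrays:
nodes ``0..n-1`` are the labelled tips, nodes ``n..2n-2`` are internal nodes in
coalescence order, and the last node is the root.  This layout makes external
branch extraction and Poisson mutation dropping cheap, while Newick round
trips go through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:  # dendropy is only needed for Newick round trips
    import dendropy
except ImportError:  # pragma: no cover
    dendropy = None


class InvalidGenealogyError(ValueError):
    pass


@dataclass
class Genealogy:
    """Rooted binary tree over ``n`` labelled tips.

    Parameters
    ----------
    parent:
        Length ``2n-1`` integer array; ``parent[root] == -1``.
    length:
        Length ``2n-1`` array of branch lengths (branch above each node);
        ``length[root]`` is ignored and stored as 0.
    tip_labels:
        Labels of tips ``0..n-1``.
    units:
        Time units of the branch lengths: ``"coalescent"`` (units of 2N
        generations) or ``"generations"``.
    """

    parent: np.ndarray
    length: np.ndarray
    tip_labels: list[str]
    units: str = "coalescent"
    node_time: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=float)
        self.tip_labels = [str(t) for t in self.tip_labels]
        n = len(self.tip_labels)
        if n < 2:
            raise InvalidGenealogyError("need at least 2 tips")
        if len(set(self.tip_labels)) != n:
            raise InvalidGenealogyError("tip labels must be unique")
        if self.parent.shape != (2 * n - 1,) or self.length.shape != (2 * n - 1,):
            raise InvalidGenealogyError(
                f"expected arrays of length {2 * n - 1} for n={n} tips"
            )
        if (self.parent == -1).sum() != 1:
            raise InvalidGenealogyError("tree must have exactly one root")
        root = int(np.flatnonzero(self.parent == -1)[0])
        self.length[root] = 0.0
        if np.any(self.length < 0):
            raise InvalidGenealogyError("negative branch length")

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def external_branch_lengths(self) -> np.ndarray:
        """Branch lengths of the tip branches, ordered like ``tip_labels``."""
        return self.length[: self.n_tips].copy()

    def total_external_length(self) -> float:
        return float(self.length[: self.n_tips].sum())

    def total_length(self) -> float:
        return float(self.length.sum())

    def descendant_masks(self) -> np.ndarray:
        """Boolean matrix ``(2n-1, n)``: tips below each node.

        Relies on the child-before-parent node ordering produced by the
        simulators; falls back to a topological sweep otherwise.
        """
        n = self.n_tips
        masks = np.zeros((self.n_nodes, n), dtype=bool)
        masks[np.arange(n), np.arange(n)] = True
        nonroot = np.flatnonzero(self.parent >= 0)
        if np.all(self.parent[nonroot] > nonroot):
            order: np.ndarray = np.arange(self.n_nodes)
        else:
            order = np.argsort(self._depth_order())
        for v in order:
            p = self.parent[v]
            if p >= 0:
                masks[p] |= masks[v]
        return masks

    def _depth_order(self) -> np.ndarray:
        # depth from root; processing deepest-first guarantees children first
        depth = np.zeros(self.n_nodes, dtype=int)
        for v in range(self.n_nodes):
            d, u = 0, v
            while self.parent[u] >= 0:
                u = self.parent[u]
                d += 1
            depth[v] = -d
        return depth

    def rescale(self, factor: float, units: str | None = None) -> "Genealogy":
        return Genealogy(
            self.parent.copy(),
            self.length * factor,
            list(self.tip_labels),
            units or self.units,
        )

    # ------------------------------------------------------------------ #
    # Newick round trip                                                  #
    # ------------------------------------------------------------------ #
    def to_newick(self) -> str:
        n = self.n_nodes
        children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            if self.parent[v] >= 0:
                children[self.parent[v]].append(v)

        def fmt(v: int) -> str:
            if v < self.n_tips:
                return f"{self.tip_labels[v]}:{self.length[v]:.10g}"
            inner = ",".join(fmt(c) for c in children[v])
            if self.parent[v] < 0:
                return f"({inner})"
            return f"({inner}):{self.length[v]:.10g}"

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * n + 100))
        try:
            return fmt(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)

    @classmethod
    def from_newick(cls, newick: str, units: str = "coalescent") -> "Genealogy":
        if dendropy is None:  # pragma: no cover
            raise ImportError("dendropy is required for Newick parsing")
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree, units=units)

    @classmethod
    def from_dendropy(cls, tree, units: str = "coalescent") -> "Genealogy":
        nodes = list(tree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        n = len(tips)
        labels = []
        for nd in tips:
            if nd.taxon is None or nd.taxon.label is None:
                raise InvalidGenealogyError("unlabeled tip in Newick tree")
            labels.append(nd.taxon.label)
        internal = [nd for nd in nodes if not nd.is_leaf()]
        if len(internal) != n - 1:
            raise InvalidGenealogyError(
                f"tree is not strictly binary: {n} tips, {len(internal)} internal nodes"
            )
        index = {}
        for i, nd in enumerate(tips):
            index[id(nd)] = i
        # root last so that parent indices exist for every non-root node
        for i, nd in enumerate(reversed(internal)):
            index[id(nd)] = n + i
        parent = np.full(2 * n - 1, -1, dtype=np.int64)
        length = np.zeros(2 * n - 1, dtype=float)
        for nd in nodes:
            v = index[id(nd)]
            if nd.parent_node is not None:
                parent[v] = index[id(nd.parent_node)]
                bl = nd.edge.length
                if bl is None:
                    bl = 0.0
                if bl < 0:
                    raise InvalidGenealogyError("negative branch length in Newick")
                length[v] = bl
        return cls(parent, length, labels, units=units)
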