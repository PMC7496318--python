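"""Rooted ultrametric phylogenies as lightweight array-backed objects.

Newick parsing and serialisation are delegated to :mod:`dendropy`; the
in-memory representation used by the simulators and samplers is a flat
parent-pointer array, which keeps Brownian-motion recursions and MCMC
sweeps cheap.

Node indexing convention: tips occupy indices ``0 .. n_tips-1`` (in the
order of ``tip_labels``), internal nodes follow, and the root is the last
index (``2*n_tips - 2`` for a binary tree).  Every non-root node ``v``
carries the branch that connects it to its parent, so branches are
identified with their child node.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np

from .exceptions import InvalidArgumentError

__all__ = ["Phylogeny"]


class Phylogeny:
    """A rooted binary ultrametric tree with branch lengths in relative time.

    Parameters
    ----------
    parent : array of int
        ``parent[v]`` is the parent index of node ``v``; the root has -1.
    branch_length : array of float
        ``branch_length[v]`` is the length of the branch above node ``v``
        (ignored for the root).
    tip_labels : sequence of str
        Labels for nodes ``0 .. n_tips-1``.
    ultrametric_tol : float
        Maximum allowed spread of root-to-tip path lengths.
    """

    def __init__(self, parent, branch_length, tip_labels, ultrametric_tol=1e-6):
        self.parent = np.asarray(parent, dtype=int)
        self.branch_length = np.asarray(branch_length, dtype=float)
        self.tip_labels = list(tip_labels)
        self.n_tips = len(self.tip_labels)
        self.n_nodes = len(self.parent)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise InvalidArgumentError("tree must have exactly one root")
        self.root = int(roots[0])
        self._children = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                self._children[p].append(v)
        for v in range(self.n_tips):
            if self._children[v]:
                raise InvalidArgumentError(f"node {v} is labelled as a tip but has children")
        for v in range(self.n_tips, self.n_nodes):
            if len(self._children[v]) != 2 and not (v == self.root and len(self._children[v]) == 1):
                raise InvalidArgumentError("tree must be binary (a unary root is tolerated)")
        nonroot = np.arange(self.n_nodes) != self.root
        if np.any(self.branch_length[nonroot] <= 0):
            raise InvalidArgumentError("all branch lengths must be positive (zero-length branches rejected)")
        self._postorder = self._compute_postorder()
        depths = self.node_depths()
        tipd = depths[: self.n_tips]
        if tipd.max() - tipd.min() > ultrametric_tol:
            raise InvalidArgumentError(
                f"tree is not ultrametric within {ultrametric_tol:g}: "
                f"tip depth spread {tipd.max() - tipd.min():.3g}"
            )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, source, ultrametric_tol=1e-6):
        """Load a rooted tree from a Newick string or file path."""
        if "(" in str(source):
            dt = dendropy.Tree.get(data=str(source), schema="newick")
        else:
            dt = dendropy.Tree.get(path=str(source), schema="newick")
        nodes = list(dt.postorder_node_iter())
        tips = [n for n in nodes if n.is_leaf()]
        internals = [n for n in nodes if not n.is_leaf()]
        index = {}
        labels = []
        for i, n in enumerate(tips):
            index[n] = i
            labels.append(n.taxon.label if n.taxon is not None else f"tip{i}")
        for j, n in enumerate(internals):
            index[n] = len(tips) + j
        n_nodes = len(nodes)
        parent = np.full(n_nodes, -1, dtype=int)
        blen = np.zeros(n_nodes)
        for n in nodes:
            v = index[n]
            if n.parent_node is not None:
                parent[v] = index[n.parent_node]
                blen[v] = n.edge.length if n.edge.length is not None else 0.0
        return cls(parent, blen, labels, ultrametric_tol=ultrametric_tol)

    def to_newick(self):
        """Serialise to a Newick string (with branch lengths)."""

        def render(v):
            if v < self.n_tips:
                core = self.tip_labels[v]
            else:
                core = "(" + ",".join(render(c) for c in self._children[v]) + ")"
            if v == self.root:
                return core + ";"
            return f"{core}:{self.branch_length[v]:.10g}"

        return render(self.root)

    def write_newick(self, path):
        with io.open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- structure --------------------------------------------------------

    def children(self, v):
        return tuple(self._children[v])

    @property
    def branch_nodes(self):
        """Indices of all non-root nodes, i.e. one per branch."""
        return np.array([v for v in range(self.n_nodes) if v != self.root])

    @property
    def n_branches(self):
        return self.n_nodes - 1

    def _compute_postorder(self):
        order = []
        stack = [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done or v < self.n_tips:
                order.append(v)
            else:
                stack.append((v, True))
                for c in self._children[v]:
                    stack.append((c, False))
        return np.array(order)

    @property
    def postorder(self):
        """All node indices in postorder (children before parents)."""
        return self._postorder

    def preorder(self):
        return self._postorder[::-1]

    def node_depths(self):
        """Distance from the root to every node."""
        depth = np.zeros(self.n_nodes)
        for v in self._postorder[::-1]:
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.branch_length[v]
        return depth

    def depth(self):
        """Root-to-tip height of the (ultrametric) tree."""
        return float(self.node_depths()[: self.n_tips].max())

    def shared_path_matrix(self, rates=None):
        """Tip x tip matrix of (optionally rate-weighted) shared path lengths.

        Entry (i, j) is the summed ``t_b * r_b`` over branches on the path
        from the root to the most recent common ancestor of tips i and j;
        the diagonal is each tip's own weighted depth.  This is the Brownian
        covariance structure up to the trait rate.
        """
        w = self.branch_length.copy()
        if rates is not None:
            rates = np.asarray(rates, dtype=float)
            for i, v in enumerate(self.branch_nodes):
                w[v] = w[v] * rates[i]
        # weighted depth of every node
        depth = np.zeros(self.n_nodes)
        for v in self._postorder[::-1]:
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + w[v]
        # tips below each node
        below = [set() for _ in range(self.n_nodes)]
        for v in self._postorder:
            if v < self.n_tips:
                below[v].add(v)
            else:
                for c in self._children[v]:
                    below[v] |= below[c]
        C = np.zeros((self.n_tips, self.n_tips))
        for i in range(self.n_tips):
            C[i, i] = depth[i]
        for v in range(self.n_tips, self.n_nodes):
            a, b = self._children[v]
            for i in below[a]:
                for j in below[b]:
                    C[i, j] = C[j, i] = depth[v]
        return C

    def __repr__(self):
        return f"Phylogeny(n_tips={self.n_tips}, depth={self.depth():.4g})"
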