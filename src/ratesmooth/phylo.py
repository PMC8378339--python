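"""Indexed phylogeny, node heights, and the Brownian-motion covariance matrices.

A rooted, time-calibrated tree with branch lengths is the substrate for
everything in this package.  Tips are numbered ``1..n`` in Newick encounter
order and internal nodes ``n+1..n+m`` in preorder, so the root is always
``n+1``.  All matrices and output files follow that ordering.

Two covariance structures are built here:

* ``C`` — the n x n matrix whose (i, j) entry is the height above the root of
  the most recent common ancestor (MRCA) of tips i and j.  Under single-rate
  Brownian motion the tip trait covariance is ``sigma^2 * C``.
* ``C_ext`` — the same construction extended to the non-root internal nodes
  (dimension ``n + m - 1``); it is the covariance structure of node-level
  log-rates when the log-rate itself evolves by Brownian motion.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "parse_newick",
    "node_heights",
    "mrca_height_matrix",
    "extended_cov_matrix",
    "NewickError",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or violated tree invariants."""


@dataclass
class Phylogeny:
    """Rooted tree with positive branch lengths and deterministic indexing.

    Node ids are 1-based: tips ``1..n`` (Newick encounter order), internal
    nodes ``n+1..n+m`` (preorder), root ``n+1``.  Arrays indexed by node id
    have length ``n + m + 1`` with slot 0 unused.
    """

    n: int
    m: int
    tip_labels: list[str]
    parent: np.ndarray          # parent[id] -> parent id, 0 for the root
    edge_length: np.ndarray     # edge_length[id] -> length of edge above id, nan for root
    children: list[list[int]] = field(repr=False)

    @property
    def root_id(self) -> int:
        return self.n + 1

    @property
    def n_nodes(self) -> int:
        return self.n + self.m

    def preorder(self) -> list[int]:
        """Node ids, parents before children."""
        order: list[int] = []
        stack = [self.root_id]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def edges(self) -> list[tuple[int, int]]:
        """(parent, child) pairs in preorder of the child."""
        return [(self.parent[v], v) for v in self.preorder() if v != self.root_id]

    def ext_node_ids(self) -> list[int]:
        """Tips then non-root internal nodes — the row order of ``C_ext``."""
        return list(range(1, self.n + 1)) + list(range(self.n + 2, self.n + self.m + 1))

    def tip_index(self) -> dict[str, int]:
        return {lab: i + 1 for i, lab in enumerate(self.tip_labels)}

    def newick(self, annotations: dict[int, str] | None = None) -> str:
        """Serialize back to Newick.  ``annotations`` maps node id to a
        comment string inserted after the node (extended-Newick style)."""

        def render(v: int) -> str:
            if self.children[v]:
                inner = ",".join(render(c) for c in self.children[v])
                label = f"({inner})"
            else:
                label = _quote_label(self.tip_labels[v - 1])
            note = annotations.get(v, "") if annotations else ""
            if v == self.root_id:
                return f"{label}{note}"
            return f"{label}{note}:{self.edge_length[v]:.17g}"

        return render(self.root_id) + ";"


def _quote_label(label: str) -> str:
    if any(c in label for c in "(),:;[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_newick(text: str, collapse_zero: bool = False) -> Phylogeny:
    """Parse a rooted Newick string into an indexed :class:`Phylogeny`.

    Tips are indexed ``1..n`` in encounter order; internal nodes ``n+1..n+m``
    in preorder with the root first.  Branch lengths are required on every
    non-root edge and must be strictly positive — ``C_ext`` is singular
    otherwise.  With ``collapse_zero`` a zero-length *internal* edge is
    collapsed into a polytomy instead of rejected (zero-length terminal
    edges are always an error).  Polytomies are allowed (a basal polytomy is
    logged, not rejected).
    """
    if not text.strip():
        raise NewickError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises various DataError subclasses
        raise NewickError(f"malformed Newick: {exc}") from exc

    root = dtree.seed_node
    if len(root.child_nodes()) == 0:
        raise NewickError("tree has no tips")
    if collapse_zero:
        doomed = [
            nd for nd in dtree.preorder_node_iter()
            if nd.parent_node is not None and nd.child_nodes()
            and nd.edge.length is not None and nd.edge.length == 0
        ]
        for nd in doomed:
            p = nd.parent_node
            for c in list(nd.child_nodes()):
                nd.remove_child(c)
                p.add_child(c)
            p.remove_child(nd)
        if doomed:
            logger.info("collapsed %d zero-length internal edge(s)", len(doomed))
    if len(root.child_nodes()) > 2:
        logger.info("basal polytomy (%d children at the root)", len(root.child_nodes()))

    # number tips in encounter (preorder-leaf) order, internals in preorder
    tips: list[dendropy.Node] = []
    internals: list[dendropy.Node] = []
    for nd in dtree.preorder_node_iter():
        (internals if nd.child_nodes() else tips).append(nd)

    n, m = len(tips), len(internals)
    if n < 2:
        raise NewickError(f"need at least 2 tips, got {n}")

    tip_labels = []
    for nd in tips:
        if nd.taxon is None or nd.taxon.label is None:
            raise NewickError("tip without a label")
        tip_labels.append(nd.taxon.label)
    if len(set(tip_labels)) != n:
        dupes = sorted({x for x in tip_labels if tip_labels.count(x) > 1})
        raise NewickError(f"duplicate tip labels: {dupes}")

    ids: dict[int, int] = {}
    for i, nd in enumerate(tips):
        ids[id(nd)] = i + 1
    for j, nd in enumerate(internals):
        ids[id(nd)] = n + 1 + j

    parent = np.zeros(n + m + 1, dtype=np.int64)
    edge_length = np.full(n + m + 1, np.nan)
    children: list[list[int]] = [[] for _ in range(n + m + 1)]
    for nd in dtree.preorder_node_iter():
        v = ids[id(nd)]
        if nd.parent_node is None:
            continue
        if nd.edge.length is None:
            raise NewickError(f"missing branch length on edge above node {v}")
        if nd.edge.length <= 0:
            raise NewickError(
                f"non-positive branch length ({nd.edge.length}) above node {v}; "
                "collapse zero-length edges before analysis"
            )
        p = ids[id(nd.parent_node)]
        parent[v] = p
        edge_length[v] = nd.edge.length
        children[p].append(v)

    return Phylogeny(n=n, m=m, tip_labels=tip_labels, parent=parent,
                     edge_length=edge_length, children=children)


def node_heights(tree: Phylogeny) -> np.ndarray:
    """Height above the root for every node (array indexed by node id).

    The root sits at height 0; a child's height is its parent's height plus
    the connecting edge length.
    """
    h = np.zeros(tree.n_nodes + 1)
    for v in tree.preorder():
        if v != tree.root_id:
            h[v] = h[tree.parent[v]] + tree.edge_length[v]
    return h


def _mrca_table(tree: Phylogeny, node_ids: list[int]) -> np.ndarray:
    """MRCA id for every pair in ``node_ids`` (MRCA(u, u) = u).

    Quadratic root-path intersection; trees here are small (tens to a few
    hundred nodes) so this is never the bottleneck.
    """
    paths: dict[int, list[int]] = {}
    for v in node_ids:
        path = []
        u = v
        while u != 0:
            path.append(u)
            u = tree.parent[u]
        paths[v] = path[::-1]  # root first

    k = len(node_ids)
    out = np.zeros((k, k), dtype=np.int64)
    for a in range(k):
        pa = paths[node_ids[a]]
        out[a, a] = node_ids[a]
        for b in range(a + 1, k):
            pb = paths[node_ids[b]]
            mrca = tree.root_id
            for x, y in zip(pa, pb):
                if x != y:
                    break
                mrca = x
            out[a, b] = out[b, a] = mrca
    return out


def mrca_height_matrix(tree: Phylogeny) -> np.ndarray:
    """The n x n matrix ``C`` of MRCA heights for every pair of tips."""
    h = node_heights(tree)
    tips = list(range(1, tree.n + 1))
    return h[_mrca_table(tree, tips)]


def extended_cov_matrix(tree: Phylogeny) -> np.ndarray:
    """``C_ext``: MRCA heights over tips and non-root internal nodes.

    Dimension ``(n + m - 1)``, rows ordered tips ``1..n`` then internal nodes
    ``n+2..n+m``.  Positive definite only when every non-root node has height
    strictly above the root, which holds whenever branch lengths are positive.
    """
    h = node_heights(tree)
    ext = tree.ext_node_ids()
    for v in ext:
        if h[v] <= 0:
            raise ValueError(
                f"node {v} has height 0 above the root; C_ext would be singular "
                "(collapse zero-length edges first)"
            )
    return h[_mrca_table(tree, ext)]
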