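"""Phylogenetic tree utilities.

Trees are :class:`dendropy.Tree` objects (rooted, branch lengths in time
units).  This module provides Newick I/O plus the tree-derived quantities the
comparative analysis needs: patristic distances, the Brownian-motion
covariance of tip states, the Ornstein--Uhlenbeck (Martins--Hansen)
correlation structure, and Faith's phylogenetic diversity.

All matrix-valued functions return :class:`pandas.DataFrame` objects labelled
by tip name so they can be aligned with trait tables without positional
bookkeeping.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "read_newick",
    "parse_newick",
    "write_newick",
    "tip_labels",
    "patristic_distances",
    "bm_covariance",
    "ou_correlation",
    "faith_pd",
    "total_branch_length",
    "root_height",
    "scale_to_unit_height",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed into a valid tree."""


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree.

    Underscores in labels are preserved verbatim (not translated to spaces).
    Duplicate tip labels are rejected because tips index rows of trait
    tables and covariance matrices.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
    if dupes:
        raise NewickParseError(f"duplicate tip labels: {dupes}")
    return tree


def read_newick(path) -> dendropy.Tree:
    """Read a Newick file from *path*."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize *tree* as Newick; write to *path* if given, return the string."""
    text = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in the tree's leaf-iteration order (the canonical row order)."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _node_depths(tree: dendropy.Tree) -> dict:
    """Depth (sum of branch lengths from the root) of every node.

    A missing branch length anywhere except the root edge is an error;
    the root edge itself is ignored.
    """
    depths = {}
    root = tree.seed_node
    depths[id(root)] = 0.0
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        bl = node.edge.length
        if bl is None:
            raise ValueError(
                f"missing branch length on edge above "
                f"{node.taxon.label if node.taxon else 'an internal node'}"
            )
        depths[id(node)] = depths[id(node.parent_node)] + bl
    return depths


def _mrca_depth_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Matrix of most-recent-common-ancestor depths for all tip pairs.

    Entry (i, j) is the depth of MRCA(i, j); the diagonal holds tip depths.
    Runs in O(n^2) via a single postorder sweep, assigning each internal
    node's depth to all cross-child tip pairs.
    """
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    index = {id(leaf): k for k, leaf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = np.array([index[id(node)]], dtype=np.intp)
            continue
        groups = [below.pop(id(c)) for c in node.child_nodes()]
        d = depths[id(node)]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                V[np.ix_(groups[a], groups[b])] = d
                V[np.ix_(groups[b], groups[a])] = d
        below[id(node)] = np.concatenate(groups)
    tip_depth = np.array([depths[id(leaf)] for leaf in leaves])
    V[np.diag_indices(n)] = tip_depth
    return pd.DataFrame(V, index=labels, columns=labels)


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Pairwise patristic distances (sum of branch lengths on the tip-to-tip path)."""
    V = _mrca_depth_matrix(tree)
    depth = np.diag(V.to_numpy())
    D = depth[:, None] + depth[None, :] - 2.0 * V.to_numpy()
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)  # guard float round-off on near-zero branches
    return pd.DataFrame(D, index=V.index, columns=V.columns)


def bm_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Brownian-motion tip covariance: V_ij = depth of MRCA(i, j).

    Under a unit-rate Brownian walk from the root, the covariance between
    two tip states is the length of their shared root-to-MRCA path; the
    diagonal holds each tip's depth (root height on ultrametric trees).
    """
    return _mrca_depth_matrix(tree)


def ou_correlation(tree: dendropy.Tree, alpha: float) -> pd.DataFrame:
    """Ornstein--Uhlenbeck (Martins--Hansen) correlation: R_ij = exp(-alpha * d_ij).

    ``alpha`` is the selection strength (1/time); alpha = 0 degenerates to an
    all-ones matrix and large alpha approaches the identity.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {alpha}")
    D = patristic_distances(tree)
    R = np.exp(-alpha * D.to_numpy())
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=D.index, columns=D.columns)


def faith_pd(tree: dendropy.Tree, taxa: Iterable[str]) -> float:
    """Faith's phylogenetic diversity of a tip set, include-root convention.

    The sum of branch lengths of the minimal subtree connecting ``taxa``
    *and the root*, so a single taxon's PD equals its root-to-tip path
    length.  Monotone non-decreasing in the taxon set.
    """
    taxa = set(taxa)
    if not taxa:
        raise ValueError("taxon set is empty")
    leaf_by_label = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = sorted(taxa - leaf_by_label.keys())
    if missing:
        raise KeyError(f"taxa not found in tree: {missing}")
    marked: set[int] = set()
    root = tree.seed_node
    for label in taxa:
        node = leaf_by_label[label]
        while node is not root and id(node) not in marked:
            marked.add(id(node))
            node = node.parent_node
    total = 0.0
    for node in tree.preorder_node_iter():
        if id(node) in marked:
            total += node.edge.length or 0.0
    return total


def total_branch_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths (root edge excluded)."""
    return sum(
        node.edge.length or 0.0
        for node in tree.preorder_node_iter()
        if node is not tree.seed_node
    )


def root_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip depth (the tree height on ultrametric trees)."""
    depths = _node_depths(tree)
    return max(depths[id(leaf)] for leaf in tree.leaf_node_iter())


def scale_to_unit_height(tree: dendropy.Tree) -> dendropy.Tree:
    """Rescale branch lengths in place so the maximum tip depth is 1.

    Selection strengths (OU alpha, PWR bandwidths) are rate parameters per
    unit branch length, so fixing the height makes them comparable across
    trees of different depth.  Returns the tree for chaining.
    """
    h = root_height(tree)
    if h <= 0:
        raise ValueError("tree has zero height; cannot rescale")
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length /= h
    return tree
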