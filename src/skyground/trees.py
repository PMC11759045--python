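"""Phylogenetic tree utilities shared across modules.

Trees are ``dendropy.Tree`` objects throughout.  The helpers here extract
the numeric matrices the diversity and comparative machinery needs: tip
labels in a stable order, patristic (tip-to-tip path) distances, the
shared-path-length matrix that is the Brownian-motion covariance up to a
rate constant, and ultrametricity checks.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np

__all__ = [
    "tip_labels",
    "patristic_matrix",
    "shared_path_matrix",
    "root_to_tip_depths",
    "is_ultrametric",
    "root_age",
    "total_branch_length",
    "read_newick",
    "write_newick",
    "to_newick",
]


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Taxon labels of the leaves, in leaf-iteration order."""
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _leaf_index(tree: dendropy.Tree) -> dict[str, int]:
    return {lab: i for i, lab in enumerate(tip_labels(tree))}


def root_to_tip_depths(tree: dendropy.Tree) -> np.ndarray:
    """Path length from the root to every tip (leaf-iteration order)."""
    depths = []
    for lf in tree.leaf_node_iter():
        d = 0.0
        nd = lf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        depths.append(d)
    return np.asarray(depths, dtype=float)


def shared_path_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Matrix of shared root-to-MRCA path lengths between tips.

    Under Brownian motion with unit rate this is the covariance of tip
    states; the diagonal holds root-to-tip depths.
    """
    labels = tip_labels(tree)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n), dtype=float)

    # depth of every node, then for each internal node assign its depth as
    # the shared path of tip pairs straddling distinct child subtrees
    depth: dict[int, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depth[id(nd)] = 0.0
        else:
            depth[id(nd)] = depth[id(nd.parent_node)] + (nd.edge.length or 0.0)

    tips_below: dict[int, list[int]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            tips_below[id(nd)] = [idx[nd.taxon.label]]
        else:
            children = [tips_below[id(c)] for c in nd.child_nodes()]
            merged: list[int] = []
            for a_i, a in enumerate(children):
                for b in children[a_i + 1 :]:
                    for i in a:
                        for j in b:
                            C[i, j] = C[j, i] = depth[id(nd)]
                merged.extend(a)
            tips_below[id(nd)] = merged

    d = root_to_tip_depths(tree)
    np.fill_diagonal(C, d)
    return labels, C


def patristic_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Tip-to-tip path-length (patristic) distance matrix.

    Raises ``ValueError`` if any edge below the root lacks a length.
    """
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is None:
            raise ValueError("tree has missing branch lengths")
    labels, C = shared_path_matrix(tree)
    d = np.diag(C)
    # path(i,j) = depth(i) + depth(j) - 2 * shared(i,j)
    D = d[:, None] + d[None, :] - 2.0 * C
    np.fill_diagonal(D, 0.0)
    return labels, D


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-8) -> bool:
    d = root_to_tip_depths(tree)
    return bool(np.ptp(d) <= tol * max(1.0, float(np.max(d))))


def root_age(tree: dendropy.Tree) -> float:
    return float(np.max(root_to_tip_depths(tree)))


def total_branch_length(tree: dendropy.Tree) -> float:
    return float(
        sum(nd.edge.length or 0.0 for nd in tree.preorder_node_iter() if nd.parent_node is not None)
    )


def read_newick(path_or_text: str) -> dendropy.Tree:
    """Read a rooted Newick tree from a file path or a literal string."""
    text = path_or_text
    if not path_or_text.lstrip().startswith("("):
        with open(path_or_text) as fh:
            text = fh.read()
    return dendropy.Tree.get(data=text, schema="newick", rooting="default-rooted")


def to_newick(tree: dendropy.Tree) -> str:
    buf = io.StringIO()
    tree.write(file=buf, schema="newick", suppress_rooting=True)
    return buf.getvalue().strip()


def write_newick(tree: dendropy.Tree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
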