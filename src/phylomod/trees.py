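"""Rooted trees: Newick IO, p-distance neighbor joining, outgroup rooting.

Trees are `dendropy.Tree` objects throughout.  For real analyses the
reference gene tree is expected as curated input; the distance-based
builders here are a convenience backend for module trees and simulations.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np

__all__ = [
    "read_newick",
    "write_newick",
    "parse_newick",
    "to_newick",
    "pdistance_matrix",
    "nj_tree",
    "midpoint_root",
    "root_with_outgroup",
    "label_internal_nodes",
    "node_label",
    "leaf_labels",
]


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick string; duplicate leaf labels raise."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except dendropy.utility.error.DataParseError as exc:
        if "Multiple occurrences" in str(exc):
            raise ValueError(f"duplicate leaf labels: {exc}") from None
        raise ValueError(f"malformed newick: {exc}") from None
    labels = leaf_labels(tree)
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    return tree


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_label(node: dendropy.Node) -> str:
    """Stable node identifier: taxon label for leaves, node label otherwise."""
    if node.taxon is not None:
        return node.taxon.label
    if node.label is None:
        raise ValueError("internal node without label; "
                         "call label_internal_nodes first")
    return node.label


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "G") -> dendropy.Tree:
    """Assign preorder labels (G1, G2, ...) to unlabeled internal nodes."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.taxon is None:
            i += 1
            if node.label is None:
                node.label = f"{prefix}{i}"
    return tree


def pdistance_matrix(alignment: dict) -> tuple[list[str], np.ndarray]:
    """Proportion of mismatching positions between equal-length sequences.

    `alignment` maps id -> gapless sequence string.  Returns (ids, matrix)
    with matrix[i, j] = mismatches / length.
    """
    ids = list(alignment)
    seqs = [alignment[i] for i in ids]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have equal length")
    if length == 0:
        raise ValueError("empty alignment")
    arr = np.array([list(s) for s in seqs])
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(arr[i] != arr[j])
    return ids, d


def nj_tree(
    ids: list[str],
    matrix: np.ndarray,
    outgroup: list[str] = None,
) -> dendropy.Tree:
    """Neighbor joining on a symmetric distance matrix.

    The unrooted NJ tree is midpoint-rooted unless an outgroup is given.
    Additive matrices are reconstructed exactly (up to float rounding).
    Negative branch-length estimates are clamped to zero.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if matrix.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(matrix < 0):
        raise ValueError("distances must be non-negative")

    buf = io.StringIO()
    buf.write("," + ",".join(ids) + "\n")
    for i, name in enumerate(ids):
        buf.write(name + "," + ",".join(repr(float(x)) for x in matrix[i])
                  + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        buf, delimiter=",", is_allow_new_taxa=True
    )
    tree = pdm.nj_tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    if outgroup:
        tree = root_with_outgroup(tree, outgroup)
    else:
        tree = midpoint_root(tree)
    tree.is_rooted = True
    return tree


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    tree.reroot_at_midpoint(update_bipartitions=False)
    tree.is_rooted = True
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup_leaves) -> dendropy.Tree:
    """Root on the branch separating the outgroup clade from the ingroup.

    The outgroup must form one side of a split of the unrooted tree;
    otherwise the leaves breaking monophyly are reported.
    """
    outgroup = set(outgroup_leaves)
    labels = set(leaf_labels(tree))
    missing = outgroup - labels
    if missing:
        raise ValueError(f"outgroup leaves not in tree: {sorted(missing)}")
    ingroup = labels - outgroup
    if not ingroup:
        raise ValueError("outgroup cannot contain every leaf")

    # view the tree as unrooted from an ingroup leaf, then find the MRCA
    # of the outgroup; monophyly <=> its clade is exactly the outgroup
    anchor = sorted(ingroup)[0]
    work = tree.clone(depth=1)
    anchor_node = next(
        l for l in work.leaf_node_iter() if l.taxon.label == anchor
    )
    work.reroot_at_node(anchor_node.parent_node, update_bipartitions=False)
    taxa = [t for t in work.taxon_namespace if t.label in outgroup]
    mrca = work.mrca(taxa=taxa)
    clade = {l.taxon.label for l in mrca.leaf_iter()}
    if clade != outgroup:
        offenders = sorted(clade - outgroup)
        raise ValueError(
            f"outgroup is not monophyletic; clade also contains {offenders}"
        )
    length = mrca.edge.length or 0.0
    work.reroot_at_edge(mrca.edge, length1=length / 2.0,
                        length2=length / 2.0, update_bipartitions=False)
    # drop a possible degree-2 node left at the old root
    work.suppress_unifurcations()
    work.is_rooted = True
    return work
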