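"""Ancestral module composition on the gene tree.

Each gene-tree node n is assigned a module set Mn.  Two backends:

* Dollo parsimony — a module arises once, at the last common ancestor of
  its carrier leaves, and may be lost independently any number of times;
  the loss-minimising assignment puts the module at exactly the nodes
  lying on a path from that LCA down to some carrier.
* LCA mapping of module trees — every internal node of a module tree is
  mapped to the gene-tree LCA of the gene leaves below it; presence is
  closed along the gene-tree paths connecting the images of module-tree
  parent/child nodes.  This backend tolerates module trees whose topology
  conflicts with the gene tree.

Gains (Mn+) and losses (Mn-) are set differences against the parent node;
the root, having no parent, gains and loses nothing by convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import dendropy

from .trees import node_label

__all__ = [
    "ModulePresence",
    "presence_from_modules",
    "dollo_composition",
    "lca_composition",
    "composition_diff",
    "gains_losses",
    "write_composition_tsv",
    "write_gains_tsv",
]


@dataclass(frozen=True)
class ModulePresence:
    """Leaves of the gene tree carrying >= 1 segment of a module."""

    module_id: str
    carriers: frozenset

    def __post_init__(self):
        if not self.carriers:
            raise ValueError(f"module {self.module_id} has no carriers")


def presence_from_modules(modules) -> list[ModulePresence]:
    """Carrier sets from PLMA modules (multiple segments per leaf collapse)."""
    return [
        ModulePresence(m.id, frozenset(m.member_sequences)) for m in modules
    ]


def _leaf_map(tree: dendropy.Tree) -> dict:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def dollo_composition(tree: dendropy.Tree, presences) -> dict:
    """Dollo (single-gain, minimal-loss) module composition per node.

    Returns {node_label: set of module ids}.  A module is present at node
    n iff n descends from the LCA of its carriers and n's clade contains
    at least one carrier.
    """
    leaves = _leaf_map(tree)
    composition = {node_label(n): set() for n in tree.preorder_node_iter()}
    # per-node carrier counts via postorder, one pass per module
    for pres in presences:
        unknown = [c for c in pres.carriers if c not in leaves]
        if unknown:
            raise KeyError(
                f"module {pres.module_id}: carriers not in tree: "
                f"{sorted(unknown)}"
            )
        count: dict[int, int] = {}
        lca = None
        target = len(pres.carriers)
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                c = 1 if node.taxon.label in pres.carriers else 0
            else:
                c = sum(count[id(ch)] for ch in node.child_nodes())
            count[id(node)] = c
            if c == target and lca is None:
                lca = node
        # presence: below the LCA and above some carrier
        stack = [lca]
        while stack:
            node = stack.pop()
            if count[id(node)] == 0:
                continue
            composition[node_label(node)].add(pres.module_id)
            stack.extend(node.child_nodes())
    return composition


def lca_composition(
    tree: dendropy.Tree,
    module_trees: dict,
    segment_to_leaf: dict = None,
) -> dict:
    """Composition from per-module trees mapped onto the gene tree by LCA.

    `module_trees` maps module id -> rooted tree over that module's
    segments; `segment_to_leaf` maps segment leaf labels to gene-tree
    leaf labels (identity when omitted).
    """
    leaves = _leaf_map(tree)
    parent = {
        id(n): n.parent_node for n in tree.preorder_node_iter()
    }
    composition = {node_label(n): set() for n in tree.preorder_node_iter()}
    for module_id, mtree in module_trees.items():
        mapped = {}
        for v in mtree.postorder_node_iter():
            if v.is_leaf():
                seg = v.taxon.label
                gene = seg if segment_to_leaf is None else segment_to_leaf.get(seg, seg)
                if gene not in leaves:
                    raise KeyError(
                        f"module {module_id}: segment {seg!r} maps to "
                        f"unknown gene leaf {gene!r}"
                    )
                mapped[id(v)] = leaves[gene]
            else:
                children = [mapped[id(c)] for c in v.child_nodes()]
                mapped[id(v)] = _lca(tree, children)
        for v in mtree.preorder_node_iter():
            g = mapped[id(v)]
            composition[node_label(g)].add(module_id)
            if v.parent_node is not None:
                top = mapped[id(v.parent_node)]
                # close presence upward from g to its ancestor image
                walk = g
                while walk is not top and walk is not None:
                    composition[node_label(walk)].add(module_id)
                    walk = parent[id(walk)]
    return composition


def _lca(tree, nodes):
    if len(nodes) == 1:
        return nodes[0]
    ancestors = []
    for n in nodes:
        chain = []
        while n is not None:
            chain.append(n)
            n = n.parent_node
        ancestors.append(chain[::-1])
    lca = None
    for tier in zip(*ancestors):
        if all(t is tier[0] for t in tier):
            lca = tier[0]
        else:
            break
    return lca


def gains_losses(tree: dendropy.Tree, node_sets: dict) -> dict:
    """Per-node (gained, lost) sets relative to the parent node.

    The root has no parent: both sets are empty there and root content is
    never counted as a gain event.
    """
    out = {}
    for node in tree.preorder_node_iter():
        label = node_label(node)
        if node.parent_node is None:
            out[label] = (set(), set())
            continue
        own = node_sets[label]
        anc = node_sets[node_label(node.parent_node)]
        out[label] = (set(own) - set(anc), set(anc) - set(own))
    return out


# `composition_diff` is the module-flavoured name; traits reuse the same rule.
composition_diff = gains_losses


def write_composition_tsv(composition: dict, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["node_id", "module_ids"])
        for node in sorted(composition):
            writer.writerow([node, " ".join(sorted(composition[node]))])


def write_gains_tsv(diff: dict, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["node_id", "gained", "lost"])
        for node in sorted(diff):
            gained, lost = diff[node]
            writer.writerow(
                [node, " ".join(sorted(gained)), " ".join(sorted(lost))]
            )
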