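"""Synthetic gene families with planted modules and traits.

The generator emulates the statistical structure the detection pipeline
assumes: a gene family evolving on a species tree by duplication and
loss, conserved sequence modules gained at chosen gene-tree nodes and
inherited (with optional losses) by descendants as mutated copies of a
master motif planted into i.i.d. background sequence, and binary PPI
traits gained at chosen nodes — some coinciding with module gains.  The
full ground truth (per-node module and trait sets, gain nodes, planted
segments) is returned so every downstream stage can be scored.

Background residues are drawn i.i.d.; there is no indel process inside
modules (modules are gapless by definition), and module copies are
inserted in a shared left-to-right order across sequences so planted
configurations are alignment-consistent.  A ``shuffled_module_order``
mode breaks that order to exercise consistency rejection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import dendropy
import numpy as np

from .scoring import AMINO_ACIDS, ROBINSON_FREQUENCIES
from .seqprep import ProteinRecord
from .ancestral_traits import TraitTable, _transition
from .trees import label_internal_nodes, node_label, parse_newick, to_newick

__all__ = ["SimConfig", "GroundTruth", "SimResult", "simulate_family",
           "simulate_binary_trait"]


@dataclass
class SimConfig:
    seed: int = 0
    n_species: int = 16
    species_tree: Optional[str] = None       # newick; default balanced
    duplication_rate: float = 0.0            # gene birth-death on species tree
    gene_loss_rate: float = 0.0
    module_count: int = 6
    module_length_range: tuple = (8, 16)     # residues, within [5, 20]
    module_gain_nodes: Optional[list] = None  # node labels; default random
    module_loss_rate: float = 0.05           # per unit branch length
    #: expected pairwise substitution divergence between two planted copies
    #: of a module; each copy mutates from the master motif at half this
    #: rate, so two copies differ at ~`divergence` of their sites
    divergence: float = 0.10
    background_frequencies: Optional[dict] = None
    background_length: int = 100
    trait_count: int = 3
    trait_gain_nodes: Optional[list] = None
    coplaced_fraction: float = 1.0           # traits placed at module gains
    focal_species: Optional[list] = None     # None = all species annotated
    shuffled_module_order: bool = False

    def validate(self):
        if self.duplication_rate < 0 or self.gene_loss_rate < 0 \
                or self.module_loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if not (0 <= self.divergence < 1):
            raise ValueError("divergence must be in [0, 1)")
        lo, hi = self.module_length_range
        if not (5 <= lo <= hi <= 20):
            raise ValueError("module lengths must stay within [5, 20]")
        if not (0 <= self.coplaced_fraction <= 1):
            raise ValueError("coplaced_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    gene_tree: str                       # newick with internal labels
    node_modules: dict                   # node label -> sorted module list
    node_traits: dict
    module_gain_nodes: dict              # module id -> node label
    trait_gain_nodes: dict
    coappearance_nodes: list
    segments: dict                       # leaf -> {module: [start, end]}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimResult:
    records: list
    gene_tree: dendropy.Tree
    trait_table: TraitTable
    truth: GroundTruth


def _balanced_species_tree(n: int, rng) -> dendropy.Tree:
    """Balanced-as-possible binary tree over sp01..spNN, random lengths."""
    names = [f"sp{i + 1:02d}" for i in range(n)]

    def build(lo, hi):
        if hi - lo == 1:
            return names[lo]
        mid = (lo + hi + 1) // 2
        return f"({build(lo, mid)}:{rng.uniform(0.1, 0.5):.4f}," \
               f"{build(mid, hi)}:{rng.uniform(0.1, 0.5):.4f})"

    return parse_newick(build(0, n) + ";")


def _gene_tree_on_species(sp_tree, dup_rate, loss_rate, rng):
    """Gene birth-death along the species tree; returns a dendropy tree.

    Leaf labels are ``<species>_g<k>``.  With both rates at zero the gene
    tree mirrors the species tree with one gene copy per species.
    """
    counters: dict[str, int] = {}

    def descend(sp_node):
        """Subtree(s) for ONE gene copy entering the branch to sp_node."""
        length = sp_node.edge.length or 0.0
        if loss_rate > 0 and rng.random() > np.exp(-loss_rate * length):
            return None
        extra = rng.poisson(dup_rate * length) if dup_rate > 0 else 0
        copies = []
        for _ in range(extra + 1):
            sub = _resolve(sp_node)
            if sub is not None:
                copies.append(sub)
        if not copies:
            return None
        if len(copies) == 1:
            node = copies[0]
            node.edge.length = (node.edge.length or 0.0) + length
            return node
        dup = dendropy.Node()
        dup.edge.length = length
        for c in copies:
            dup.add_child(c)
        return dup

    def _resolve(sp_node):
        if sp_node.is_leaf():
            sp = sp_node.taxon.label
            counters[sp] = counters.get(sp, 0) + 1
            leaf = dendropy.Node()
            leaf.edge.length = 0.0
            leaf._gene_label = f"{sp}_g{counters[sp]}"
            return leaf
        children = [descend(c) for c in sp_node.child_nodes()]
        children = [c for c in children if c is not None]
        if not children:
            return None
        if len(children) == 1:
            return children[0]
        node = dendropy.Node()
        node.edge.length = 0.0
        for c in children:
            node.add_child(c)
        return node

    for _ in range(50):
        counters.clear()
        root = _resolve(sp_tree.seed_node)
        if root is not None and sum(1 for n in _iter_leaves(root)) >= 3:
            break
    else:
        raise RuntimeError("gene family went extinct in every attempt")

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.seed_node = root
    tree.is_rooted = True
    for leaf in _iter_leaves(root):
        taxon = taxon_namespace.new_taxon(leaf._gene_label)
        leaf.taxon = taxon
    return tree


def _iter_leaves(node):
    stack = [node]
    while stack:
        n = stack.pop()
        kids = n.child_nodes()
        if not kids:
            yield n
        stack.extend(kids)


def _mutate(motif_idx, divergence, freqs, rng):
    """Per-site substitution to a *different* residue with prob `divergence`."""
    out = motif_idx.copy()
    hit = rng.random(len(out)) < divergence
    for i in np.nonzero(hit)[0]:
        cur = out[i]
        probs = freqs.copy()
        probs[cur] = 0.0
        probs = probs / probs.sum()
        out[i] = rng.choice(len(freqs), p=probs)
    return out


def simulate_family(config: SimConfig) -> SimResult:
    """Generate a full synthetic dataset with ground truth.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    if config.species_tree:
        sp_tree = parse_newick(config.species_tree)
    else:
        sp_tree = _balanced_species_tree(config.n_species, rng)
    gene_tree = _gene_tree_on_species(
        sp_tree, config.duplication_rate, config.gene_loss_rate, rng
    )
    label_internal_nodes(gene_tree)
    nodes = {node_label(n): n for n in gene_tree.preorder_node_iter()}
    leaves = [l.taxon.label for l in gene_tree.leaf_node_iter()]
    root_label = node_label(gene_tree.seed_node)

    # --- module gain placement ------------------------------------------
    internal_nonroot = [
        lab for lab, n in nodes.items()
        if not n.is_leaf() and lab != root_label
        and sum(1 for _ in n.leaf_iter()) >= 2
    ]
    if config.module_gain_nodes is not None:
        gain_nodes = list(config.module_gain_nodes)
        if len(gain_nodes) != config.module_count:
            raise ValueError("need one gain node per module")
    else:
        replace = len(internal_nonroot) < config.module_count
        gain_nodes = list(
            rng.choice(internal_nonroot, size=config.module_count,
                       replace=replace)
        )

    # --- module presence with losses ------------------------------------
    module_ids = [f"M{i + 1}" for i in range(config.module_count)]
    node_modules = {lab: set() for lab in nodes}
    module_gain_map = {}
    for mid, glab in zip(module_ids, gain_nodes):
        gnode = nodes[glab]
        for _ in range(20):
            present = _propagate_with_losses(
                gnode, config.module_loss_rate, rng
            )
            carriers = [lab for lab in present if nodes[lab].is_leaf()]
            if len(carriers) >= 2:
                break
        for lab in present:
            node_modules[lab].add(mid)
        module_gain_map[mid] = str(glab)

    # --- motifs and sequences -------------------------------------------
    freq_map = config.background_frequencies or ROBINSON_FREQUENCIES
    freqs = np.array([freq_map[a] for a in AMINO_ACIDS], dtype=float)
    freqs = freqs / freqs.sum()
    lo, hi = config.module_length_range
    motif_len = rng.integers(lo, hi + 1, size=config.module_count)
    motifs = [
        rng.choice(len(freqs), p=freqs, size=int(l)) for l in motif_len
    ]

    n_slots = config.module_count + 1
    chunk = config.background_length // n_slots
    if chunk < 1:
        raise ValueError(
            "background too short to place all modules: "
            f"{config.background_length} residues for {n_slots} slots"
        )
    records = []
    segments = {}
    aa = np.array(list(AMINO_ACIDS))
    for leaf in leaves:
        carried = [i for i, mid in enumerate(module_ids)
                   if mid in node_modules[leaf]]
        order = list(carried)
        if config.shuffled_module_order:
            rng.shuffle(order)
        bg = rng.choice(len(freqs), p=freqs, size=config.background_length)
        parts = []
        segs = {}
        pos = 0
        cursor = 0
        for slot, midx in enumerate(order):
            parts.append(bg[cursor:cursor + chunk])
            pos += chunk
            cursor += chunk
            copy = _mutate(motifs[midx], config.divergence / 2.0, freqs, rng)
            segs[module_ids[midx]] = [pos, pos + len(copy)]
            parts.append(copy)
            pos += len(copy)
        parts.append(bg[cursor:])
        seq_idx = np.concatenate(parts) if parts else bg
        species = leaf.rsplit("_g", 1)[0]
        records.append(
            ProteinRecord(id=leaf, sequence="".join(aa[seq_idx]),
                          species=species)
        )
        segments[leaf] = segs

    # --- traits ----------------------------------------------------------
    trait_ids = [f"T{i + 1}" for i in range(config.trait_count)]
    if config.trait_gain_nodes is not None:
        trait_nodes = [str(x) for x in config.trait_gain_nodes]
        if len(trait_nodes) != config.trait_count:
            raise ValueError("need one gain node per trait")
    else:
        n_co = int(round(config.coplaced_fraction * config.trait_count))
        distinct_gains = sorted(set(module_gain_map.values()))
        co = list(rng.choice(distinct_gains,
                             size=min(n_co, len(distinct_gains)),
                             replace=len(distinct_gains) < n_co))
        others = [lab for lab in internal_nonroot if lab not in set(co)]
        extra_n = config.trait_count - len(co)
        extra = list(rng.choice(others, size=extra_n, replace=False)) \
            if extra_n else []
        trait_nodes = [str(x) for x in co + extra]

    node_traits = {lab: set() for lab in nodes}
    trait_gain_map = {}
    for tid, glab in zip(trait_ids, trait_nodes):
        for node in nodes[glab].preorder_iter():
            node_traits[node_label(node)].add(tid)
        trait_gain_map[tid] = glab

    focal = (
        set(config.focal_species)
        if config.focal_species is not None
        else {r.species for r in records}
    )
    status = {}
    for rec in records:
        for tid in trait_ids:
            if rec.species in focal:
                status[(rec.id, tid)] = (
                    "1" if tid in node_traits[rec.id] else "0"
                )
            else:
                status[(rec.id, tid)] = "?"
    trait_table = TraitTable(traits=trait_ids, status=status, leaves=leaves)

    coappear = sorted(
        set(module_gain_map.values()) & set(trait_gain_map.values())
    )
    truth = GroundTruth(
        gene_tree=to_newick(gene_tree),
        node_modules={k: sorted(v) for k, v in node_modules.items()},
        node_traits={k: sorted(v) for k, v in node_traits.items()},
        module_gain_nodes=module_gain_map,
        trait_gain_nodes=trait_gain_map,
        coappearance_nodes=coappear,
        segments=segments,
    )
    return SimResult(records=records, gene_tree=gene_tree,
                     trait_table=trait_table, truth=truth)


def _propagate_with_losses(gain_node, loss_rate, rng):
    """Node labels carrying the module: gain node's clade minus lost subtrees."""
    present = []
    stack = [(gain_node, True)]
    while stack:
        node, alive = stack.pop()
        if node is not gain_node and alive and loss_rate > 0:
            length = node.edge.length or 0.0
            if rng.random() > np.exp(-loss_rate * length):
                alive = False
        if alive:
            present.append(node_label(node))
        for child in node.child_nodes():
            stack.append((child, alive))
    return present


def simulate_binary_trait(tree, pi1: float, rate: float, seed: int):
    """Evolve one binary trait under the reconstruction model itself.

    Returns ``(leaf_states, node_states)`` as {label: 0/1}.  The root
    state is drawn from the stationary distribution.
    """
    rng = np.random.default_rng(seed)
    pi = np.array([1.0 - pi1, pi1])
    node_states = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state = int(rng.random() < pi1)
        else:
            parent_state = node_states[node_label(node.parent_node)]
            length = node.edge.length
            if length is None or length <= 0:
                length = 1e-6
            P = _transition(pi, rate, length)
            state = int(rng.random() < P[parent_state, 1])
        node_states[node_label(node)] = state
    leaf_states = {
        l.taxon.label: node_states[l.taxon.label]
        for l in tree.leaf_node_iter()
    }
    return leaf_states, node_states
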