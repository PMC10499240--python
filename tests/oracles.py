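"""Independent brute-force reference implementations used by the tests.

Everything here favours transparency over speed and is deliberately
written from first principles, not by calling the code under test.
"""

from __future__ import annotations

import itertools

import numpy as np

from phylomod.trees import node_label


# -- interval grouping ---------------------------------------------------


def connected_interval_components(intervals):
    """Connected components of the >=1-base overlap graph, by edge listing.

    `intervals` is a list of (start, end) half-open pairs; returns a list
    of frozensets of indices.
    """
    n = len(intervals)
    adjacency = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            si, ei = intervals[i]
            sj, ej = intervals[j]
            if si < ej and sj < ei:
                adjacency[i].add(j)
                adjacency[j].add(i)
    seen = set()
    components = []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adjacency[k] - comp)
        seen |= comp
        components.append(frozenset(comp))
    return components


# -- diagonal enumeration ------------------------------------------------


def enumerate_diagonals_bruteforce(seq_a, seq_b, ids, scoring, max_length,
                                   threshold):
    """All (i, j, l) windows filtered and selected by the same rules.

    Returns tuples (id_a, id_b, i, j, l, score, weight) after per-offset
    greedy weight-maximal non-overlapping selection.
    """
    ia = scoring.encode(seq_a)
    ib = scoring.encode(seq_b)
    la, lb = len(ia), len(ib)
    candidates = []
    for i in range(la):
        for j in range(lb):
            for l in range(1, max_length + 1):
                if i + l > la or j + l > lb:
                    break
                score = int(scoring.score[ia[i:i + l], ib[j:j + l]].sum())
                w = scoring.corrected_weight(l, score, la, lb)
                if w >= threshold:
                    candidates.append((i - j, i, l, score, w))
    kept = []
    by_offset = {}
    for c in candidates:
        by_offset.setdefault(c[0], []).append(c)
    for offset in sorted(by_offset):
        group = sorted(by_offset[offset], key=lambda c: (-c[4], -c[2], c[1]))
        chosen = []
        for c in group:
            _, start, length, _score, _w = c
            if not any(start < cs + cl and cs < start + length
                       for (_, cs, cl, _s2, _w2) in chosen):
                chosen.append(c)
        kept.extend(chosen)
    return {
        (ids[0], ids[1], i, i - off, l, s, round(w, 9))
        for off, i, l, s, w in kept
    }


# -- blocks --------------------------------------------------------------


def blocks_bruteforce(plma):
    """Maximal runs of consecutive identical-membership classes.

    Re-derived from the class partition by pure set arithmetic: a run is
    extended while shifting every member position by +1 lands in a single
    class with exactly the same (seq, pos+1) member set.
    """
    classes = {
        cid: frozenset(members.items())
        for cid, members in plma.classes().items()
    }
    by_members = {members: cid for cid, members in classes.items()}

    def shifted(members, delta):
        return frozenset((s, p + delta) for s, p in members)

    blocks = set()
    for members in classes.values():
        if shifted(members, -1) in by_members:
            continue  # not a run start
        chain = [members]
        while shifted(chain[-1], +1) in by_members:
            chain.append(shifted(chain[-1], +1))
        length = len(chain)
        segments = tuple(sorted(
            (plma.seq_ids[s], p, length) for s, p in chain[0]
        ))
        blocks.add(segments)
    return blocks


def assert_block_alignment_property(plma, blocks):
    """Each segment aligns, column by column, to all and only the block."""
    for block in blocks:
        for col in range(block.length):
            expected = {
                seq_id: start + col for seq_id, start, _l in block.segments
            }
            for seq_id, start, _l in block.segments:
                aligned = plma.aligned_positions(seq_id, start + col)
                assert aligned == expected, (
                    f"block {block.id} column {col}: {aligned} != {expected}"
                )


# -- Dollo ---------------------------------------------------------------


def dollo_optima_bruteforce(tree, carriers):
    """All minimum-loss single-gain presence sets for one module.

    Enumerates every choice of gain node and every 'top-connected' node
    subset of its clade whose leaves are exactly the carriers; a loss is
    an edge from a present node to an absent child.
    """
    nodes = list(tree.preorder_node_iter())
    best_cost = None
    optima = []
    for top in nodes:
        clade = list(top.preorder_iter())
        index = {id(n): k for k, n in enumerate(clade)}
        m = len(clade)
        for bits in range(1 << m):
            if not bits & 1:  # top itself must be present
                continue
            chosen = [clade[k] for k in range(m) if bits >> k & 1]
            chosen_ids = {id(n) for n in chosen}
            ok = all(
                n is top or id(n.parent_node) in chosen_ids for n in chosen
            )
            if not ok:
                continue
            leaf_set = {
                n.taxon.label for n in chosen if n.is_leaf()
            }
            if leaf_set != set(carriers):
                continue
            losses = sum(
                1 for n in chosen for c in n.child_nodes()
                if id(c) not in chosen_ids
            )
            labels = frozenset(node_label(n) for n in chosen)
            if best_cost is None or losses < best_cost:
                best_cost = losses
                optima = [labels]
            elif losses == best_cost and labels not in optima:
                optima.append(labels)
    return best_cost, optima


# -- binary trait likelihood --------------------------------------------


def trait_likelihood_bruteforce(tree, states, pi1, rate):
    """Joint summation over every unobserved node state.

    Returns (total likelihood, {node label: P(state=1 | data)}).
    """
    pi = np.array([1.0 - pi1, pi1])

    def transition(t):
        e = np.exp(-rate * t)
        return np.array([
            [pi[0] + pi[1] * e, pi[1] * (1 - e)],
            [pi[0] * (1 - e), pi[1] + pi[0] * e],
        ])

    nodes = list(tree.preorder_node_iter())
    free = [
        n for n in nodes
        if not n.is_leaf() or states[n.taxon.label] is None
    ]
    total = 0.0
    post1 = {node_label(n): 0.0 for n in nodes}
    for combo in itertools.product([0, 1], repeat=len(free)):
        assign = {}
        for n, s in zip(free, combo):
            assign[id(n)] = s
        for n in nodes:
            if n.is_leaf() and states[n.taxon.label] is not None:
                assign[id(n)] = states[n.taxon.label]
        like = pi[assign[id(tree.seed_node)]]
        for n in nodes:
            if n.parent_node is None:
                continue
            length = n.edge.length
            if length is None or length <= 0:
                length = 1e-6
            P = transition(length)
            like *= P[assign[id(n.parent_node)], assign[id(n)]]
        total += like
        for n in nodes:
            if assign[id(n)] == 1:
                post1[node_label(n)] += like
    return total, {k: v / total for k, v in post1.items()}


# -- random additive trees ----------------------------------------------


def random_tree_newick(n_leaves, rng):
    """Random rooted binary tree with uniform branch lengths in [0.1, 1]."""
    parts = [f"T{i}" for i in range(n_leaves)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(
            f"({a}:{rng.uniform(0.1, 1.0):.6f},"
            f"{b}:{rng.uniform(0.1, 1.0):.6f})"
        )
    return parts[0] + ";"


def patristic_distances(tree):
    """Leaf-to-leaf path-length matrix computed by root-path walking."""
    leaves = list(tree.leaf_node_iter())
    paths = {}
    for leaf in leaves:
        dist = {}
        node, acc = leaf, 0.0
        while node is not None:
            dist[id(node)] = acc
            acc += node.edge.length or 0.0
            node = node.parent_node
        paths[leaf.taxon.label] = dist
    labels = sorted(paths)
    out = {}
    for a in labels:
        for b in labels:
            if a >= b:
                continue
            da, db = paths[a], paths[b]
            best = min(
                da[k] + db[k] for k in da.keys() & db.keys()
            )
            out[(a, b)] = best
    return out
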