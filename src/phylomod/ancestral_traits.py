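"""Ancestral binary trait reconstruction on the gene tree.

Traits are protein–protein interactions (PPIs) of the gene family's
proteins with fixed partner proteins, observed only in a focal species
(statuses 1 = able to interact, 0 = not able, ? = missing annotation).
Ancestral states are reconstructed per trait under a two-state
continuous-time Markov model with stationary frequencies (pi0, pi1) and
overall substitution intensity mu (an F81-type model):

    P(i -> j | t) = pi_j + (delta_ij - pi_j) * exp(-mu * t)

Parameters are fitted by maximising the pruning likelihood; per-node
marginal posteriors come from the standard up/down (inside/outside) pass,
and states are called with the MPPA decision rule: the subset of states
(the best state alone, or both) that minimises the Brier distance to the
marginal posteriors.  For two states the best state is called alone iff
its posterior exceeds 3/4; otherwise the node is left ambiguous ({0, 1}).
Ambiguous nodes are excluded from In (the set of traits called present),
keeping gain events conservative.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

import dendropy

from .trees import node_label
from .ancestral_modules import gains_losses as trait_diff  # same set rule

__all__ = [
    "TraitTable",
    "annotate_leaves",
    "TraitReconstruction",
    "ancestral_binary_ml",
    "reconstruct_traits",
    "trait_diff",
]

MIN_BRANCH_LENGTH = 1e-6

STATUS_SYMBOLS = ("0", "1", "?")


@dataclass
class TraitTable:
    """Leaf-by-trait status table over the alphabet {1, 0, ?}."""

    traits: list[str]
    status: dict  # (leaf_id, trait_id) -> "0" | "1" | "?"
    leaves: list[str] = field(default_factory=list)

    def __post_init__(self):
        for key, value in self.status.items():
            if value not in STATUS_SYMBOLS:
                raise ValueError(f"bad status {value!r} for {key}")

    def column(self, trait: str) -> dict:
        """{leaf: 0/1/None} for one trait; absent rows default to ?."""
        out = {}
        for leaf in self.leaves:
            s = self.status.get((leaf, trait), "?")
            out[leaf] = None if s == "?" else int(s)
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["leaf_id", "trait_id", "status"])
            for leaf in self.leaves:
                for trait in self.traits:
                    writer.writerow(
                        [leaf, trait, self.status.get((leaf, trait), "?")]
                    )

    @classmethod
    def from_tsv(cls, path, leaves=None) -> "TraitTable":
        status = {}
        traits, seen_leaves = [], []
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header != ["leaf_id", "trait_id", "status"]:
                raise ValueError(f"unexpected trait TSV header in {path}")
            for leaf, trait, s in reader:
                status[(leaf, trait)] = s
                if trait not in traits:
                    traits.append(trait)
                if leaf not in seen_leaves:
                    seen_leaves.append(leaf)
        return cls(traits=traits, status=status,
                   leaves=list(leaves) if leaves else seen_leaves)


def annotate_leaves(
    ppi_pairs,
    focal_leaves,
    all_partners,
    all_leaves,
) -> tuple[TraitTable, list[str]]:
    """Build the leaf status table from observed focal-species PPIs.

    `ppi_pairs` is an iterable of (leaf_id, partner_id) interactions
    observed in the focal species.  Focal leaves get status 1 for listed
    partners and 0 for every other partner; all other leaves get ?.
    Partners in the pair list but absent from `all_partners` are appended
    to the trait universe and returned for logging.
    """
    focal = set(focal_leaves)
    leaves = list(all_leaves)
    leaf_set = set(leaves)
    traits = list(all_partners)
    known = set(traits)
    added = []
    observed = set()
    for leaf, partner in ppi_pairs:
        if leaf not in leaf_set:
            raise KeyError(f"PPI table references unknown leaf {leaf!r}")
        if partner not in known:
            known.add(partner)
            traits.append(partner)
            added.append(partner)
        observed.add((leaf, partner))
    status = {}
    for leaf in leaves:
        for trait in traits:
            if leaf in focal:
                status[(leaf, trait)] = "1" if (leaf, trait) in observed else "0"
            else:
                status[(leaf, trait)] = "?"
    return TraitTable(traits=traits, status=status, leaves=leaves), added


@dataclass
class TraitReconstruction:
    """Fitted model and per-node marginal posteriors for one trait."""

    trait: str
    pi1: float
    rate: float
    log_likelihood: float
    posterior1: dict          # node label -> P(state = 1)
    calls: dict               # node label -> frozenset of called states
    single_carrier: bool = False

    def present_nodes(self) -> set:
        """Nodes whose call is unambiguously {1}."""
        return {n for n, c in self.calls.items() if c == frozenset({1})}


def _edge_length(node) -> float:
    length = node.edge.length
    if length is None or length <= 0:
        return MIN_BRANCH_LENGTH
    return float(length)


def _transition(pi: np.ndarray, mu: float, t: float) -> np.ndarray:
    e = np.exp(-mu * t)
    return np.array(
        [
            [pi[0] + pi[1] * e, pi[1] * (1.0 - e)],
            [pi[0] * (1.0 - e), pi[1] + pi[0] * e],
        ]
    )


def _pruning_up(tree, states, pi, mu):
    """Partial likelihoods L_n(k) = P(observed leaves below n | state k)."""
    partial = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states[node.taxon.label]
            if s is None:
                vec = np.ones(2)
            else:
                vec = np.zeros(2)
                vec[s] = 1.0
            partial[id(node)] = vec
        else:
            vec = np.ones(2)
            for child in node.child_nodes():
                P = _transition(pi, mu, _edge_length(child))
                vec = vec * (P @ partial[id(child)])
            partial[id(node)] = vec
    return partial


def _log_likelihood(tree, states, pi, mu) -> float:
    partial = _pruning_up(tree, states, pi, mu)
    root = tree.seed_node
    like = float(pi @ partial[id(root)])
    return -np.inf if like <= 0 else float(np.log(like))


def ancestral_binary_ml(
    tree: dendropy.Tree,
    states: dict,
    pi1: float = None,
    rate: float = None,
    trait: str = "trait",
) -> TraitReconstruction:
    """Marginal ML ancestral reconstruction of one binary trait.

    `states` maps every leaf label to 0, 1, or None (missing).  Stationary
    frequency pi1 and intensity `rate` are estimated by coordinate-wise
    bounded likelihood maximisation unless fixed by the caller.  Observed
    leaves keep their state (posterior 0 or 1 exactly).
    """
    leaf_ids = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = [l for l in leaf_ids if l not in states]
    if missing:
        raise KeyError(f"no state for leaves: {sorted(missing)}")
    observed = [states[l] for l in leaf_ids if states[l] is not None]
    if not observed:
        raise ValueError("trait unobserved: every leaf status is '?'")

    fit_pi = pi1 is None
    fit_rate = rate is None
    if fit_pi:
        p = np.mean(observed)
        pi1 = min(max(p, 1e-3), 1.0 - 1e-3)
    if fit_rate:
        rate = 1.0

    def nll(pi1_, rate_):
        return -_log_likelihood(tree, states, np.array([1 - pi1_, pi1_]), rate_)

    if fit_pi or fit_rate:
        for _ in range(4):  # coordinate ascent with bounded 1-D optimisers
            if fit_pi:
                res = minimize_scalar(
                    lambda p_: nll(p_, rate), bounds=(1e-6, 1 - 1e-6),
                    method="bounded",
                )
                pi1 = float(res.x)
            if fit_rate:
                res = minimize_scalar(
                    lambda r_: nll(pi1, np.exp(r_)),
                    bounds=(np.log(1e-4), np.log(1e3)), method="bounded",
                )
                rate = float(np.exp(res.x))

    pi = np.array([1.0 - pi1, pi1])
    partial = _pruning_up(tree, states, pi, rate)
    loglik = _log_likelihood(tree, states, pi, rate)

    # outside pass for marginal posteriors
    outside = {id(tree.seed_node): pi.copy()}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            sib = np.ones(2)
            for other in node.child_nodes():
                if other is not child:
                    P = _transition(pi, rate, _edge_length(other))
                    sib = sib * (P @ partial[id(other)])
            above = outside[id(node)] * sib
            P = _transition(pi, rate, _edge_length(child))
            outside[id(child)] = above @ P

    posterior1, calls = {}, {}
    for node in tree.preorder_node_iter():
        label = node_label(node)
        joint = outside[id(node)] * partial[id(node)]
        total = joint.sum()
        p1 = float(joint[1] / total)
        if node.is_leaf() and states[node.taxon.label] is not None:
            p1 = float(states[node.taxon.label])
        posterior1[label] = p1
        calls[label] = _mppa_call(p1)

    return TraitReconstruction(
        trait=trait, pi1=float(pi1), rate=float(rate),
        log_likelihood=loglik, posterior1=posterior1, calls=calls,
        single_carrier=(sum(observed) == 1),
    )


def _mppa_call(p1: float, tol: float = 1e-9) -> frozenset:
    """Brier-optimal state set (MPPA).

    Among candidate sets S (the top-k states), pick the one minimising
    the squared distance between the marginal posteriors and the flat
    prediction 1/|S| over S.  For two states this keeps the best state
    alone iff its posterior exceeds 3/4 and prefers the smaller set on
    ties; nodes left ambiguous ({0, 1}) never enter In.
    """
    best = max(p1, 1.0 - p1)
    if best >= 0.75 - tol:
        return frozenset({1}) if p1 >= 0.5 else frozenset({0})
    return frozenset({0, 1})


def reconstruct_traits(
    tree: dendropy.Tree,
    table: TraitTable,
    pi1: float = None,
    rate: float = None,
) -> tuple[dict, dict]:
    """Reconstruct every trait; returns (In map, reconstructions).

    In maps node label -> set of traits called unambiguously present.
    """
    in_map = {node_label(n): set() for n in tree.preorder_node_iter()}
    recons = {}
    for trait in table.traits:
        rec = ancestral_binary_ml(
            tree, table.column(trait), pi1=pi1, rate=rate, trait=trait
        )
        recons[trait] = rec
        for node in rec.present_nodes():
            in_map[node].add(trait)
    return in_map, recons


def write_posteriors_tsv(recons: dict, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["trait_id", "node_id", "posterior_1", "call"])
        for trait in sorted(recons):
            rec = recons[trait]
            for node in sorted(rec.posterior1):
                call = "".join(str(s) for s in sorted(rec.calls[node]))
                writer.writerow(
                    [trait, node, f"{rec.posterior1[node]:.6g}", call]
                )
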