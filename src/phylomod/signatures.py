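"""Module–PPI co-appearance events (candidate functional signatures).

A node of the gene tree where both a module and a PPI are gained relative
to the parent is a co-appearance event: the gained modules Mn+ form the
candidate sequence signature of the gained interactions In+.  A packaged
reference catalogue of 45 such events, curated for the ADAMTS-TSL family
across nine species, ships with the package for worked examples and as a
statistics fixture.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "Signature",
    "detect_coappearances",
    "signature_stats",
    "load_adamts_signatures",
    "write_signatures_tsv",
]


@dataclass(frozen=True)
class Signature:
    """One co-appearance event: a node gaining both modules and PPIs."""

    node: str
    gained_ppis: tuple
    gained_modules: tuple
    descendants: str = ""
    is_paralog_ancestor: bool = False

    def __post_init__(self):
        if not self.gained_ppis or not self.gained_modules:
            raise ValueError(
                f"signature at {self.node} needs both gained PPIs and modules"
            )


def detect_coappearances(
    tree, module_gains: dict, trait_gains: dict, duplication_nodes=None
):
    """Nodes where Mn+ and In+ are both non-empty.

    `module_gains` / `trait_gains` map node label -> (gained, lost).
    Returns ``(signatures, ppi_only_nodes)``; the second list holds nodes
    with a PPI gain but no module gain.  Output is sorted by node label
    and independent of input enumeration order.
    """
    from .trees import node_label

    duplication_nodes = set(duplication_nodes or ())
    signatures = []
    ppi_only = []
    for node in tree.preorder_node_iter():
        label = node_label(node)
        m_plus = module_gains.get(label, (set(), set()))[0]
        i_plus = trait_gains.get(label, (set(), set()))[0]
        if i_plus and m_plus:
            signatures.append(
                Signature(
                    node=label,
                    gained_ppis=tuple(sorted(i_plus)),
                    gained_modules=tuple(sorted(m_plus)),
                    is_paralog_ancestor=label in duplication_nodes,
                )
            )
        elif i_plus:
            ppi_only.append(label)
    signatures.sort(key=lambda s: s.node)
    ppi_only.sort()
    return signatures, ppi_only


def signature_stats(signatures) -> dict:
    """Exact summary counts over a signature list."""
    sigs = list(signatures)
    if not sigs:
        return {
            "n_events": 0,
            "min_modules": 0, "max_modules": 0,
            "min_ppis": 0, "max_ppis": 0,
            "total_module_entries": 0, "total_ppi_entries": 0,
            "distinct_modules": 0, "distinct_ppis": 0,
        }
    n_modules = [len(s.gained_modules) for s in sigs]
    n_ppis = [len(s.gained_ppis) for s in sigs]
    return {
        "n_events": len(sigs),
        "min_modules": min(n_modules), "max_modules": max(n_modules),
        "min_ppis": min(n_ppis), "max_ppis": max(n_ppis),
        "total_module_entries": sum(n_modules),
        "total_ppi_entries": sum(n_ppis),
        "distinct_modules": len({m for s in sigs for m in s.gained_modules}),
        "distinct_ppis": len({p for s in sigs for p in s.gained_ppis}),
    }


def load_adamts_signatures() -> list[Signature]:
    """The packaged ADAMTS-TSL co-appearance catalogue (45 events).

    Each row lists an ancestral gene node, its descendant paralogs, the
    PPIs gained there and the module signature (whitespace-separated
    ids).  Nodes ancestral to two or more paralog lineages are flagged.
    """
    path = resources.files("phylomod.data") / "adamts_coappearance_events.tsv"
    signatures = []
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != ["node", "paralog_ancestor", "descendants", "ppis",
                      "modules"]:
            raise ValueError("malformed co-appearance catalogue header")
        for row in reader:
            if len(row) != 5:
                raise ValueError(f"malformed catalogue row: {row!r}")
            node, flag, descendants, ppis, modules = row
            signatures.append(
                Signature(
                    node=node,
                    descendants=descendants,
                    gained_ppis=tuple(ppis.split()),
                    gained_modules=tuple(modules.split()),
                    is_paralog_ancestor=flag == "1",
                )
            )
    return signatures


def write_signatures_tsv(signatures, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["node", "paralog_ancestor", "descendants", "ppis", "modules"]
        )
        for s in signatures:
            writer.writerow(
                [s.node, int(s.is_paralog_ancestor), s.descendants,
                 " ".join(s.gained_ppis), " ".join(s.gained_modules)]
            )


def write_stats_json(stats: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
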