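"""iTOL (Interactive Tree Of Life) annotation export.

Emits plain-text dataset files conforming to the iTOL dataset grammar
(SEPARATOR / DATASET_LABEL / COLOR headers followed by a DATA section):

* ``DATASET_BINARY`` — per-leaf presence/absence of selected modules;
* ``DATASET_DOMAINS`` — module segments drawn as coloured shapes along
  each sequence;
* a plain text annotation marking the modules gained at each node.

Module colours are assigned by a stable hash of the module id so reruns
colour identically.  A small reader parses the emitted files back for
round-trip checks.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

from .trees import node_label, write_newick

__all__ = ["module_color", "export_itol", "read_itol_dataset"]

_SHAPES = ["RE", "HH", "HV", "EL", "DI", "TR", "TL", "PL", "PR", "PU", "PD",
           "OC", "GP"]


def module_color(module_id: str) -> str:
    """Deterministic #RRGGBB colour from the module id."""
    digest = hashlib.sha256(module_id.encode()).digest()
    # keep colours mid-range so shapes stay visible on white
    r, g, b = (64 + d % 160 for d in digest[:3])
    return f"#{r:02x}{g:02x}{b:02x}"


def _module_shape(module_id: str) -> str:
    digest = hashlib.sha256(module_id.encode()).digest()
    return _SHAPES[digest[3] % len(_SHAPES)]


def export_itol(
    tree,
    modules,
    gains: dict,
    signatures,
    outdir,
    sequence_lengths: dict = None,
    selected_modules: list = None,
) -> dict:
    """Write the tree plus iTOL datasets; returns {name: path}.

    `modules` are PLMA modules (segments give DATASET_DOMAINS shapes);
    `gains` maps node label -> (gained, lost) module sets; `signatures`
    mark co-appearance nodes.  `sequence_lengths` maps leaf id -> length
    (required for DATASET_DOMAINS; inferred as max segment end otherwise).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    leaf_ids = {l.taxon.label for l in tree.leaf_node_iter()}
    node_ids = {node_label(n) for n in tree.preorder_node_iter()}
    for label in gains:
        if label not in node_ids:
            raise KeyError(f"gain annotation for unknown node {label!r}")

    paths = {}
    tree_path = outdir / "tree.nwk"
    write_newick(tree, tree_path)
    paths["tree"] = tree_path

    mods = list(modules)
    if selected_modules is not None:
        chosen = [m for m in mods if m.id in set(selected_modules)]
    else:
        chosen = mods

    # ---- DATASET_BINARY: module presence per leaf ----------------------
    binary_path = outdir / "dataset_binary_modules.txt"
    with open(binary_path, "w") as fh:
        fh.write("DATASET_BINARY\n")
        fh.write("SEPARATOR COMMA\n")
        fh.write("DATASET_LABEL,Module presence\n")
        fh.write("COLOR,#3b6fb6\n")
        fh.write("FIELD_SHAPES," + ",".join("1" for _ in chosen) + "\n")
        fh.write("FIELD_LABELS," + ",".join(m.id for m in chosen) + "\n")
        fh.write("FIELD_COLORS," + ",".join(module_color(m.id) for m in chosen)
                 + "\n")
        fh.write("DATA\n")
        carriers = {m.id: m.member_sequences for m in chosen}
        for leaf in sorted(leaf_ids):
            flags = [
                "1" if leaf in carriers[m.id] else "0" for m in chosen
            ]
            if any(f == "1" for f in flags):
                fh.write(leaf + "," + ",".join(flags) + "\n")
    paths["binary"] = binary_path

    # ---- DATASET_DOMAINS: segments as shapes along sequences -----------
    domains_path = outdir / "dataset_domains_modules.txt"
    seg_by_leaf: dict[str, list] = {}
    for m in mods:
        for seq_id, start, length in m.segments:
            seg_by_leaf.setdefault(seq_id, []).append(
                (start, start + length, m.id)
            )
    with open(domains_path, "w") as fh:
        fh.write("DATASET_DOMAINS\n")
        fh.write("SEPARATOR COMMA\n")
        fh.write("DATASET_LABEL,Module segments\n")
        fh.write("COLOR,#7a4fb6\n")
        fh.write("DATA\n")
        for leaf in sorted(seg_by_leaf):
            if leaf not in leaf_ids:
                continue
            segs = sorted(seg_by_leaf[leaf])
            if sequence_lengths and leaf in sequence_lengths:
                total = sequence_lengths[leaf]
            else:
                total = max(end for _s, end, _m in segs)
            fields = [
                f"{_module_shape(mid)}|{start}|{end}|{module_color(mid)}|{mid}"
                for start, end, mid in segs
            ]
            fh.write(f"{leaf},{total}," + ",".join(fields) + "\n")
    paths["domains"] = domains_path

    # ---- gained modules per node (plain text annotation) ---------------
    gains_path = outdir / "gained_modules.txt"
    signature_nodes = {s.node for s in signatures}
    with open(gains_path, "w") as fh:
        fh.write("# modules gained per gene-tree node "
                 "(* = module-PPI co-appearance)\n")
        for label in sorted(gains):
            gained = sorted(gains[label][0])
            if not gained:
                continue
            mark = "*" if label in signature_nodes else ""
            fh.write(f"{label}{mark}\t{' '.join(gained)}\n")
    paths["gains"] = gains_path
    return paths


def read_itol_dataset(path) -> dict:
    """Parse an emitted iTOL dataset back into headers + data rows."""
    headers: dict[str, str] = {}
    data: list[list[str]] = []
    dataset_type = None
    sep = ","
    in_data = False
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if dataset_type is None:
                dataset_type = line.strip()
                continue
            if not in_data:
                if line.strip() == "DATA":
                    in_data = True
                    continue
                if line.startswith("SEPARATOR"):
                    kind = line.split()[1]
                    sep = {"COMMA": ",", "TAB": "\t", "SPACE": " "}[kind]
                    headers["SEPARATOR"] = kind
                    continue
                key, _, value = line.partition(sep)
                headers[key] = value
            else:
                data.append(line.split(sep))
    if dataset_type is None:
        raise ValueError(f"{path} is not an iTOL dataset")
    return {"type": dataset_type, "headers": headers, "data": data}
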