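"""End-to-end orchestration: sequences -> modules -> ancestral states ->
co-appearance signatures.

`analyze` is the in-memory core; `run_pipeline` wraps it with file IO,
logging, a reproducibility manifest (parameters, seed, input checksums)
and iTOL export.

Stages
------
1. representatives — isoform filtering by locus overlap (skipped without GFF)
2. plma            — diagonal enumeration, PLMA construction, modules
3. modules-anc     — ancestral module composition (Dollo or LCA backend)
4. traits-anc      — ancestral PPI reconstruction (binary ML, marginal calls)
5. gains           — per-node gained/lost module and trait sets
6. signatures      — module-PPI co-appearance events + summary statistics
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import yaml

from .seqprep import (read_fasta, attach_loci, select_representatives,
                      write_representatives)
from .scoring import ScoringModel
from .plma import (build_plma, extract_blocks, extract_modules,
                   write_modules_tsv, write_plma_text,
                   DEFAULT_MAX_DIAGONAL_LENGTH, DEFAULT_WEIGHT_THRESHOLD,
                   DEFAULT_MIN_MODULE_LENGTH)
from .trees import read_newick, label_internal_nodes, pdistance_matrix, nj_tree
from .ancestral_modules import (presence_from_modules, dollo_composition,
                                lca_composition, gains_losses,
                                write_composition_tsv, write_gains_tsv)
from .ancestral_traits import (TraitTable, reconstruct_traits,
                               write_posteriors_tsv, trait_diff)
from .signatures import (detect_coappearances, signature_stats,
                         write_signatures_tsv, write_stats_json)
from .itol import export_itol

logger = logging.getLogger("phylomod")

STAGES = ["representatives", "plma", "modules-anc", "traits-anc",
          "gains", "signatures"]


@dataclass
class AnalysisResult:
    plma: object
    blocks: list
    modules: list
    composition: dict
    in_map: dict
    reconstructions: dict
    module_gains: dict
    trait_gains: dict
    signatures: list
    ppi_only_nodes: list


def analyze(
    records,
    tree,
    trait_table: Optional[TraitTable] = None,
    *,
    max_diagonal_length: int = DEFAULT_MAX_DIAGONAL_LENGTH,
    weight_threshold: float = DEFAULT_WEIGHT_THRESHOLD,
    min_module_length: int = DEFAULT_MIN_MODULE_LENGTH,
    backend: str = "dollo",
    scoring: Optional[ScoringModel] = None,
    trait_pi1: Optional[float] = None,
    trait_rate: Optional[float] = None,
) -> AnalysisResult:
    """Run module detection, ancestral inference and signature detection.

    `records` are ProteinRecords whose ids match the leaf labels of the
    rooted `tree` (internal nodes are labeled in place when missing).
    """
    if scoring is None:
        scoring = ScoringModel()
    label_internal_nodes(tree)

    plma = build_plma(records, max_length=max_diagonal_length,
                      threshold=weight_threshold, scoring=scoring)
    blocks = extract_blocks(plma)
    modules = extract_modules(blocks, min_module_length)
    logger.info("PLMA: %d blocks, %d modules", len(blocks), len(modules))

    presences = presence_from_modules(modules)
    if backend == "dollo":
        composition = dollo_composition(tree, presences)
    elif backend == "lca":
        composition = _lca_backend(records, tree, modules, presences)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    if trait_table is not None:
        in_map, recons = reconstruct_traits(
            tree, trait_table, pi1=trait_pi1, rate=trait_rate
        )
        trait_gains = trait_diff(tree, in_map)
    else:
        in_map, recons, trait_gains = {}, {}, {}

    module_gains = gains_losses(tree, composition)
    signatures, ppi_only = detect_coappearances(
        tree, module_gains, trait_gains
    )
    return AnalysisResult(
        plma=plma, blocks=blocks, modules=modules,
        composition=composition, in_map=in_map, reconstructions=recons,
        module_gains=module_gains, trait_gains=trait_gains,
        signatures=signatures, ppi_only_nodes=ppi_only,
    )


def _lca_backend(records, tree, modules, presences):
    """Per-module NJ trees from segment p-distances, mapped onto the tree.

    Modules with fewer than three segments cannot get an NJ tree and fall
    back to the Dollo assignment.
    """
    seqs = {r.id: r.sequence for r in records}
    module_trees, seg_map = {}, {}
    for m in modules:
        if len(m.member_sequences) < 3:
            continue
        aln, mapping = {}, {}
        for seq_id, start, length in m.segments:
            seg_id = f"{m.id}.{seq_id}"
            aln[seg_id] = seqs[seq_id][start:start + length]
            mapping[seg_id] = seq_id
        ids, mat = pdistance_matrix(aln)
        module_trees[m.id] = nj_tree(ids, mat)
        seg_map.update(mapping)
    composition = lca_composition(tree, module_trees, seg_map)
    small = [p for p in presences if p.module_id not in module_trees]
    if small:
        for node, mods in dollo_composition(tree, small).items():
            composition[node] |= mods
    return composition


@dataclass
class RunConfig:
    fasta: str
    gene_tree: str
    traits: Optional[str] = None          # long-format trait TSV
    gff: Optional[str] = None
    outdir: str = "phylomod_out"
    max_diagonal_length: int = DEFAULT_MAX_DIAGONAL_LENGTH
    weight_threshold: float = DEFAULT_WEIGHT_THRESHOLD
    min_module_length: int = DEFAULT_MIN_MODULE_LENGTH
    module_backend: str = "dollo"         # "dollo" | "lca"
    trait_pi1: Optional[float] = None     # fixed stationary freq (else ML)
    trait_rate: Optional[float] = None
    seed: int = 0
    log_level: str = "INFO"
    itol: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def validate(self):
        for name in ("fasta", "gene_tree", "traits", "gff"):
            path = getattr(self, name)
            if path is not None and not Path(path).is_file():
                raise FileNotFoundError(f"{name} file not found: {path}")
        if self.module_backend not in ("dollo", "lca"):
            raise ValueError(f"unknown backend {self.module_backend!r}")
        if not (1 <= self.max_diagonal_length <= 100):
            raise ValueError("max_diagonal_length out of range")
        if self.weight_threshold <= 0:
            raise ValueError("weight_threshold must be positive")
        if self.min_module_length < 1:
            raise ValueError("min_module_length must be >= 1")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages with file outputs; returns the output directory."""
    from . import __version__

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper()))
    completed = []
    stage = "representatives"
    try:
        records = read_fasta(config.fasta)
        if config.gff:
            records, unmatched = attach_loci(records, config.gff)
            if unmatched:
                logger.warning("no locus for %d records: %s",
                               len(unmatched), unmatched[:10])
            groups, records = select_representatives(records)
            by_id = {r.id: r for r in records}
            write_representatives(groups, by_id,
                                  outdir / "representatives.fasta",
                                  outdir / "gene_groups.tsv")
        completed.append(stage)

        stage = "plma"
        tree = read_newick(config.gene_tree)
        leaf_ids = [l.taxon.label for l in tree.leaf_node_iter()]
        trait_table = (
            TraitTable.from_tsv(config.traits, leaves=leaf_ids)
            if config.traits else None
        )
        result = analyze(
            records, tree, trait_table,
            max_diagonal_length=config.max_diagonal_length,
            weight_threshold=config.weight_threshold,
            min_module_length=config.min_module_length,
            backend=config.module_backend,
            trait_pi1=config.trait_pi1,
            trait_rate=config.trait_rate,
        )
        write_modules_tsv(result.modules, outdir / "modules.tsv")
        write_plma_text(result.plma, result.blocks, outdir / "plma.txt")
        completed.append(stage)

        stage = "modules-anc"
        write_composition_tsv(result.composition, outdir / "composition.tsv")
        completed.append(stage)

        stage = "traits-anc"
        if result.reconstructions:
            write_posteriors_tsv(result.reconstructions,
                                 outdir / "trait_posteriors.tsv")
        completed.append(stage)

        stage = "gains"
        write_gains_tsv(result.module_gains, outdir / "module_gains.tsv")
        if result.trait_gains:
            write_gains_tsv(result.trait_gains, outdir / "trait_gains.tsv")
        completed.append(stage)

        stage = "signatures"
        write_signatures_tsv(result.signatures, outdir / "signatures.tsv")
        write_stats_json(signature_stats(result.signatures),
                         outdir / "signature_stats.json")
        (outdir / "ppi_only_nodes.txt").write_text(
            "\n".join(result.ppi_only_nodes)
            + ("\n" if result.ppi_only_nodes else "")
        )
        if config.itol:
            export_itol(
                tree, result.modules, result.module_gains, result.signatures,
                outdir / "itol",
                sequence_lengths={r.id: len(r.sequence) for r in records},
            )
        completed.append(stage)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {exc}"
        ) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "input_checksums": {
            name: _sha256(getattr(config, name))
            for name in ("fasta", "gene_tree", "traits", "gff")
            if getattr(config, name)
        },
        "stages_completed": completed,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
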