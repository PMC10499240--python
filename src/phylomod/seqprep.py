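"""Sequence input and per-gene representative selection.

Protein isoforms translated from the same gene have overlapping loci on
the genome.  Given per-protein genomic coordinates (from a GFF3 file),
proteins of one species whose loci overlap by at least one base on the
same strand of the same contig are grouped as isoforms of a single gene
(transitively), and the longest protein of each group is kept as the
gene's representative.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Optional

from Bio import SeqIO

__all__ = [
    "Locus",
    "ProteinRecord",
    "GeneGroup",
    "read_fasta",
    "write_fasta",
    "attach_loci",
    "select_representatives",
    "write_representatives",
]


@dataclass(frozen=True)
class Locus:
    """Genomic interval of a protein's coding features.

    Coordinates are 0-based half-open internally; GFF3 input (1-based,
    closed) is converted on parsing.
    """

    contig: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"empty locus [{self.start}, {self.end})")

    def overlaps(self, other: "Locus") -> bool:
        """True when the two loci share >= 1 base on the same contig+strand."""
        return (
            self.contig == other.contig
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    species: str = ""
    locus: Optional[Locus] = None

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self):
        return len(self.sequence)


@dataclass
class GeneGroup:
    """Isoform group: proteins of one species whose loci overlap transitively."""

    id: str
    species: str
    members: list[ProteinRecord] = field(default_factory=list)
    representative: str = ""
    #: set when the group is a singleton only because its member has no locus
    no_locus: bool = False


def read_fasta(path, species: str = "") -> list[ProteinRecord]:
    """Read protein records; the first whitespace-delimited header token is the id.

    Sequences are uppercased.  Duplicate ids and empty files raise.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), species=species)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def _parse_gff_attributes(text: str) -> dict:
    attrs = {}
    for part in text.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"attribute without '=': {part!r}")
        key, value = part.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def attach_loci(
    records,
    gff_path,
    attribute: str = "protein_id",
    feature_types: tuple = ("CDS", "mRNA"),
):
    """Attach genomic loci to records from a GFF3 file.

    Features of the given types are matched to records by exact equality
    of the GFF attribute `attribute` with the record id.  A matched
    record's locus spans (contig, strand, min start, max end) over its
    features.  Returns ``(records, unmatched_ids)``; unmatched records
    keep ``locus=None``.
    """
    by_id = {rec.id: rec for rec in records}
    spans: dict[str, list] = {}
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{gff_path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            contig, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = cols
            if ftype not in feature_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
                attrs = _parse_gff_attributes(attr_s)
            except ValueError as exc:
                raise ValueError(f"{gff_path}:{lineno}: {exc}") from None
            pid = attrs.get(attribute)
            if pid is None or pid not in by_id:
                continue
            spans.setdefault(pid, []).append((contig, strand, start, end, lineno))

    out = []
    unmatched = []
    for rec in records:
        feats = spans.get(rec.id)
        if not feats:
            unmatched.append(rec.id)
            out.append(rec)
            continue
        contigs = {f[0] for f in feats}
        strands = {f[1] for f in feats}
        if len(contigs) > 1:
            raise ValueError(
                f"features for {rec.id!r} span multiple contigs: {sorted(contigs)}"
            )
        if len(strands) > 1:
            raise ValueError(
                f"features for {rec.id!r} span both strands"
            )
        start = min(f[2] for f in feats) - 1  # GFF3 is 1-based closed
        end = max(f[3] for f in feats)
        out.append(
            replace(rec, locus=Locus(contigs.pop(), strands.pop(), start, end))
        )
    return out, unmatched


def select_representatives(records):
    """Group isoforms by transitive locus overlap and pick one protein per gene.

    Within each (species, contig, strand), records whose loci overlap by
    at least one base are chained into gene groups (connected components
    of the overlap graph).  The longest member represents the group; ties
    go to the lexicographically smallest id.  Records without loci form
    flagged singleton groups.

    Returns ``(groups, representatives)``.
    """
    with_locus: dict[tuple, list[ProteinRecord]] = {}
    no_locus: list[ProteinRecord] = []
    for rec in records:
        if rec.locus is None:
            no_locus.append(rec)
        else:
            key = (rec.species, rec.locus.contig, rec.locus.strand)
            with_locus.setdefault(key, []).append(rec)

    groups: list[GeneGroup] = []
    for key in sorted(with_locus):
        bucket = sorted(with_locus[key], key=lambda r: (r.locus.start, r.id))
        # sweep: intervals sorted by start chain while they keep overlapping
        current: list[ProteinRecord] = []
        max_end = None
        for rec in bucket:
            if current and rec.locus.start < max_end:
                current.append(rec)
                max_end = max(max_end, rec.locus.end)
            else:
                if current:
                    groups.append(_make_group(key[0], current))
                current = [rec]
                max_end = rec.locus.end
        if current:
            groups.append(_make_group(key[0], current))

    for rec in sorted(no_locus, key=lambda r: r.id):
        g = _make_group(rec.species, [rec])
        g.no_locus = True
        groups.append(g)

    for i, g in enumerate(groups, start=1):
        g.id = f"GG{i}"
    reps = []
    by_id = {rec.id: rec for rec in records}
    for g in groups:
        reps.append(by_id[g.representative])
    return groups, reps


def _make_group(species: str, members: list[ProteinRecord]) -> GeneGroup:
    rep = min(members, key=lambda r: (-len(r.sequence), r.id))
    return GeneGroup(id="", species=species, members=list(members),
                     representative=rep.id)


def write_representatives(groups, records_by_id, fasta_path, tsv_path) -> None:
    """Write representative sequences plus a gene-group mapping table."""
    write_fasta([records_by_id[g.representative] for g in groups], fasta_path)
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene_group_id", "species", "representative_id", "member_ids"]
        )
        for g in groups:
            writer.writerow(
                [g.id, g.species, g.representative,
                 ",".join(sorted(m.id for m in g.members))]
            )
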