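"""Partial local multiple alignment (PLMA) and conserved sequence modules.

A PLMA is a set of alignment *blocks*, each aligning gap-free, equal-length
segments from a subset of the input sequences.  It is built greedily from
weighted gap-free pairwise diagonals: candidates are enumerated, ranked by
decreasing weight, and inserted one by one — with transitive alignment
through position equivalence classes and single-column local extension —
whenever the induced alignment stays consistent (no class holds two
positions of one sequence; the class precedence order is acyclic).

Blocks are maximal runs of consecutive alignment columns with identical
sequence membership; blocks of length >= ``min_module_length`` whose
membership has >= 2 sequences define the conserved sequence modules whose
gains and losses are traced on the gene tree downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .scoring import ScoringModel, diagonal_weight

__all__ = [
    "Diagonal",
    "Block",
    "Module",
    "Plma",
    "diagonal_weight",
    "enumerate_diagonals",
    "rank_diagonals",
    "build_plma",
    "extract_blocks",
    "extract_modules",
    "write_modules_tsv",
    "read_modules_tsv",
    "write_plma_text",
]

DEFAULT_MAX_DIAGONAL_LENGTH = 20  # residues; the -M parameter
DEFAULT_WEIGHT_THRESHOLD = 10.0   # nats;     the -t parameter
DEFAULT_MIN_MODULE_LENGTH = 5     # residues


@dataclass(frozen=True, order=True)
class Diagonal:
    """A gap-free pairwise local alignment of two equal-length segments."""

    seq_a: str
    seq_b: str
    start_a: int
    start_b: int
    length: int
    score: int
    weight: float

    def __post_init__(self):
        if self.seq_a == self.seq_b:
            raise ValueError("a diagonal must involve two distinct sequences")
        if self.length < 1:
            raise ValueError("diagonal length must be >= 1")


@dataclass(frozen=True)
class Block:
    """Maximal set of equal-length segments mutually aligned over all columns."""

    id: str
    segments: tuple  # of (seq_id, start, length), sorted by seq order
    length: int

    @property
    def member_sequences(self) -> frozenset:
        return frozenset(s for s, _, _ in self.segments)


@dataclass(frozen=True)
class Module:
    """A block long enough to carry phylogenetic signal (>= L_min residues)."""

    id: str
    block: Block
    member_sequences: frozenset
    length: int

    @property
    def segments(self):
        return self.block.segments


class Plma:
    """Consistent partial local multiple alignment over position classes.

    Every sequence position belongs to exactly one alignment class;
    initially all classes are singletons.  Merging the columns of an
    accepted diagonal unions classes transitively.  Consistency requires
    that no class holds two positions of one sequence and that the
    precedence relation between classes (induced by position order within
    each sequence) stays acyclic.
    """

    def __init__(self, sequences: Iterable[tuple]):
        self.seq_ids: list[str] = []
        self.seq_lengths: list[int] = []
        for sid, length in sequences:
            self.seq_ids.append(sid)
            self.seq_lengths.append(int(length))
        if len(set(self.seq_ids)) != len(self.seq_ids):
            raise ValueError("duplicate sequence ids")
        self.seq_index = {sid: i for i, sid in enumerate(self.seq_ids)}
        # negative ids encode singleton classes; merged classes get ids >= 0
        self.pos_class: list[np.ndarray] = []
        base = 1
        for length in self.seq_lengths:
            self.pos_class.append(-np.arange(base, base + length, dtype=np.int64))
            base += length
        self.class_members: dict[int, dict[int, int]] = {}
        self._next_class = 0
        self.accepted: list[Diagonal] = []

    # -- class accessors -------------------------------------------------

    def members_of(self, class_id: int, seq: int = None, pos: int = None) -> dict:
        """Members of a class as {seq_index: position}."""
        if class_id >= 0:
            return self.class_members[class_id]
        if seq is not None:
            return {seq: pos}
        # decode a singleton id back to its (seq, pos)
        gpos = -class_id - 1
        for s, length in enumerate(self.seq_lengths):
            if gpos < length:
                return {s: gpos}
            gpos -= length
        raise KeyError(class_id)

    def class_of(self, seq_id: str, pos: int) -> int:
        return int(self.pos_class[self.seq_index[seq_id]][pos])

    def aligned_positions(self, seq_id: str, pos: int) -> dict:
        """{seq_id: position} of everything aligned with (seq_id, pos)."""
        s = self.seq_index[seq_id]
        cid = int(self.pos_class[s][pos])
        return {
            self.seq_ids[t]: p for t, p in self.members_of(cid, s, pos).items()
        }

    # -- insertion -------------------------------------------------------

    def _union(self, sa: int, pa: int, sb: int, pb: int) -> bool:
        """Merge the classes of (sa,pa) and (sb,pb); False on membership clash."""
        ca = int(self.pos_class[sa][pa])
        cb = int(self.pos_class[sb][pb])
        if ca == cb:
            return True
        ma = self.members_of(ca, sa, pa)
        mb = self.members_of(cb, sb, pb)
        for s in ma.keys() & mb.keys():
            if ma[s] != mb[s]:
                return False  # two positions of one sequence in a class
        new = dict(ma)
        new.update(mb)
        cid = self._next_class
        self._next_class += 1
        self.class_members[cid] = new
        for s, p in new.items():
            self.pos_class[s][p] = cid
        self.class_members.pop(ca, None)
        self.class_members.pop(cb, None)
        return True

    def _snapshot(self):
        return (
            [a.copy() for a in self.pos_class],
            {k: dict(v) for k, v in self.class_members.items()},
            self._next_class,
        )

    def _restore(self, snap):
        self.pos_class, self.class_members, self._next_class = snap

    def _precedence_acyclic(self) -> bool:
        """Kahn's algorithm on the precedence graph condensed to merged classes.

        Singleton classes have a single in- and out-neighbour along their
        own sequence, so any precedence cycle survives contraction onto
        the merged (multi-member) classes; edges join consecutive merged
        classes along each sequence.
        """
        succ: dict[int, set] = {}
        indeg: dict[int, int] = {}
        for arr in self.pos_class:
            merged = arr[arr >= 0]
            for u, v in zip(merged[:-1], merged[1:]):
                u, v = int(u), int(v)
                if u == v:
                    return False  # same class twice in one sequence
                s = succ.setdefault(u, set())
                if v not in s:
                    s.add(v)
                    indeg[v] = indeg.get(v, 0) + 1
                indeg.setdefault(u, indeg.get(u, 0))
        queue = [u for u, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            u = queue.pop()
            seen += 1
            for v in succ.get(u, ()):
                indeg[v] -= 1
                if indeg[v] == 0:
                    queue.append(v)
        return seen == len(indeg)

    def check_consistency(self) -> bool:
        """Full recheck over the uncondensed precedence graph (for tests)."""
        for cid, members in self.class_members.items():
            positions = {}
            for s, p in members.items():
                if s in positions and positions[s] != p:
                    return False
                positions[s] = p
                if int(self.pos_class[s][p]) != cid:
                    return False
        succ: dict[int, set] = {}
        indeg: dict[int, int] = {}
        for arr in self.pos_class:
            for u, v in zip(arr[:-1], arr[1:]):
                u, v = int(u), int(v)
                if u == v:
                    return False
                s = succ.setdefault(u, set())
                if v not in s:
                    s.add(v)
                    indeg[v] = indeg.get(v, 0) + 1
                indeg.setdefault(u, indeg.get(u, 0))
        queue = [u for u, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            u = queue.pop()
            seen += 1
            for v in succ.get(u, ()):
                indeg[v] -= 1
                if indeg[v] == 0:
                    queue.append(v)
        return seen == len(indeg)

    def add_diagonal(self, diag: Diagonal) -> bool:
        """Insert a diagonal atomically; returns acceptance.

        All columns are merged (transitively through existing classes) if
        and only if the merged alignment stays consistent; otherwise the
        PLMA is left unchanged.
        """
        sa = self.seq_index.get(diag.seq_a)
        sb = self.seq_index.get(diag.seq_b)
        if sa is None or sb is None:
            raise KeyError(f"unknown sequence in diagonal: {diag.seq_a}/{diag.seq_b}")
        if diag.start_a < 0 or diag.start_a + diag.length > self.seq_lengths[sa]:
            raise IndexError(f"diagonal out of range in {diag.seq_a}")
        if diag.start_b < 0 or diag.start_b + diag.length > self.seq_lengths[sb]:
            raise IndexError(f"diagonal out of range in {diag.seq_b}")
        snap = self._snapshot()
        ok = True
        for i in range(diag.length):
            if not self._union(sa, diag.start_a + i, sb, diag.start_b + i):
                ok = False
                break
        if ok:
            ok = self._precedence_acyclic()
        if not ok:
            self._restore(snap)
            return False
        self.accepted.append(diag)
        return True

    def classes(self) -> dict[int, dict[int, int]]:
        """All merged (multi-member) classes."""
        return dict(self.class_members)


# -- diagonal enumeration ------------------------------------------------


def enumerate_diagonals(
    records,
    max_length: int = DEFAULT_MAX_DIAGONAL_LENGTH,
    threshold: float = DEFAULT_WEIGHT_THRESHOLD,
    scoring: Optional[ScoringModel] = None,
) -> list[Diagonal]:
    """All locally maximal gap-free diagonals with weight >= `threshold`.

    Every window of length 1..`max_length` over every ordered sequence
    pair is scored with the sequence-length corrected weight
    (`ScoringModel.corrected_weight`), so the threshold bounds the
    probability of a chance diagonal anywhere in the pair comparison.
    Windows reaching the threshold are kept per offset by greedy
    weight-maximal non-overlapping selection.
    """
    if scoring is None:
        scoring = ScoringModel()
    recs = list(records)
    if len(recs) < 2:
        raise ValueError("need at least 2 sequences")
    encoded = [(r.id, scoring.encode(r.sequence)) for r in recs]
    lookups = {
        l: scoring.weight_lookup(l)
        for l in range(1, max_length + 1)
    }
    out: list[Diagonal] = []
    for x in range(len(encoded)):
        for y in range(x + 1, len(encoded)):
            ida, ia = encoded[x]
            idb, ib = encoded[y]
            out.extend(
                _pair_diagonals(ida, ia, idb, ib, max_length, threshold,
                                lookups, scoring)
            )
    return out


def _pair_diagonals(ida, ia, idb, ib, max_length, threshold, lookups, scoring):
    la, lb = len(ia), len(ib)
    smin = scoring.smin
    # cumulative sums along diagonals: dcum[i+1, j+1] = score(i,j) + dcum[i, j]
    dcum = np.zeros((la + 1, lb + 1), dtype=np.int64)
    dcum[1:, 1:] = scoring.score[ia[:, None], ib[None, :]]
    for i in range(1, la + 1):
        dcum[i, 1:] += dcum[i - 1, :-1]

    hits = []  # (offset, start_a, length, score, weight)
    for l in range(1, min(max_length, la, lb) + 1):
        win = dcum[l:, l:] - dcum[:-l, :-l]
        wtab = lookups[l]
        idx = win - l * smin
        log_n = np.log((la - l + 1) * (lb - l + 1))
        weights = wtab[np.clip(idx, 0, wtab.size - 1)] - log_n
        weights = np.where(idx < 0, -np.inf, weights)
        sel = np.argwhere(weights >= threshold)
        for i0, j0 in sel:
            hits.append(
                (int(i0) - int(j0), int(i0), l, int(win[i0, j0]),
                 float(weights[i0, j0]))
            )

    # local maximality per offset: greedily keep weight-maximal windows,
    # discarding any window overlapping an already-kept stronger one, so
    # each conserved stretch contributes its best-supported window only
    by_offset: dict[int, list] = {}
    for h in hits:
        by_offset.setdefault(h[0], []).append(h)
    kept = []
    for offset, group in sorted(by_offset.items()):
        group.sort(key=lambda h: (-h[4], -h[2], h[1]))  # weight desc
        chosen = []
        for h in group:
            _, start, length, _score, _weight = h
            overlaps = any(
                start < cs + cl and cs < start + length
                for (_, cs, cl, _cscore, _cw) in chosen
            )
            if not overlaps:
                chosen.append(h)
        kept.extend(chosen)
    return [
        Diagonal(ida, idb, start, start - offset, length, score, weight)
        for offset, start, length, score, weight in kept
    ]


def rank_diagonals(diagonals) -> list[Diagonal]:
    """Deterministic greedy order: weight desc, length desc, coordinates."""
    return sorted(
        diagonals,
        key=lambda d: (-d.weight, -d.length, d.seq_a, d.seq_b,
                       d.start_a, d.start_b),
    )


def build_plma(
    records,
    max_length: int = DEFAULT_MAX_DIAGONAL_LENGTH,
    threshold: float = DEFAULT_WEIGHT_THRESHOLD,
    scoring: Optional[ScoringModel] = None,
    extend: bool = True,
) -> Plma:
    """Enumerate, rank and greedily insert diagonals into a consistent PLMA.

    After each accepted insertion the diagonal is locally extended one
    column at a time at both ends, as long as each extension strictly
    improves the diagonal's weight (which therefore stays above
    `threshold`) and the extension column merges consistently.
    """
    if scoring is None:
        scoring = ScoringModel()
    recs = list(records)
    diagonals = enumerate_diagonals(recs, max_length, threshold, scoring)
    ranked = rank_diagonals(diagonals)
    plma = Plma((r.id, len(r.sequence)) for r in recs)
    seqs = {r.id: r.sequence for r in recs}
    for diag in ranked:
        if plma.add_diagonal(diag) and extend:
            _extend_diagonal(plma, diag, seqs, scoring, threshold)
    return plma


EXTENSION_DROPOFF = 8.0  # nats; bridges one poor column, not a run of noise


def _extend_diagonal(plma, diag, seqs, scoring, threshold,
                     dropoff: float = EXTENSION_DROPOFF):
    """Local extension at both ends, kept up to the weight-maximal endpoint.

    Columns are explored outward while the corrected weight stays within
    `dropoff` nats of the best weight seen, so a mutated column inside a
    conserved stretch is bridged, but the kept extension never runs the
    weight below its maximum — extension cannot crawl into background.
    Each kept column is merged only if consistency is preserved.
    """
    sa, sb = diag.seq_a, diag.seq_b
    seq_a, seq_b = seqs[sa], seqs[sb]
    enc_a = scoring.encode(seq_a)
    enc_b = scoring.encode(seq_b)
    la, lb = len(seq_a), len(seq_b)
    for direction in (-1, +1):
        start_a, start_b, length, score = (
            diag.start_a, diag.start_b, diag.length, diag.score
        )
        best_w = diag.weight
        best_k = 0
        walk_w = best_w
        k = 0
        while walk_w > best_w - dropoff:
            k += 1
            if direction < 0:
                pa, pb = start_a - k, start_b - k
            else:
                pa, pb = start_a + length - 1 + k, start_b + length - 1 + k
            if pa < 0 or pb < 0 or pa >= la or pb >= lb:
                break
            score += int(scoring.score[enc_a[pa], enc_b[pb]])
            walk_w = scoring.corrected_weight(length + k, score, la, lb)
            if walk_w > best_w:
                best_w, best_k = walk_w, k
        for j in range(1, best_k + 1):
            if direction < 0:
                pa, pb = start_a - j, start_b - j
            else:
                pa, pb = start_a + length - 1 + j, start_b + length - 1 + j
            trial = Diagonal(sa, sb, pa, pb, 1, 0, threshold)
            if not plma.add_diagonal(trial):
                break


# -- blocks and modules --------------------------------------------------


def extract_blocks(plma: Plma) -> list[Block]:
    """Maximal runs of consecutive columns with identical membership.

    A block chains merged classes whose members advance by one position in
    every member sequence with an unchanged sequence set; each merged
    class belongs to exactly one block.
    """
    classes = plma.classes()
    # index classes by frozen membership for successor lookup
    starts = []
    for cid, members in classes.items():
        pred = _shift_class(plma, members, -1)
        if pred is None:
            starts.append(cid)
    blocks = []
    for cid in starts:
        chain = [cid]
        members = classes[cid]
        nxt = _shift_class(plma, members, +1)
        while nxt is not None:
            chain.append(nxt)
            members = classes[nxt]
            nxt = _shift_class(plma, members, +1)
        first = classes[chain[0]]
        length = len(chain)
        segments = tuple(
            sorted(
                (plma.seq_ids[s], int(p), length)
                for s, p in first.items()
            )
        )
        blocks.append(Block(id="", segments=segments, length=length))
    blocks.sort(key=lambda b: (b.segments[0][0], b.segments[0][1], b.segments))
    return [
        Block(id=f"B{i}", segments=b.segments, length=b.length)
        for i, b in enumerate(blocks, start=1)
    ]


def _shift_class(plma: Plma, members: dict, delta: int):
    """Id of the neighbouring class if membership is preserved, else None."""
    target = None
    for s, p in members.items():
        q = p + delta
        if q < 0 or q >= plma.seq_lengths[s]:
            return None
        cid = int(plma.pos_class[s][q])
        if cid < 0:
            return None
        if target is None:
            target = cid
        elif cid != target:
            return None
    neighbour = plma.class_members.get(target)
    if neighbour is None or set(neighbour) != set(members):
        return None
    return target


def extract_modules(
    blocks, min_length: int = DEFAULT_MIN_MODULE_LENGTH
) -> list[Module]:
    """Blocks of length >= `min_length` with >= 2 member sequences.

    Module ids are assigned deterministically by first segment coordinate.
    """
    chosen = [
        b for b in blocks
        if b.length >= min_length and len(b.member_sequences) >= 2
    ]
    chosen.sort(key=lambda b: (b.segments[0][0], b.segments[0][1], b.segments))
    return [
        Module(
            id=f"B{i}",
            block=b,
            member_sequences=b.member_sequences,
            length=b.length,
        )
        for i, b in enumerate(chosen, start=1)
    ]


# -- IO ------------------------------------------------------------------


def write_modules_tsv(modules, path) -> None:
    """module_id, length, n_members header lines followed by segment lines."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["module_id", "length", "n_members",
                         "seq_id", "start", "end"])
        for mod in modules:
            for seq_id, start, length in mod.segments:
                writer.writerow(
                    [mod.id, mod.length, len(mod.member_sequences),
                     seq_id, start, start + length]
                )


def read_modules_tsv(path) -> list[Module]:
    rows: dict[str, list] = {}
    order = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:3] != ["module_id", "length", "n_members"]:
            raise ValueError(f"unexpected module TSV header in {path}")
        for row in reader:
            mid, length, _n, seq_id, start, end = row
            if mid not in rows:
                rows[mid] = []
                order.append(mid)
            rows[mid].append((seq_id, int(start), int(end) - int(start)))
    modules = []
    for mid in order:
        segs = tuple(sorted(rows[mid]))
        length = segs[0][2]
        block = Block(id=mid, segments=segs, length=length)
        modules.append(
            Module(id=mid, block=block,
                   member_sequences=block.member_sequences, length=length)
        )
    return modules


def write_plma_text(plma: Plma, blocks, path) -> None:
    """Plain-text PLMA dump: sequences, then one block per stanza."""
    with open(path, "w") as fh:
        fh.write(f"# PLMA over {len(plma.seq_ids)} sequences\n")
        for sid, length in zip(plma.seq_ids, plma.seq_lengths):
            fh.write(f"sequence\t{sid}\t{length}\n")
        for b in blocks:
            fh.write(f"block\t{b.id}\tlength={b.length}\t"
                     f"members={len(b.segments)}\n")
            for seq_id, start, length in b.segments:
                fh.write(f"  segment\t{seq_id}\t{start}\t{start + length}\n")
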