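"""PLMA construction: diagonals, consistency, blocks and modules."""

import numpy as np
import pytest

from phylomod.plma import (Diagonal, Plma, enumerate_diagonals,
                           rank_diagonals, build_plma, extract_blocks,
                           extract_modules)
from phylomod.seqprep import ProteinRecord
from oracles import (enumerate_diagonals_bruteforce, blocks_bruteforce,
                     assert_block_alignment_property)

AA = np.array(list("ARNDCQEGHILKMFPSTWYV"))


def random_records(rng, n, length):
    return [
        ProteinRecord(id=f"S{i}", sequence="".join(rng.choice(AA, length)))
        for i in range(n)
    ]


def plant(rng, motif, n, flank, carriers=None):
    """Records with `motif` inserted between random flanks."""
    records = []
    for i in range(n):
        left = "".join(rng.choice(AA, flank))
        right = "".join(rng.choice(AA, flank))
        core = motif if (carriers is None or i in carriers) else \
            "".join(rng.choice(AA, len(motif)))
        records.append(ProteinRecord(id=f"S{i}", sequence=left + core + right))
    return records


class TestEnumerateDiagonals:
    def test_equals_bruteforce_on_toy_12mers(self, scoring):
        seq_a = "WCWHDEKMYFRA"
        seq_b = "ACWHDEKMYVRW"
        records = [ProteinRecord("A", seq_a), ProteinRecord("B", seq_b)]
        for threshold in (2.0, 5.0, 8.0):
            got = {
                (d.seq_a, d.seq_b, d.start_a, d.start_b, d.length, d.score,
                 round(d.weight, 9))
                for d in enumerate_diagonals(records, 20, threshold, scoring)
            }
            expected = enumerate_diagonals_bruteforce(
                seq_a, seq_b, ("A", "B"), scoring, 20, threshold
            )
            assert got == expected
            assert got, "toy sequences share a conserved stretch"

    def test_length_cap_on_identical_sequences(self, scoring):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(AA, 25))
        records = [ProteinRecord("A", seq), ProteinRecord("B", seq)]
        diagonals = enumerate_diagonals(records, 20, 10.0, scoring)
        assert diagonals
        assert all(d.length <= 20 for d in diagonals)

    def test_random_pair_mostly_empty_and_all_above_threshold(self, scoring):
        rng = np.random.default_rng(11)
        records = random_records(rng, 2, 30)
        diagonals = enumerate_diagonals(records, 20, 10.0, scoring)
        assert all(d.weight >= 10.0 for d in diagonals)

    def test_threshold_monotonicity(self, scoring):
        rng = np.random.default_rng(3)
        records = plant(rng, "".join(rng.choice(AA, 9)), 3, 15)
        counts = [
            len(enumerate_diagonals(records, 20, t, scoring))
            for t in (4.0, 6.0, 8.0, 10.0, 14.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestRankDiagonals:
    def _diag(self, w, l, a="A", b="B", sa=0, sb=0):
        return Diagonal(a, b, sa, sb, l, 0, w)

    def test_weight_then_length_then_coordinates(self):
        d_low = self._diag(3.2, 5)
        d_len8 = self._diag(10.5, 8)
        d_len6 = self._diag(10.5, 6)
        ranked = rank_diagonals([d_low, d_len6, d_len8])
        assert ranked == [d_len8, d_len6, d_low]

    def test_coordinate_tiebreak_and_permutation_invariance(self):
        diagonals = [
            self._diag(5.0, 4, sa=3, sb=1),
            self._diag(5.0, 4, sa=1, sb=2),
            self._diag(5.0, 4, sa=1, sb=0),
        ]
        expected = [diagonals[2], diagonals[1], diagonals[0]]
        for order in ([0, 1, 2], [2, 1, 0], [1, 2, 0]):
            assert rank_diagonals([diagonals[k] for k in order]) == expected


class TestAddDiagonal:
    def test_transitive_alignment_builds_three_member_classes(self):
        plma = Plma([("a", 10), ("b", 10), ("c", 10)])
        for x, y in (("a", "b"), ("b", "c"), ("a", "c")):
            d = Diagonal(x, y, 2, 2, 4, 0, 20.0)
            assert plma.add_diagonal(d)
        for col in range(2, 6):
            assert plma.aligned_positions("a", col) == {
                "a": col, "b": col, "c": col
            }
        assert plma.check_consistency()

    def test_crossing_alignment_rejected(self):
        plma = Plma([("S1", 5), ("S2", 5)])
        assert plma.add_diagonal(Diagonal("S1", "S2", 1, 2, 1, 0, 20.0))
        # aligning S1:2 with S2:1 would order the classes both ways
        assert not plma.add_diagonal(Diagonal("S1", "S2", 2, 1, 1, 0, 20.0))
        assert plma.aligned_positions("S1", 2) == {"S1": 2}
        assert plma.check_consistency()

    def test_two_positions_of_one_sequence_rejected(self):
        plma = Plma([("S1", 10), ("S2", 10)])
        assert plma.add_diagonal(Diagonal("S1", "S2", 3, 5, 1, 0, 20.0))
        # S1:7 ~ S2:5 would pull S1:3 and S1:7 into one class
        assert not plma.add_diagonal(Diagonal("S1", "S2", 7, 5, 1, 0, 20.0))
        assert plma.check_consistency()

    def test_unknown_sequence_and_range_errors(self):
        plma = Plma([("S1", 5), ("S2", 5)])
        with pytest.raises(KeyError):
            plma.add_diagonal(Diagonal("S1", "SX", 0, 0, 2, 0, 20.0))
        with pytest.raises(IndexError):
            plma.add_diagonal(Diagonal("S1", "S2", 4, 0, 3, 0, 20.0))

    def test_rejection_leaves_plma_unchanged(self):
        plma = Plma([("S1", 6), ("S2", 6), ("S3", 6)])
        assert plma.add_diagonal(Diagonal("S1", "S2", 0, 0, 3, 0, 20.0))
        assert plma.add_diagonal(Diagonal("S2", "S3", 0, 0, 3, 0, 20.0))
        before = {
            (s, p): plma.class_of(s, p)
            for s in ("S1", "S2", "S3") for p in range(6)
        }
        # S1:3 ~ S3:0 would put S1:0 and S1:3 in one class via transitivity
        assert not plma.add_diagonal(Diagonal("S1", "S3", 3, 0, 3, 0, 20.0))
        after = {
            (s, p): plma.class_of(s, p)
            for s in ("S1", "S2", "S3") for p in range(6)
        }
        assert after == before


class TestBuildPlma:
    def test_planted_motif_gives_single_full_membership_run(self, scoring):
        rng = np.random.default_rng(1)
        motif = "".join(rng.choice(AA, 10))
        records = plant(rng, motif, 4, 20)
        plma = build_plma(records, scoring=scoring)
        modules = extract_modules(extract_blocks(plma))
        full = [m for m in modules
                if m.member_sequences == {"S0", "S1", "S2", "S3"}]
        assert len(full) == 1
        assert full[0].length == 10
        start = dict(
            (s, p) for s, p, _l in full[0].segments
        )
        assert start == {"S0": 20, "S1": 20, "S2": 20, "S3": 20}

    def test_no_retained_diagonals_leaves_singletons(self, scoring):
        rng = np.random.default_rng(5)
        records = random_records(rng, 3, 15)
        plma = build_plma(records, threshold=50.0, scoring=scoring)
        assert plma.classes() == {}
        assert extract_blocks(plma) == []

    def test_rebuilding_from_accepted_diagonals_is_idempotent(self, scoring):
        rng = np.random.default_rng(2)
        records = plant(rng, "".join(rng.choice(AA, 12)), 4, 15)
        plma = build_plma(records, scoring=scoring)
        rebuilt = Plma((r.id, len(r.sequence)) for r in records)
        for d in plma.accepted:
            assert rebuilt.add_diagonal(d)

        def canon(p):
            return {
                frozenset(
                    (p.seq_ids[s], pos) for s, pos in members.items()
                )
                for members in p.classes().values()
            }

        assert canon(rebuilt) == canon(plma)

    def test_consistency_holds_after_every_insertion(self, scoring):
        rng = np.random.default_rng(4)
        records = plant(rng, "".join(rng.choice(AA, 8)), 4, 12)
        diagonals = rank_diagonals(
            enumerate_diagonals(records, 20, 8.0, scoring)
        )
        plma = Plma((r.id, len(r.sequence)) for r in records)
        for d in diagonals:
            plma.add_diagonal(d)
            assert plma.check_consistency()


class TestExtractBlocks:
    def test_membership_change_splits_blocks(self):
        # a long S1-S3 alignment whose right part also aligns S2
        plma = Plma([("S1", 12), ("S2", 12), ("S3", 12)])
        assert plma.add_diagonal(Diagonal("S1", "S3", 0, 0, 8, 0, 20.0))
        assert plma.add_diagonal(Diagonal("S1", "S2", 4, 4, 4, 0, 15.0))
        blocks = extract_blocks(plma)
        by_members = {
            frozenset(b.member_sequences): b for b in blocks
        }
        assert set(by_members) == {
            frozenset({"S1", "S3"}), frozenset({"S1", "S2", "S3"})
        }
        assert by_members[frozenset({"S1", "S3"})].length == 4
        assert by_members[frozenset({"S1", "S2", "S3"})].length == 4

    def test_no_multi_classes_no_blocks(self):
        plma = Plma([("S1", 5), ("S2", 5)])
        assert extract_blocks(plma) == []

    def test_matches_bruteforce_runs_on_random_plmas(self, scoring):
        rng = np.random.default_rng(9)
        for trial in range(10):
            records = random_records(rng, rng.integers(3, 6), 40)
            plma = build_plma(records, threshold=5.0, scoring=scoring)
            blocks = extract_blocks(plma)
            got = {b.segments for b in blocks}
            assert got == blocks_bruteforce(plma)
            assert_block_alignment_property(plma, blocks)
            # every merged class belongs to exactly one block
            n_block_columns = sum(b.length for b in blocks)
            assert n_block_columns == len(plma.classes())


class TestExtractModules:
    def _block_of_length(self, n):
        plma = Plma([("S1", 25), ("S2", 25)])
        assert plma.add_diagonal(Diagonal("S1", "S2", 0, 0, n, 0, 20.0))
        return extract_blocks(plma)

    @pytest.mark.parametrize("length,expected", [(4, 0), (5, 1), (6, 1)])
    def test_minimum_length_boundary(self, length, expected):
        modules = extract_modules(self._block_of_length(length))
        assert len(modules) == expected

    def test_module_ids_deterministic_and_members_at_least_two(self, scoring):
        rng = np.random.default_rng(12)
        records = plant(rng, "".join(rng.choice(AA, 9)), 3, 10)
        plma = build_plma(records, scoring=scoring)
        modules = extract_modules(extract_blocks(plma))
        assert [m.id for m in modules] == \
            [f"B{i}" for i in range(1, len(modules) + 1)]
        assert all(len(m.member_sequences) >= 2 for m in modules)


class TestPlantedMotifRecovery:
    def test_recovers_planted_subsets_in_most_trials(self, scoring):
        """Motifs of length >= 8 at <= 15% pairwise divergence are found
        with exactly the planted member set in >= 90% of 50 trials."""
        rng = np.random.default_rng(2024)
        hits = 0
        trials = 50
        for _ in range(trials):
            motif = rng.choice(len(AA), size=10,
                               p=np.full(20, 0.05))
            carriers = {0, 1, 2}
            records = []
            for i in range(5):
                flank_l = "".join(rng.choice(AA, 15))
                flank_r = "".join(rng.choice(AA, 15))
                if i in carriers:
                    copy = motif.copy()
                    hit = rng.random(len(copy)) < 0.075
                    for k in np.nonzero(hit)[0]:
                        copy[k] = rng.integers(20)
                    core = "".join(AA[copy])
                else:
                    core = "".join(rng.choice(AA, len(motif)))
                records.append(
                    ProteinRecord(id=f"S{i}", sequence=flank_l + core + flank_r)
                )
            plma = build_plma(records, scoring=scoring)
            modules = extract_modules(extract_blocks(plma))
            if any(m.member_sequences == {"S0", "S1", "S2"}
                   for m in modules):
                hits += 1
        assert hits >= 0.9 * trials
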