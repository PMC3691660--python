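import numpy as np
import pytest

from transcensus.io_formats import AlignmentHit, Contig, ReadAssignment
from transcensus.library_partition import (
    LibraryPartition,
    PartitionError,
    classify_by_origin,
    direct_subtraction,
    indirect_subtraction,
    partition_summary,
)


def contig(cid, reads, length=100):
    return Contig(cid, "A" * length, frozenset(reads), 1.0)


def hit(q, s, cov=0.9, e=1e-60, qlen=100, bits=200.0):
    alen = int(cov * qlen)
    return AlignmentHit(q, s, 95.0, alen, e, bits, query_length=qlen)


class TestClassifyByOrigin:
    def test_single_origin_and_mixed(self):
        contigs = [
            contig("c1", ["r1", "r2", "r3"]),
            contig("c2", ["r4", "r5"]),
            contig("c3", ["r6"]),
        ]
        assignments = [
            ReadAssignment("r1", "A", "c1"),
            ReadAssignment("r2", "A", "c1"),
            ReadAssignment("r3", "A", "c1"),
            ReadAssignment("r4", "A", "c2"),
            ReadAssignment("r5", "B", "c2"),
            ReadAssignment("r6", "B", "c3"),
        ]
        part = classify_by_origin(contigs, assignments)
        assert part.specific_a == {"c1"}
        assert part.common == {"c2"}
        assert part.specific_b == {"c3"}

    def test_orphan_contig_is_an_error(self):
        with pytest.raises(PartitionError, match="c1"):
            classify_by_origin([contig("c1", ["rX"])], [])

    def test_membership_recoverable_from_assignment_table(self):
        # contig carries no read_ids; the table's contig column supplies them
        contigs = [Contig("c1", "ACGT" * 25)]
        assignments = [ReadAssignment("r1", "B", "c1")]
        part = classify_by_origin(contigs, assignments)
        assert part.specific_b == {"c1"}


class TestDirectSubtraction:
    def base_partition(self):
        return LibraryPartition({"a1", "a2"}, {"b1", "b2"}, {"x"})

    def test_passing_both_thresholds_moves(self):
        part = direct_subtraction(self.base_partition(), [hit("a1", "b1", 0.85, 1e-60)])
        assert "a1" in part.common
        assert part.specific_a == {"a2"}
        assert part.specific_b == {"b1", "b2"}  # subject does not move

    def test_failing_evalue_stays(self):
        part = direct_subtraction(self.base_partition(), [hit("a1", "b1", 0.85, 1e-40)])
        assert "a1" in part.specific_a

    def test_failing_coverage_stays(self):
        part = direct_subtraction(self.base_partition(), [hit("a1", "b1", 0.80, 1e-60)])
        assert "a1" in part.specific_a  # coverage must be strictly > 0.80

    def test_hit_on_common_contig_ignored(self):
        part = direct_subtraction(self.base_partition(), [hit("a1", "x")])
        assert "a1" in part.specific_a

    def test_bidirectional_qualification_moves_once(self):
        part = direct_subtraction(
            self.base_partition(), [hit("a1", "b1"), hit("b1", "a1")]
        )
        assert {"a1", "b1"} <= part.common
        stage, ma, mb = part.stage_log[0]
        assert ma == {"a1"} and mb == {"b1"}


class TestIndirectSubtraction:
    def test_shared_subject_moves_both(self):
        part = LibraryPartition({"a1"}, {"b1"}, set())
        part = indirect_subtraction(
            part, [hit("a1", "ENSDART0001", e=1e-10)], [hit("b1", "ENSDART0001", e=1e-10)]
        )
        assert part.common == {"a1", "b1"}

    def test_disjoint_subjects_move_nothing(self):
        part = LibraryPartition({"a1"}, {"b1"}, set())
        part = indirect_subtraction(
            part, [hit("a1", "s1", e=1e-10)], [hit("b1", "s2", e=1e-10)]
        )
        assert part.common == set()

    def test_evalue_threshold_is_inclusive(self):
        part = LibraryPartition({"a1"}, {"b1"}, set())
        part = indirect_subtraction(
            part, [hit("a1", "s1", e=1e-06)], [hit("b1", "s1", e=1e-06)]
        )
        assert part.common == {"a1", "b1"}

    def test_single_pass_no_fixpoint_iteration(self):
        # a2 shares subject s2 only with a1 (same library), and a1 shares s1
        # with b1: a1 and b1 move, but the pass must not chain through the
        # moved a1 to drag a2 along
        part = LibraryPartition({"a1", "a2"}, {"b1"}, set())
        part = indirect_subtraction(
            part,
            [hit("a1", "s1", e=1e-10), hit("a2", "s2", e=1e-10), hit("a1", "s2", e=1e-10)],
            [hit("b1", "s1", e=1e-10)],
        )
        assert part.common == {"a1", "b1"}
        assert part.specific_a == {"a2"}


class TestBookkeepingAndInvariants:
    def test_no_hits_is_identity(self):
        part = LibraryPartition({"a1"}, {"b1"}, {"x"})
        before = (set(part.specific_a), set(part.specific_b), set(part.common))
        part = direct_subtraction(part, [])
        part = indirect_subtraction(part, [], [])
        assert (part.specific_a, part.specific_b, part.common) == before
        assert all(not ma and not mb for _, ma, mb in part.stage_log)

    def test_summary_reconstructs_initial_counts(self):
        part = LibraryPartition({"a1", "a2", "a3"}, {"b1", "b2"}, set())
        # mutual alignment: the search is run in both directions
        direct_subtraction(part, [hit("a1", "b1"), hit("b1", "a1")])
        summary = partition_summary(part)
        assert summary["initial_a"] == 3
        assert summary["initial_b"] == 2
        assert summary["final_a"] == 2
        assert summary["final_b"] == 1
        assert summary["final_common"] == 2
        assert summary["total"] == 5

    def test_conservation_and_monotonicity_random_inputs(self, rng):
        """Total count invariant, common non-decreasing, across random
        subtraction inputs (threshold-passing hits chosen at random)."""
        ids_a = {f"a{i}" for i in range(40)}
        ids_b = {f"b{i}" for i in range(40)}
        part = LibraryPartition(set(ids_a), set(ids_b), {f"x{i}" for i in range(20)})
        total = part.total()
        all_ids = sorted(ids_a | ids_b)
        for stage in range(4):
            n_common_before = len(part.common)
            hits = [
                hit(
                    str(rng.choice(all_ids)),
                    str(rng.choice(all_ids)),
                    cov=float(rng.uniform(0.5, 1.0)),
                    e=float(10.0 ** rng.uniform(-80, -30)),
                )
                for _ in range(30)
            ]
            direct_subtraction(part, hits, stage=f"s{stage}")
            assert part.total() == total
            assert len(part.common) >= n_common_before
            assert not (part.specific_a & part.specific_b)

    def test_order_independence_within_stage(self, rng):
        hits = [
            hit(f"a{i}", f"b{j}", cov=float(rng.uniform(0.7, 1.0)),
                e=float(10.0 ** rng.uniform(-70, -40)))
            for i in range(20) for j in rng.integers(0, 20, size=2)
        ]
        def run(hit_order):
            part = LibraryPartition(
                {f"a{i}" for i in range(20)}, {f"b{i}" for i in range(20)}, set()
            )
            return direct_subtraction(part, hit_order).common

        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert run(hits) == run(shuffled) == run(list(reversed(hits)))

    def test_direct_subtraction_agrees_with_brute_force(self, rng):
        """Set-based implementation vs an O(n^2) oracle that applies the
        thresholds literally to every (query, subject) pair."""
        n = 60
        ids_a = [f"a{i}" for i in range(n)]
        ids_b = [f"b{i}" for i in range(n)]
        hits = []
        for _ in range(200):
            q, s = (
                (str(rng.choice(ids_a)), str(rng.choice(ids_b)))
                if rng.random() < 0.5
                else (str(rng.choice(ids_b)), str(rng.choice(ids_a)))
            )
            hits.append(
                hit(q, s, cov=float(rng.uniform(0.6, 1.0)),
                    e=float(10.0 ** rng.uniform(-70, -30)))
            )
        part = LibraryPartition(set(ids_a), set(ids_b), set())
        part = direct_subtraction(part, hits)

        moved = set()
        for h in hits:  # oracle: literal threshold check on every pair
            if h.query_coverage() > 0.80 and h.e_value < 1e-50:
                if (h.query_id in set(ids_a) and h.subject_id in set(ids_b)) or (
                    h.query_id in set(ids_b) and h.subject_id in set(ids_a)
                ):
                    moved.add(h.query_id)
        assert part.common == moved
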