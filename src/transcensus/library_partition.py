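"""Classify contigs by library of origin and apply in-silico subtraction.

A contig assembled only from reads of one library looks library-specific,
but may in fact represent a shared transcript that the other library
captured as a different (non-overlapping or diverged) contig. Three
subtraction stages move such disguised shared transcripts into the common
fraction:

1. direct — mutual alignment between the two specific sets (high stringency:
   query coverage > 80%, e-value < 1e-50);
2. indirect — both specific sets aligned against a shared nucleotide
   reference; pairs hitting the same subject move (e <= 1e-06, coverage > 80%);
3. the same indirect rule against a protein database.

Stages 2 and 3 are one operation invoked with different hit tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import AlignmentHit, Contig, ReadAssignment

__all__ = [
    "LibraryPartition",
    "PartitionError",
    "classify_by_origin",
    "direct_subtraction",
    "indirect_subtraction",
    "partition_summary",
]

log = logging.getLogger("transcensus")

DIRECT_MIN_COV = 0.80
DIRECT_MAX_E = 1e-50
INDIRECT_MAX_E = 1e-06
INDIRECT_MIN_COV = 0.80


class PartitionError(ValueError):
    pass


@dataclass
class LibraryPartition:
    """Three-way split of a contig set, with a log of subtraction moves.

    The three sets are pairwise disjoint, their union is constant, and
    contigs only ever move specific -> common.
    """

    specific_a: set[str]
    specific_b: set[str]
    common: set[str]
    stage_log: list[tuple[str, frozenset[str], frozenset[str]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        if (
            self.specific_a & self.specific_b
            or self.specific_a & self.common
            or self.specific_b & self.common
        ):
            raise PartitionError("partition sets must be pairwise disjoint")

    @property
    def all_ids(self) -> set[str]:
        return self.specific_a | self.specific_b | self.common

    def total(self) -> int:
        return len(self.specific_a) + len(self.specific_b) + len(self.common)

    def fraction_of(self, contig_id: str) -> str:
        if contig_id in self.specific_a:
            return "A-specific"
        if contig_id in self.specific_b:
            return "B-specific"
        if contig_id in self.common:
            return "common"
        raise KeyError(contig_id)

    def _move_to_common(
        self, stage: str, from_a: set[str], from_b: set[str]
    ) -> None:
        if not from_a <= self.specific_a or not from_b <= self.specific_b:
            raise PartitionError(f"stage {stage}: moving ids not in specific sets")
        self.specific_a -= from_a
        self.specific_b -= from_b
        self.common |= from_a | from_b
        self.stage_log.append((stage, frozenset(from_a), frozenset(from_b)))


def classify_by_origin(
    contigs: Sequence[Contig],
    assignments: Sequence[ReadAssignment],
    tags: tuple[str, str] = ("A", "B"),
) -> LibraryPartition:
    """Partition contigs by read library of origin.

    A contig is specific to a library iff every member read carries that
    library's tag; contigs with reads of both tags are common. Membership
    comes from the contig's read_ids when present, otherwise from the
    assignment table's contig column. A contig with no resolvable reads is
    an error: origin cannot be established.
    """
    tag_a, tag_b = tags
    tag_of = {a.read_id: a.library_tag for a in assignments}
    members: dict[str, set[str]] = {c.id: set(c.read_ids) for c in contigs}
    for a in assignments:
        if a.contig_id is not None and a.contig_id in members:
            members[a.contig_id].add(a.read_id)

    spec_a: set[str] = set()
    spec_b: set[str] = set()
    common: set[str] = set()
    for c in contigs:
        seen_tags: set[str] = set()
        for rid in members[c.id]:
            if rid in tag_of:
                seen_tags.add(tag_of[rid])
        if not seen_tags:
            raise PartitionError(
                f"contig {c.id!r}: no member read found in the assignment table"
            )
        if seen_tags == {tag_a}:
            spec_a.add(c.id)
        elif seen_tags == {tag_b}:
            spec_b.add(c.id)
        else:
            common.add(c.id)
    return LibraryPartition(specific_a=spec_a, specific_b=spec_b, common=common)


def _passes(
    hit: AlignmentHit,
    qlen_of: Mapping[str, int] | None,
    min_cov: float,
    max_e: float,
    e_inclusive: bool,
) -> bool:
    e_ok = hit.e_value <= max_e if e_inclusive else hit.e_value < max_e
    if not e_ok:
        return False
    qlen = hit.query_length
    if qlen is None and qlen_of is not None:
        qlen = qlen_of.get(hit.query_id)
    if qlen is None:
        raise PartitionError(
            f"hit {hit.query_id}->{hit.subject_id}: query length unknown; "
            "supply a contig set or a qlen column"
        )
    return hit.query_coverage(qlen) > min_cov


def direct_subtraction(
    partition: LibraryPartition,
    cross_hits: Iterable[AlignmentHit],
    contigs: Sequence[Contig] | None = None,
    min_cov: float = DIRECT_MIN_COV,
    max_e: float = DIRECT_MAX_E,
    stage: str = "direct",
) -> LibraryPartition:
    """Move specific contigs with a strong cross-library alignment to common.

    ``cross_hits`` are alignments of A-specific queries against B-specific
    subjects and vice versa. A contig moves when at least one of its hits
    to the opposite specific set has query coverage > min_cov and e-value
    strictly below max_e. A contig qualifying in both directions moves once.
    Hits touching contigs already in the common fraction are ignored.
    """
    qlen_of = {c.id: len(c) for c in contigs} if contigs is not None else None
    move_a: set[str] = set()
    move_b: set[str] = set()
    for hit in cross_hits:
        q, s = hit.query_id, hit.subject_id
        if q in partition.common or s in partition.common:
            log.debug("direct subtraction: ignoring hit on common contig %s/%s", q, s)
            continue
        a_to_b = q in partition.specific_a and s in partition.specific_b
        b_to_a = q in partition.specific_b and s in partition.specific_a
        if not (a_to_b or b_to_a):
            continue
        if not _passes(hit, qlen_of, min_cov, max_e, e_inclusive=False):
            continue
        if a_to_b:
            move_a.add(q)
        else:
            move_b.add(q)
    partition._move_to_common(stage, move_a, move_b)
    return partition


def indirect_subtraction(
    partition: LibraryPartition,
    hits_a: Iterable[AlignmentHit],
    hits_b: Iterable[AlignmentHit],
    contigs: Sequence[Contig] | None = None,
    max_e: float = INDIRECT_MAX_E,
    min_cov: float = INDIRECT_MIN_COV,
    stage: str = "indirect",
) -> LibraryPartition:
    """Move specific contigs that hit the same shared-reference subject.

    ``hits_a``/``hits_b`` are alignments of the remaining A-/B-specific
    contigs against one shared reference collection (nucleotide or protein).
    After filtering (e-value <= max_e, coverage > min_cov, best HSP per
    query/subject pair), every subject hit from both sides causes all its
    A- and B-specific queries to move to common, in a single pass.
    """
    qlen_of = {c.id: len(c) for c in contigs} if contigs is not None else None

    def subjects_of(hits: Iterable[AlignmentHit], spec: set[str]) -> dict[str, set[str]]:
        best: dict[tuple[str, str], AlignmentHit] = {}
        for h in hits:
            if h.query_id not in spec:
                continue
            key = (h.query_id, h.subject_id)
            prev = best.get(key)
            if prev is None or (h.bit_score, -h.e_value) > (prev.bit_score, -prev.e_value):
                best[key] = h
        by_subject: dict[str, set[str]] = {}
        for (q, s), h in best.items():
            if _passes(h, qlen_of, min_cov, max_e, e_inclusive=True):
                by_subject.setdefault(s, set()).add(q)
        return by_subject

    subj_a = subjects_of(hits_a, partition.specific_a)
    subj_b = subjects_of(hits_b, partition.specific_b)
    shared = set(subj_a) & set(subj_b)
    move_a = set().union(*(subj_a[s] for s in shared)) if shared else set()
    move_b = set().union(*(subj_b[s] for s in shared)) if shared else set()
    partition._move_to_common(stage, move_a, move_b)
    return partition


def partition_summary(partition: LibraryPartition) -> dict:
    """Per-stage move counts and final fraction sizes.

    Replaying the stage log backwards reconstructs the initial specific
    counts, so initial - sum(moves) always equals the final counts.
    """
    stages = [
        {"stage": name, "moved_a": len(a), "moved_b": len(b)}
        for name, a, b in partition.stage_log
    ]
    moved_a = sum(s["moved_a"] for s in stages)
    moved_b = sum(s["moved_b"] for s in stages)
    return {
        "initial_a": len(partition.specific_a) + moved_a,
        "initial_b": len(partition.specific_b) + moved_b,
        "stages": stages,
        "final_a": len(partition.specific_a),
        "final_b": len(partition.specific_b),
        "final_common": len(partition.common),
        "total": partition.total(),
    }
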