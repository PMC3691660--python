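"""Microsatellite (SSR) detection and motif canonicalization.

Perfect tandem repeats of 2-6 bp units are reported when they reach the
polymorphism-relevant minimum repeat counts (6 for dinucleotides, 4 for
tri- through hexanucleotides). Motifs are primitive (not themselves a
repetition of a shorter unit — a degenerate hexamer tract like ACACAC x n
is reported as the dinucleotide AC); only whole repetitions count, so a
tract's span is unit_len x n_repeats. Motif families are collapsed by
canonicalization over cyclic rotations and the reverse complement, so AC
and GT tracts tally together.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .io_formats import Contig, OrfAnnotation

__all__ = [
    "SsrLocus",
    "DEFAULT_SSR_THRESHOLDS",
    "scan_ssrs",
    "canonicalize_motif",
    "is_primitive",
    "ssr_orf_overlap",
    "motif_frequency_table",
]

# minimum whole repetitions by unit length
DEFAULT_SSR_THRESHOLDS: dict[int, int] = {2: 6, 3: 4, 4: 4, 5: 4, 6: 4}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SsrLocus:
    """A perfect microsatellite tract, 1-based inclusive coordinates."""

    contig_id: str
    start: int
    end: int
    motif: str
    canonical_motif: str
    unit_len: int
    n_repeats: int
    compound: bool = False
    in_orf: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.unit_len * self.n_repeats:
            raise ValueError(
                f"SSR {self.contig_id}:{self.start}-{self.end}: span is not "
                f"unit_len x n_repeats"
            )

    def interval0(self) -> tuple[int, int]:
        return self.start - 1, self.end


def is_primitive(motif: str) -> bool:
    """True iff the motif is not a whole-number repetition of a shorter unit."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def canonicalize_motif(motif: str) -> str:
    """Lexicographically smallest cyclic rotation of the motif or its
    reverse complement (so AC, CA, GT and TG all canonicalize to AC)."""
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 1..6, got {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rc = motif.translate(_COMPLEMENT)[::-1]
    candidates = [
        s[i:] + s[:i] for s in (motif, rc) for i in range(len(motif))
    ]
    return min(candidates)


def scan_ssrs(
    contigs: Iterable[Contig],
    thresholds: Mapping[int, int] = DEFAULT_SSR_THRESHOLDS,
    max_interruption: int = 0,
) -> list[SsrLocus]:
    """All maximal perfect SSR tracts meeting the per-unit-length thresholds.

    Tracts containing N are broken at the N. Partial trailing repetitions
    are not counted (a 6.5-unit run reports 6 repeats over 6 whole units).
    Tracts of adjacent loci separated by at most ``max_interruption`` bases
    are each reported separately with the compound flag set.
    """
    loci: list[SsrLocus] = []
    for contig in contigs:
        seq = contig.sequence
        n = len(seq)
        contig_loci: list[SsrLocus] = []
        for k in sorted(thresholds):
            min_reps = thresholds[k]
            i = 0
            while i + k < n:
                if seq[i] != "N" and seq[i] == seq[i + k]:
                    j = i
                    while j + k < n and seq[j] != "N" and seq[j] == seq[j + k]:
                        j += 1
                    run_span = (j - i) + k  # full periodic stretch length
                    reps = run_span // k
                    motif = seq[i : i + k]
                    if reps >= min_reps and "N" not in motif and is_primitive(motif):
                        contig_loci.append(
                            SsrLocus(
                                contig_id=contig.id,
                                start=i + 1,
                                end=i + reps * k,
                                motif=motif,
                                canonical_motif=canonicalize_motif(motif),
                                unit_len=k,
                                n_repeats=reps,
                            )
                        )
                    i = j + 1
                else:
                    i += 1
        # drop loci contained in another locus of the same canonical motif
        kept = [
            loc
            for loc in contig_loci
            if not any(
                o.canonical_motif == loc.canonical_motif
                and (o.start, o.end) != (loc.start, loc.end)
                and o.start <= loc.start
                and loc.end <= o.end
                for o in contig_loci
            )
        ]
        # flag compound loci (abutting or overlapping neighbours)
        kept.sort(key=lambda l: (l.start, l.end))
        compound_idx: set[int] = set()
        for idx in range(len(kept) - 1):
            gap = kept[idx + 1].start - kept[idx].end - 1
            if gap <= max_interruption:
                compound_idx.update({idx, idx + 1})
        for idx, loc in enumerate(kept):
            loci.append(
                replace(loc, compound=idx in compound_idx) if idx in compound_idx else loc
            )
    return loci


def ssr_orf_overlap(
    loci: Sequence[SsrLocus],
    orfs: Sequence[OrfAnnotation],
) -> tuple[list[SsrLocus], dict]:
    """Annotate loci with ORF overlap and summarize.

    A locus is in an ORF iff its tract interval overlaps any ORF interval
    on the same contig. The summary tallies loci per unit length and the
    overall in-ORF fraction.
    """
    orf_by_contig: dict[str, list[tuple[int, int]]] = {}
    for o in orfs:
        orf_by_contig.setdefault(o.contig_id, []).append(o.interval0())
    annotated: list[SsrLocus] = []
    for loc in loci:
        s, e = loc.interval0()
        inside = any(
            s < oe and os_ < e for os_, oe in orf_by_contig.get(loc.contig_id, ())
        )
        annotated.append(replace(loc, in_orf=inside))
    per_unit: dict[int, int] = {}
    for loc in annotated:
        per_unit[loc.unit_len] = per_unit.get(loc.unit_len, 0) + 1
    n_in = sum(1 for l in annotated if l.in_orf)
    summary = {
        "total": len(annotated),
        "per_unit_len": dict(sorted(per_unit.items())),
        "in_orf": n_in,
        "in_orf_fraction": n_in / len(annotated) if annotated else 0.0,
    }
    return annotated, summary


def motif_frequency_table(loci: Sequence[SsrLocus]) -> dict[str, int]:
    """Locus counts by canonical motif (complementary families summed)."""
    table: dict[str, int] = {}
    for loc in loci:
        table[loc.canonical_motif] = table.get(loc.canonical_motif, 0) + 1
    return dict(sorted(table.items(), key=lambda kv: (-kv[1], kv[0])))
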