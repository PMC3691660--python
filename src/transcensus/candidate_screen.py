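"""Threshold-based screening of the assembly for target gene panels.

Two screens share the machinery: a sex-determination gene panel searched
with translated/nucleotide alignments (discarding hits with e-value above
1e-03 or fewer than 50 positive-matching positions), and a
presence/absence screen for the 13 mitochondrial polypeptide genes at a
1e-10 e-value cutoff. For the panel screen, each contig keeps only its
best homolog query by bit score, and candidate contigs per gene are ranked
by bit score, then mean per-base coverage (singletons excluded), then the
translated-aligned fraction of contig length when available, with optional
user-supplied evidence scores as further tie-breakers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import AlignmentHit, Contig
from .library_partition import LibraryPartition

__all__ = [
    "GeneScreenResult",
    "MtGenePresence",
    "screen_genes",
    "screen_mt_genes",
]

SCREEN_MAX_E = 1e-03
SCREEN_MIN_POSITIVES = 50
MT_MAX_E = 1e-10


@dataclass(frozen=True)
class GeneScreenResult:
    gene_symbol: str
    detected: bool
    best_contig: str | None
    supporting_hits: tuple[AlignmentHit, ...]
    fraction: str | None  # A-specific / B-specific / common
    mean_coverage: float | None
    bit_score: float | None

    def __post_init__(self) -> None:
        if self.detected == (self.best_contig is None):
            raise ValueError("detected iff a best contig exists")


@dataclass(frozen=True)
class MtGenePresence:
    gene: str
    present: bool
    best_identity: float | None
    best_e_value: float | None
    best_contig: str | None


def _best_per_contig(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Per matched contig (subject), the homolog query with the highest bit
    score; ties by lower e-value then lexicographic query id."""
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        prev = best.get(h.subject_id)
        if prev is None:
            best[h.subject_id] = h
            continue
        key = (h.bit_score, -h.e_value, h.query_id < prev.query_id)
        prev_key = (prev.bit_score, -prev.e_value, False)
        if key[:2] > prev_key[:2] or (key[:2] == prev_key[:2] and key[2]):
            best[h.subject_id] = h
    return best


def screen_genes(
    hits_by_gene: Mapping[str, Sequence[AlignmentHit]],
    partition: LibraryPartition | None,
    contigs: Sequence[Contig],
    max_e: float = SCREEN_MAX_E,
    min_positives: int = SCREEN_MIN_POSITIVES,
    aligned_fraction: Mapping[str, float] | None = None,
    evidence_scores: Mapping[str, float] | None = None,
) -> list[GeneScreenResult]:
    """Screen each gene's hit set against the assembly.

    Hits are per-HSP: an HSP with e-value > max_e or positives < min_positives
    is discarded. Queries are homolog sequences labelled by gene; subjects
    are contigs. Ranking of candidate contigs per gene: bit score, then
    mean per-base coverage with singletons (contigs with <= 1 member read)
    excluded from the coverage criterion, then the translated-aligned
    fraction of contig length and any user-supplied evidence score when
    given, then lexicographic contig id.
    """
    cov_of = {c.id: c.mean_coverage for c in contigs}
    singleton = {c.id: len(c.read_ids) <= 1 for c in contigs}
    aligned_fraction = aligned_fraction or {}
    evidence_scores = evidence_scores or {}

    results: list[GeneScreenResult] = []
    for gene in sorted(hits_by_gene):
        passing = [
            h
            for h in hits_by_gene[gene]
            if h.e_value <= max_e and h.positives >= min_positives
        ]
        if not passing:
            results.append(
                GeneScreenResult(
                    gene_symbol=gene, detected=False, best_contig=None,
                    supporting_hits=(), fraction=None,
                    mean_coverage=None, bit_score=None,
                )
            )
            continue
        per_contig = _best_per_contig(passing)

        def rank(item: tuple[str, AlignmentHit]):
            cid, h = item
            coverage = 0.0 if singleton.get(cid, True) else cov_of.get(cid, 0.0)
            return (
                -h.bit_score,
                -coverage,
                -aligned_fraction.get(cid, 0.0),
                -evidence_scores.get(cid, 0.0),
                h.e_value,
                cid,
            )

        best_cid, best_hit = min(per_contig.items(), key=rank)
        fraction = None
        if partition is not None and best_cid in partition.all_ids:
            fraction = partition.fraction_of(best_cid)
        results.append(
            GeneScreenResult(
                gene_symbol=gene,
                detected=True,
                best_contig=best_cid,
                supporting_hits=tuple(passing),
                fraction=fraction,
                mean_coverage=cov_of.get(best_cid),
                bit_score=best_hit.bit_score,
            )
        )
    return results


def screen_mt_genes(
    hits_by_gene: Mapping[str, Sequence[AlignmentHit]],
    max_e: float = MT_MAX_E,
) -> list[MtGenePresence]:
    """Presence/absence of mitochondrial polypeptide genes in the assembly.

    One query per gene; a gene is present iff it has at least one hit with
    e-value <= max_e. The best passing hit (highest bit score) supplies
    the reported identity and contig.
    """
    out: list[MtGenePresence] = []
    for gene in sorted(hits_by_gene):
        passing = [h for h in hits_by_gene[gene] if h.e_value <= max_e]
        if not passing:
            out.append(MtGenePresence(gene, False, None, None, None))
            continue
        best = max(passing, key=lambda h: (h.bit_score, -h.e_value))
        out.append(
            MtGenePresence(
                gene=gene,
                present=True,
                best_identity=best.percent_identity,
                best_e_value=best.e_value,
                best_contig=best.subject_id,
            )
        )
    return out
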