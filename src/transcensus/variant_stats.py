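"""Post-processing of called variants.

Pyrosequencing over- and under-calls concentrate around repetitive
stretches, so variants beside short tandem repeats (including
homopolymers) are unreliable and are removed before any statistic is
computed. Retained SNPs are classified as transitions/transversions and,
against an ORF annotation, as synonymous/non-synonymous; the per-contig
ratio (Ka + 1)/(Ks + 1) — a raw pseudocounted count ratio, not a
rate-normalized estimator — flags contigs putatively under diversifying
selection when it exceeds 1 (equivalently Ka > Ks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .io_formats import Contig, OrfAnnotation, VariantRecord

__all__ = [
    "VariantClassSummary",
    "ContigVariantSummary",
    "left_normalize_indels",
    "find_repeat_tracts",
    "filter_repeat_adjacent",
    "classify_ts_tv",
    "classify_coding_effect",
    "summarize_variants",
]

log = logging.getLogger("transcensus")

REPEAT_MIN_UNITS = 4
REPEAT_MAX_UNIT_LEN = 6
REPEAT_PROXIMITY = 1

REPEAT_ADJACENT = "REPEAT_ADJACENT"

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# INDEL left-normalization
# ---------------------------------------------------------------------------


def _normalize_one(pos0: int, ref: str, alt: str, seq: str) -> tuple[int, str, str]:
    """Parsimonious left-aligned representation of (pos0, ref, alt) on seq."""
    ref, alt = list(ref), list(alt)
    changed = True
    while changed:
        changed = False
        # right-trim shared trailing base; extend left when an allele empties
        while ref and alt and ref[-1] == alt[-1]:
            if len(ref) == 1 and len(alt) == 1:
                break
            if pos0 == 0 and (len(ref) == 1 or len(alt) == 1):
                break  # already anchored at the contig start
            ref.pop()
            alt.pop()
            changed = True
            if not ref or not alt:
                pos0 -= 1
                base = seq[pos0]
                ref.insert(0, base)
                alt.insert(0, base)
        # left-trim shared leading base while both alleles keep length >= 2
        while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
            ref.pop(0)
            alt.pop(0)
            pos0 += 1
            changed = True
    return pos0, "".join(ref), "".join(alt)


def left_normalize_indels(
    variants: Iterable[VariantRecord],
    contigs: Sequence[Contig],
) -> list[VariantRecord]:
    """Shift INDELs to their leftmost equivalent representation.

    Two VCF records represent the same haplotype when replacing the REF
    span with ALT yields the same sequence; within a repeat tract many
    positions qualify and callers may emit any of them. Normalization
    right-trims shared trailing bases (extending left through the contig
    when an allele empties) and left-trims shared leading bases down to
    the single VCF anchor. SNPs pass through unchanged. REF alleles are
    validated against the contig sequence.
    """
    by_id = {c.id: c for c in contigs}
    out: list[VariantRecord] = []
    for v in variants:
        contig = by_id.get(v.contig_id)
        if contig is None:
            raise ValueError(f"variant on unknown contig {v.contig_id!r}")
        s, e = v.interval0()
        if contig.sequence[s:e] != v.ref_allele:
            raise ValueError(
                f"variant {v.contig_id}:{v.position}: REF {v.ref_allele!r} does "
                f"not match contig sequence {contig.sequence[s:e]!r}"
            )
        if v.is_snp or v.ref_allele == v.alt_allele:
            out.append(v)
            continue
        pos0, ref, alt = _normalize_one(
            v.position - 1, v.ref_allele, v.alt_allele, contig.sequence
        )
        out.append(
            replace(v, position=pos0 + 1, ref_allele=ref, alt_allele=alt)
        )
    return out


# ---------------------------------------------------------------------------
# Repeat-adjacency filter
# ---------------------------------------------------------------------------


def find_repeat_tracts(
    sequence: str,
    min_units: int = REPEAT_MIN_UNITS,
    max_unit_len: int = REPEAT_MAX_UNIT_LEN,
) -> list[tuple[int, int]]:
    """Maximal perfect tandem tracts of >= min_units repetitions.

    Motif lengths 1..max_unit_len (homopolymers included); returns merged
    0-based half-open intervals. The whole periodic stretch counts as the
    tract, including a partial trailing repetition (AAAAAGA..A x 4.5 is
    repeat context along its full span). N never matches, so tracts break
    at N.
    """
    n = len(sequence)
    tracts: list[tuple[int, int]] = []
    for k in range(1, max_unit_len + 1):
        i = 0
        while i + k < n:
            if sequence[i] != "N" and sequence[i] == sequence[i + k]:
                j = i
                while j + k < n and sequence[j] != "N" and sequence[j] == sequence[j + k]:
                    j += 1
                # positions i..j-1 satisfy s[p] == s[p+k]; tract spans i..j+k-1
                tract_len = (j - i) + k
                if tract_len // k >= min_units:
                    tracts.append((i, i + tract_len))
                i = j + 1
            else:
                i += 1
    if not tracts:
        return []
    tracts.sort()
    merged = [tracts[0]]
    for s, e in tracts[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def filter_repeat_adjacent(
    variants: Iterable[VariantRecord],
    contigs: Sequence[Contig],
    min_units: int = REPEAT_MIN_UNITS,
    max_unit_len: int = REPEAT_MAX_UNIT_LEN,
    proximity: int = REPEAT_PROXIMITY,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split variants into (retained, removed-as-repeat-adjacent).

    A variant is removed iff its affected interval overlaps a repeat tract
    or lies within ``proximity`` positions of one (proximity = 1 removes
    immediately adjacent variants, i.e. zero intervening bases). Removed
    records carry the REPEAT_ADJACENT flag. Idempotent: re-filtering the
    retained set removes nothing.
    """
    tract_cache: dict[str, list[tuple[int, int]]] = {}
    by_id = {c.id: c for c in contigs}
    retained: list[VariantRecord] = []
    removed: list[VariantRecord] = []
    for v in variants:
        contig = by_id.get(v.contig_id)
        if contig is None:
            raise ValueError(f"variant on unknown contig {v.contig_id!r}")
        if v.contig_id not in tract_cache:
            tract_cache[v.contig_id] = find_repeat_tracts(
                contig.sequence, min_units, max_unit_len
            )
        vs, ve = v.interval0()
        hit = False
        for ts, te in tract_cache[v.contig_id]:
            gap = max(ts - ve, vs - te)  # < 0 means overlap
            if gap <= proximity - 1 or gap < 0:
                hit = True
                break
            if ts - ve > proximity:  # tracts sorted: nothing further can match
                break
        # gap semantics: adjacent intervals have gap 0 bases between them
        if hit:
            removed.append(v.with_flag(REPEAT_ADJACENT))
        else:
            retained.append(v)
    return retained, removed


# ---------------------------------------------------------------------------
# SNP classification
# ---------------------------------------------------------------------------


def classify_ts_tv(snp: VariantRecord) -> str:
    """'transition' for A<->G and C<->T, 'transversion' otherwise."""
    if not snp.is_snp:
        raise ValueError(f"not a SNP: {snp.ref_allele}>{snp.alt_allele}")
    r, a = snp.ref_allele, snp.alt_allele
    if (r in PURINES and a in PURINES) or (r in PYRIMIDINES and a in PYRIMIDINES):
        return "transition"
    return "transversion"


def classify_coding_effect(
    snp: VariantRecord,
    orf: OrfAnnotation,
    contig: Contig,
) -> str:
    """'synonymous', 'non_synonymous' or 'non_coding' for a SNP on a contig.

    The SNP's codon is read in the ORF's frame (strand-aware, standard
    genetic code); identical amino acids before/after the substitution
    mean synonymous, anything else (including stop gain/loss) is
    non-synonymous. SNPs outside the ORF, in an incomplete trailing codon,
    or in a codon containing N are non_coding (the last with a warning).
    """
    if not snp.is_snp:
        raise ValueError("coding effect is defined for SNPs only")
    if orf.contig_id != contig.id:
        raise ValueError("ORF does not belong to the supplied contig")
    pos0 = snp.position - 1
    start0, end0 = orf.interval0()
    if not (start0 <= pos0 < end0):
        return "non_coding"
    seq = contig.sequence
    if orf.strand == "+":
        offset = pos0 - start0
        codon_start = start0 + 3 * (offset // 3)
        codon_end = codon_start + 3
        if codon_end > end0:
            return "non_coding"  # incomplete trailing codon
        codon = seq[codon_start:codon_end]
        within = pos0 - codon_start
        ref_base, alt_base = snp.ref_allele, snp.alt_allele
    else:
        offset = (end0 - 1) - pos0  # distance from the strand's 5' end
        codon_end = end0 - 3 * (offset // 3)
        codon_start = codon_end - 3
        if codon_start < start0:
            return "non_coding"
        codon = revcomp(seq[codon_start:codon_end])
        within = (codon_end - 1) - pos0
        ref_base = snp.ref_allele.translate(_COMPLEMENT)
        alt_base = snp.alt_allele.translate(_COMPLEMENT)
    if codon[within] != ref_base:
        raise ValueError(
            f"variant {snp.contig_id}:{snp.position}: REF disagrees with contig"
        )
    if "N" in codon or "N" in alt_base:
        log.warning(
            "variant %s:%d: codon %s contains N, unscorable",
            snp.contig_id, snp.position, codon,
        )
        return "non_coding"
    mutated = codon[:within] + alt_base + codon[within + 1 :]
    return (
        "synonymous" if _CODON_TABLE[codon] == _CODON_TABLE[mutated] else "non_synonymous"
    )


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


@dataclass
class ContigVariantSummary:
    contig_id: str
    ts: int = 0
    tv: int = 0
    ka: int = 0
    ks: int = 0
    utr_snps: int = 0
    indels: int = 0

    @property
    def ratio(self) -> float:
        """(Ka + 1)/(Ks + 1); the +1 pseudocounts keep Ks = 0 finite."""
        return (self.ka + 1) / (self.ks + 1)

    @property
    def diversifying(self) -> bool:
        return self.ratio > 1  # equivalently ka > ks


@dataclass
class VariantClassSummary:
    per_contig: dict[str, ContigVariantSummary]
    retained_snps: int
    retained_indels: int
    removed_repeat_adjacent: int
    snp_density: float  # bp per SNP over the whole contig set
    indel_density: float
    mean_snps_per_contig: float  # over contigs containing >= 1 retained SNP
    mean_indels_per_contig: float
    diversifying_contigs: int
    diversifying_fraction: float  # over ALL contigs in the set
    ts: int
    tv: int
    ka: int
    ks: int
    utr_snps: int


def _select_orf(orfs: Sequence[OrfAnnotation]) -> dict[str, OrfAnnotation]:
    """One ORF per contig: alignment-derived frames beat predictions,
    then the longest span, then the leftmost."""
    chosen: dict[str, OrfAnnotation] = {}
    for o in orfs:
        prev = chosen.get(o.contig_id)
        if prev is None:
            chosen[o.contig_id] = o
            continue
        rank = (o.source == "blast_hsp", o.end - o.start, -o.start)
        prev_rank = (prev.source == "blast_hsp", prev.end - prev.start, -prev.start)
        if rank > prev_rank:
            chosen[o.contig_id] = o
    return chosen


def summarize_variants(
    variants: Iterable[VariantRecord],
    orfs: Sequence[OrfAnnotation],
    contigs: Sequence[Contig],
    min_units: int = REPEAT_MIN_UNITS,
    max_unit_len: int = REPEAT_MAX_UNIT_LEN,
    proximity: int = REPEAT_PROXIMITY,
    normalize: bool = True,
) -> tuple[VariantClassSummary, list[VariantRecord]]:
    """Full variant post-processing: normalize, filter, classify, tally.

    Returns the summary and the removed (repeat-adjacent) records. All
    statistics are computed on the post-filter set. Densities are total
    contig length per retained variant; means are per variant-containing
    contig; the diversifying fraction is over all contigs supplied.
    INDELs are never classified for coding effect.
    """
    variants = list(variants)
    if normalize:
        variants = left_normalize_indels(variants, contigs)
    retained, removed = filter_repeat_adjacent(
        variants, contigs, min_units, max_unit_len, proximity
    )
    orf_of = _select_orf(orfs)
    by_contig = {c.id: c for c in contigs}

    per_contig: dict[str, ContigVariantSummary] = {}
    for v in retained:
        summ = per_contig.setdefault(v.contig_id, ContigVariantSummary(v.contig_id))
        if v.is_snp:
            if classify_ts_tv(v) == "transition":
                summ.ts += 1
            else:
                summ.tv += 1
            orf = orf_of.get(v.contig_id)
            effect = (
                classify_coding_effect(v, orf, by_contig[v.contig_id])
                if orf is not None
                else "non_coding"
            )
            if effect == "synonymous":
                summ.ks += 1
            elif effect == "non_synonymous":
                summ.ka += 1
            else:
                summ.utr_snps += 1
        elif v.is_indel:
            summ.indels += 1

    n_snps = sum(s.ts + s.tv for s in per_contig.values())
    n_indels = sum(s.indels for s in per_contig.values())
    total_len = sum(len(c) for c in contigs)
    snp_contigs = sum(1 for s in per_contig.values() if s.ts + s.tv > 0)
    indel_contigs = sum(1 for s in per_contig.values() if s.indels > 0)
    diversifying = sum(
        1 for s in per_contig.values() if (s.ts + s.tv) > 0 and s.diversifying
    )
    summary = VariantClassSummary(
        per_contig=per_contig,
        retained_snps=n_snps,
        retained_indels=n_indels,
        removed_repeat_adjacent=len(removed),
        snp_density=total_len / n_snps if n_snps else float("inf"),
        indel_density=total_len / n_indels if n_indels else float("inf"),
        mean_snps_per_contig=n_snps / snp_contigs if snp_contigs else 0.0,
        mean_indels_per_contig=n_indels / indel_contigs if indel_contigs else 0.0,
        diversifying_contigs=diversifying,
        diversifying_fraction=diversifying / len(contigs) if contigs else 0.0,
        ts=sum(s.ts for s in per_contig.values()),
        tv=sum(s.tv for s in per_contig.values()),
        ka=sum(s.ka for s in per_contig.values()),
        ks=sum(s.ks for s in per_contig.values()),
        utr_snps=sum(s.utr_snps for s in per_contig.values()),
    )
    return summary, removed
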