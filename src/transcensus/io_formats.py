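"""Readers and writers for the external formats the pipeline touches.

External files use the conventions of their formats (1-based inclusive
coordinates for VCF, BLAST tabular and ORF tables); everything internal is
0-based half-open. The conversion happens exactly once, in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "Contig",
    "ReadAssignment",
    "AlignmentHit",
    "VariantRecord",
    "OrfAnnotation",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_hits_tabular",
    "write_hits_tabular",
    "read_vcf_minimal",
    "write_vcf_minimal",
    "read_assignments",
    "write_assignments",
    "read_orf_table",
    "write_orf_table",
    "assignments_from_sam",
]

log = logging.getLogger("transcensus")

TOOL_VERSION = "transcensus 0.1.0"

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A malformed external file (bad syntax, bad value, broken invariant)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contig:
    """An assembled consensus sequence.

    ``read_ids`` lists the member reads when membership is known; a contig
    with no member reads is a singleton (one underlying read whose identity
    was not tracked), so its mean coverage cannot exceed 1.
    """

    id: str
    sequence: str
    read_ids: frozenset[str] = frozenset()
    mean_coverage: float = 0.0

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"contig {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"contig {self.id!r}: invalid characters {sorted(bad)}"
            )
        if self.mean_coverage < 0:
            raise FormatError(f"contig {self.id!r}: negative coverage")
        if not self.read_ids and self.mean_coverage > 1:
            raise FormatError(
                f"contig {self.id!r}: singleton (no member reads) with "
                f"mean coverage {self.mean_coverage} > 1"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadAssignment:
    """One read's library of origin and (optional) contig membership."""

    read_id: str
    library_tag: str
    contig_id: str | None = None


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise similarity-search hit (one HSP, tabular dialect).

    Coordinates are 1-based inclusive as printed by the search tool, with
    query_start <= query_end after strand normalization.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float
    positives: int = 0
    query_start: int = 0
    query_end: int = 0
    subject_start: int = 0
    subject_end: int = 0
    query_length: int | None = None

    def query_coverage(self, query_length: int | None = None) -> float:
        """Alignment length as a fraction of the query length.

        Values slightly above 1 are possible when the alignment contains
        gap columns; anything above 1.5 is rejected as inconsistent input.
        """
        qlen = self.query_length if query_length is None else query_length
        if qlen is None or qlen <= 0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: query length unknown"
            )
        cov = self.alignment_length / qlen
        if cov > 1.5:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: query coverage "
                f"{cov:.2f} > 1.5 — alignment length inconsistent with query"
            )
        if cov > 1.0:
            log.debug(
                "hit %s->%s: coverage %.3f > 1 (gapped alignment)",
                self.query_id, self.subject_id, cov,
            )
        return cov


@dataclass(frozen=True)
class VariantRecord:
    """A called sequence variant on a contig (VCF conventions, 1-based POS)."""

    contig_id: str
    position: int  # 1-based position of the first affected (REF) base
    ref_allele: str
    alt_allele: str
    filter_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(
                f"variant {self.contig_id}:{self.position}: POS must be >= 1"
            )
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or set(allele) - VALID_BASES:
                raise FormatError(
                    f"variant {self.contig_id}:{self.position}: bad allele "
                    f"{allele!r}"
                )

    @property
    def variant_class(self) -> str:
        if self.ref_allele == self.alt_allele:
            return "NO_VARIANT"
        if len(self.ref_allele) == len(self.alt_allele) == 1:
            return "SNP"
        if len(self.ref_allele) != len(self.alt_allele):
            return "INDEL"
        return "MNP"

    @property
    def is_snp(self) -> bool:
        return self.variant_class == "SNP"

    @property
    def is_indel(self) -> bool:
        return self.variant_class == "INDEL"

    def interval0(self) -> tuple[int, int]:
        """Affected reference interval, 0-based half-open."""
        return self.position - 1, self.position - 1 + len(self.ref_allele)

    def with_flag(self, flag: str) -> "VariantRecord":
        return replace(self, filter_flags=self.filter_flags | {flag})


@dataclass(frozen=True)
class OrfAnnotation:
    """An open reading frame on a contig, 1-based inclusive bounds.

    ``source`` records whether the frame came from a best protein alignment
    (blast_hsp) or an ab initio prediction; alignment-derived frames take
    precedence when both exist.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    source: str = "predicted"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"ORF on {self.contig_id}: bad strand {self.strand!r}")
        if self.source not in {"blast_hsp", "predicted"}:
            raise FormatError(f"ORF on {self.contig_id}: bad source {self.source!r}")
        if self.end - self.start + 1 < 3:
            raise FormatError(
                f"ORF on {self.contig_id}: span {self.start}-{self.end} < 3 bp"
            )
        if self.start < 1:
            raise FormatError(f"ORF on {self.contig_id}: start must be >= 1")

    def interval0(self) -> tuple[int, int]:
        return self.start - 1, self.end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[Contig]:
    """Read contig sequences from FASTA (sequences only, no membership).

    Record ids are the first whitespace-delimited token of the header;
    sequences are upper-cased; N is allowed. Duplicate ids are an error.
    """
    path = Path(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has no sequence")
        contigs.append(Contig(id=rec.id, sequence=seq))
    if not contigs:
        log.warning("%s: no FASTA records found", path)
    return contigs


def write_fasta(path: str | Path, contigs: Iterable[Contig], width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6, optionally with a 13th qlen column)
# ---------------------------------------------------------------------------

_BLAST6_COLS = 12


def _parse_float(token: str, path: Path, lineno: int, col: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: cannot parse {col} value {token!r}"
        ) from None


def _parse_int(token: str, path: Path, lineno: int, col: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: cannot parse {col} value {token!r}"
        ) from None


def read_hits_tabular(
    path: str | Path,
    dialect: str = "blast6",
    positives_col: int | None = None,
) -> list[AlignmentHit]:
    """Read a similarity-search hit table in 12-column tabular dialect.

    Columns: query, subject, %identity, alignment length, mismatches,
    gap opens, qstart, qend, sstart, send, e-value, bit score.
    ``blast6+qlen`` expects a 13th column with the query length.

    An e-value of 0 is accepted and means underflow (smaller than any
    threshold). The standard dialect has no positives column; when a table
    carries one (custom outfmt), name its 1-based index via positives_col.
    """
    if dialect not in {"blast6", "blast6+qlen"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    expected = _BLAST6_COLS + (1 if dialect == "blast6+qlen" else 0)
    if positives_col is not None:
        expected += 1
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != expected:
                raise FormatError(
                    f"{path}:{lineno}: expected {expected} columns "
                    f"(dialect {dialect}), got {len(fields)}"
                )
            e_value = _parse_float(fields[10], path, lineno, "e-value")
            if e_value < 0:
                raise FormatError(f"{path}:{lineno}: negative e-value")
            qs = _parse_int(fields[6], path, lineno, "qstart")
            qe = _parse_int(fields[7], path, lineno, "qend")
            if qs > qe:  # strand normalization: query always forward
                qs, qe = qe, qs
            extra = 12
            qlen: int | None = None
            if dialect == "blast6+qlen":
                qlen = _parse_int(fields[extra], path, lineno, "qlen")
                extra += 1
            positives = 0
            if positives_col is not None:
                positives = _parse_int(
                    fields[positives_col - 1], path, lineno, "positives"
                )
            hits.append(
                AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=_parse_float(fields[2], path, lineno, "identity"),
                    alignment_length=_parse_int(fields[3], path, lineno, "length"),
                    e_value=e_value,
                    bit_score=_parse_float(fields[11], path, lineno, "bit score"),
                    positives=positives,
                    query_start=qs,
                    query_end=qe,
                    subject_start=_parse_int(fields[8], path, lineno, "sstart"),
                    subject_end=_parse_int(fields[9], path, lineno, "send"),
                    query_length=qlen,
                )
            )
    return hits


def write_hits_tabular(path: str | Path, hits: Iterable[AlignmentHit]) -> None:
    """Write hits as 13-column tabular (qlen last; 0 when unknown)."""
    with open(path, "w") as fh:
        fh.write(f"# {TOOL_VERSION} hits blast6+qlen\n")
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, h.percent_identity,
                        h.alignment_length, 0, 0,
                        h.query_start, h.query_end,
                        h.subject_start, h.subject_end,
                        f"{h.e_value:g}", h.bit_score,
                        h.query_length if h.query_length is not None else 0,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF (minimal plain-text 4.x reader/writer)
# ---------------------------------------------------------------------------


def read_vcf_minimal(
    path: str | Path,
    contigs: Sequence[Contig] | None = None,
) -> list[VariantRecord]:
    """Read variant records from a plain-text VCF 4.x file.

    Multiallelic rows are split into one record per ALT allele. When a
    contig set is supplied, CHROM names and REF spans are validated against
    it. Existing FILTER values other than PASS/. are carried as flags.
    """
    path = Path(path)
    by_id = {c.id: c for c in contigs} if contigs is not None else None
    records: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(
                    f"{path}:{lineno}: VCF row needs >= 5 columns, got {len(fields)}"
                )
            chrom, pos_s, _id, ref, alts = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed POS {pos_s!r}") from None
            if by_id is not None:
                if chrom not in by_id:
                    raise FormatError(
                        f"{path}:{lineno}: CHROM {chrom!r} not in contig set"
                    )
                contig = by_id[chrom]
                if pos - 1 + len(ref) > len(contig):
                    raise FormatError(
                        f"{path}:{lineno}: REF span exceeds contig {chrom!r} length"
                    )
            flags: frozenset[str] = frozenset()
            if len(fields) >= 7 and fields[6] not in {".", "PASS", ""}:
                flags = frozenset(fields[6].split(";"))
            for alt in alts.split(","):
                records.append(
                    VariantRecord(
                        contig_id=chrom,
                        position=pos,
                        ref_allele=ref.upper(),
                        alt_allele=alt.upper(),
                        filter_flags=flags,
                    )
                )
    return records


def write_vcf_minimal(path: str | Path, records: Iterable[VariantRecord]) -> None:
    """Write records as plain-text VCF 4.2; filter flags go in FILTER."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={TOOL_VERSION}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            filt = ";".join(sorted(r.filter_flags)) if r.filter_flags else "PASS"
            fh.write(
                f"{r.contig_id}\t{r.position}\t.\t{r.ref_allele}\t"
                f"{r.alt_allele}\t.\t{filt}\t.\n"
            )


# ---------------------------------------------------------------------------
# Read-assignment and ORF tables (TSV)
# ---------------------------------------------------------------------------

NULL_CONTIG = "-"


def read_assignments(
    path: str | Path,
    allowed_tags: tuple[str, str] = ("A", "B"),
) -> list[ReadAssignment]:
    """Read a read_id / library_tag / contig_id table.

    contig_id "-" marks an unassembled read. Tags outside ``allowed_tags``
    and duplicate read ids are errors.
    """
    path = Path(path)
    tags = set(allowed_tags)
    out: list[ReadAssignment] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            read_id, tag, contig_id = fields
            if tag not in tags:
                raise FormatError(
                    f"{path}:{lineno}: unknown library tag {tag!r} "
                    f"(declared: {sorted(tags)})"
                )
            if read_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate read id {read_id!r}")
            seen.add(read_id)
            out.append(
                ReadAssignment(
                    read_id=read_id,
                    library_tag=tag,
                    contig_id=None if contig_id == NULL_CONTIG else contig_id,
                )
            )
    return out


def write_assignments(path: str | Path, assignments: Iterable[ReadAssignment]) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {TOOL_VERSION} read assignments: read_id\tlibrary_tag\tcontig_id\n")
        for a in assignments:
            fh.write(
                f"{a.read_id}\t{a.library_tag}\t"
                f"{a.contig_id if a.contig_id is not None else NULL_CONTIG}\n"
            )


def read_orf_table(path: str | Path) -> list[OrfAnnotation]:
    """Read ORF annotations: contig_id, start, end, strand, source (TSV)."""
    path = Path(path)
    out: list[OrfAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 columns, got {len(fields)}"
                )
            out.append(
                OrfAnnotation(
                    contig_id=fields[0],
                    start=_parse_int(fields[1], path, lineno, "start"),
                    end=_parse_int(fields[2], path, lineno, "end"),
                    strand=fields[3],
                    source=fields[4],
                )
            )
    return out


def write_orf_table(path: str | Path, orfs: Iterable[OrfAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {TOOL_VERSION} ORFs: contig_id\tstart\tend\tstrand\tsource\n")
        for o in orfs:
            fh.write(f"{o.contig_id}\t{o.start}\t{o.end}\t{o.strand}\t{o.source}\n")


# ---------------------------------------------------------------------------
# SAM adapter (optional sugar: membership only, primary alignments)
# ---------------------------------------------------------------------------


def assignments_from_sam(
    path: str | Path,
    tag_of_read,
) -> list[ReadAssignment]:
    """Extract read->contig assignments from a SAM file.

    Only primary alignments are used; unmapped reads become assignments
    with a null contig. ``tag_of_read`` maps a read id to its library tag
    (e.g. a prefix lookup).
    """
    import pysam

    out: list[ReadAssignment] = []
    seen: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_secondary or aln.is_supplementary:
                continue
            rid = aln.query_name
            if rid in seen:
                continue
            seen.add(rid)
            out.append(
                ReadAssignment(
                    read_id=rid,
                    library_tag=tag_of_read(rid),
                    contig_id=None if aln.is_unmapped else aln.reference_name,
                )
            )
    return out
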