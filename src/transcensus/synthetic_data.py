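"""Ground-truth fixture generation for every pipeline stage.

Emulates the study design the pipeline assumes: a closed population of
transcripts sampled by two sequencing libraries (one per individual), each
transcript captured independently by each library with a per-library
probability; an idealized joint assembly in which every captured
transcript becomes one contig whose read labels record the libraries that
saw it; paralog families that confound library-specificity; planted
variants of known transition/transversion, coding-effect and
repeat-adjacency status; and planted microsatellite tracts.

Every emitter is a pure function of (parameters, seed); each derives its
own random stream from (master seed, emitter name) so adding an emitter
never perturbs the others. Planted truth labels are verified at generation
time by running the package's own classifiers; a fixture that fails
verification is rejected rather than emitted.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    Contig,
    OrfAnnotation,
    ReadAssignment,
    VariantRecord,
    write_assignments,
    write_fasta,
    write_orf_table,
    write_vcf_minimal,
)
from .ssr_scan import scan_ssrs, canonicalize_motif
from .variant_stats import (
    classify_coding_effect,
    classify_ts_tv,
    filter_repeat_adjacent,
    find_repeat_tracts,
    left_normalize_indels,
)

__all__ = [
    "SyntheticTruth",
    "generate_population",
    "simulate_two_libraries",
    "plant_variants_and_ssrs",
    "sample_read_pool",
    "build_reference_hit_map",
    "emit_fixture",
]

BASES = np.array(list("ACGT"))
MIN_TRANSCRIPT_LEN = 300


def _rng(seed: int, emitter: str) -> np.random.Generator:
    """Independent stream per (master seed, emitter name)."""
    return np.random.default_rng([seed, zlib.crc32(emitter.encode()) & 0x7FFFFFFF])


@dataclass
class SyntheticTruth:
    """Everything the generator knows that the pipeline must recover."""

    seed: int
    n_transcripts: int = 0
    capture_prob_a: float = 0.0
    capture_prob_b: float = 0.0
    n1: int = 0
    n2: int = 0
    m: int = 0
    paralog_families: list[list[str]] = field(default_factory=list)
    fragmented_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_variants: list[dict] = field(default_factory=list)
    planted_ssrs: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["fragmented_pairs"] = [list(p) for p in self.fragmented_pairs]
        return json.dumps(d, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def generate_population(
    n: int,
    length_dist: tuple[float, float] = (500.0, 200.0),
    gc: float = 0.40,
    seed: int = 0,
    paralog_families: Sequence[tuple[int, float]] = (),
) -> tuple[list[Contig], SyntheticTruth]:
    """A population of ``n`` random transcripts.

    Lengths are log-normal with the given mean and sd (floored at 300 bp,
    the scale of a pyrosequencing read). ``paralog_families`` is a list of
    (family_size, identity) specs; each family is built by copying one base
    transcript with per-base substitution at rate 1 - identity, replacing
    family_size - 1 of the independent transcripts.
    """
    if n < 10:
        raise ValueError("population size must be >= 10")
    mean, sd = length_dist
    if mean <= 0 or sd < 0:
        raise ValueError("invalid length distribution parameters")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    extra = sum(size - 1 for size, _ in paralog_families)
    if extra >= n:
        raise ValueError("paralog families exceed the population size")
    rng = _rng(seed, "generate_population")
    # log-normal parametrized by the target arithmetic mean/sd
    sigma2 = np.log(1 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    lengths = np.maximum(
        MIN_TRANSCRIPT_LEN,
        rng.lognormal(mu, np.sqrt(sigma2), size=n - extra).astype(int),
    )
    transcripts = [
        Contig(id=f"t{i:05d}", sequence=_random_sequence(rng, int(L), gc))
        for i, L in enumerate(lengths)
    ]
    truth = SyntheticTruth(seed=seed, n_transcripts=n)
    next_id = n - extra
    for size, identity in paralog_families:
        if not 0 < identity < 1:
            raise ValueError("paralog identity must be in (0, 1)")
        base = transcripts[int(rng.integers(0, n - extra))]
        family = [base.id]
        for _ in range(size - 1):
            seq = np.array(list(base.sequence))
            mutate = rng.random(len(seq)) < (1 - identity)
            for pos in np.flatnonzero(mutate):
                choices = [b for b in "ACGT" if b != seq[pos]]
                seq[pos] = choices[int(rng.integers(0, 3))]
            tid = f"t{next_id:05d}"
            next_id += 1
            transcripts.append(Contig(id=tid, sequence="".join(seq)))
            family.append(tid)
        truth.paralog_families.append(family)
    return transcripts, truth


# ---------------------------------------------------------------------------
# Two-library sampling
# ---------------------------------------------------------------------------


def simulate_two_libraries(
    transcripts: Sequence[Contig],
    p_a: float,
    p_b: float,
    reads_per_captured: float = 3.0,
    read_len: tuple[float, float] = (350.0, 50.0),
    seed: int = 0,
    fragmentation: float = 0.0,
    truth: SyntheticTruth | None = None,
) -> tuple[list[Contig], list[ReadAssignment], SyntheticTruth]:
    """Sample the population with two libraries and idealize the assembly.

    Each transcript is captured independently by each library with its
    probability; a captured transcript yields at least one read. The
    idealized joint assembly makes one contig per transcript captured by
    either library, so contig read labels encode the true
    specific/common partition. With probability ``fragmentation``, a
    transcript captured by BOTH libraries is instead assembled as two
    non-overlapping half-transcript contigs, one per library — the
    disguised-shared case that indirect subtraction exists to repair.

    Truth records the two-occasion counts n1, n2, m.
    """
    if not (0 < p_a <= 1 and 0 < p_b <= 1):
        raise ValueError("capture probabilities must be in (0, 1]")
    rng = _rng(seed, "simulate_two_libraries")
    truth = truth or SyntheticTruth(seed=seed, n_transcripts=len(transcripts))
    truth.capture_prob_a, truth.capture_prob_b = p_a, p_b

    contigs: list[Contig] = []
    assignments: list[ReadAssignment] = []
    read_counter = 0
    n1 = n2 = m = 0

    def make_reads(
        contig_id: str, tag: str, n_reads: int, contig_len: int
    ) -> tuple[set[str], float]:
        nonlocal read_counter
        mean_rl, _ = read_len
        covered = 0
        ids: set[str] = set()
        for _ in range(n_reads):
            rid = f"r{read_counter:07d}"
            read_counter += 1
            ids.add(rid)
            assignments.append(
                ReadAssignment(read_id=rid, library_tag=tag, contig_id=contig_id)
            )
            covered += min(contig_len, int(mean_rl))
        return ids, covered / contig_len

    for t in transcripts:
        cap_a = rng.random() < p_a
        cap_b = rng.random() < p_b
        if cap_a:
            n1 += 1
        if cap_b:
            n2 += 1
        if cap_a and cap_b:
            m += 1
        if not (cap_a or cap_b):
            continue
        reads_a = 1 + rng.poisson(max(reads_per_captured - 1, 0)) if cap_a else 0
        reads_b = 1 + rng.poisson(max(reads_per_captured - 1, 0)) if cap_b else 0
        if cap_a and cap_b and rng.random() < fragmentation and len(t) >= 2 * MIN_TRANSCRIPT_LEN:
            half = len(t) // 2
            ids_l, cov_l = make_reads(f"{t.id}.L", "A", reads_a, half)
            ids_r, cov_r = make_reads(f"{t.id}.R", "B", reads_b, len(t) - half)
            contigs.append(Contig(f"{t.id}.L", t.sequence[:half], frozenset(ids_l), cov_l))
            contigs.append(Contig(f"{t.id}.R", t.sequence[half:], frozenset(ids_r), cov_r))
            truth.fragmented_pairs.append((f"{t.id}.L", f"{t.id}.R"))
            continue
        cid = f"c_{t.id}"
        rids: set[str] = set()
        cov = 0.0
        if cap_a:
            ids, c = make_reads(cid, "A", reads_a, len(t))
            rids |= ids
            cov += c
        if cap_b:
            ids, c = make_reads(cid, "B", reads_b, len(t))
            rids |= ids
            cov += c
        contigs.append(Contig(cid, t.sequence, frozenset(rids), cov))

    truth.n1, truth.n2, truth.m = n1, n2, m
    return contigs, assignments, truth


# ---------------------------------------------------------------------------
# Variant and SSR planting
# ---------------------------------------------------------------------------

# (effect, ts/tv) -> (reference codon, codon offset, ref base, alt base)
_CODING_TEMPLATES = {
    ("synonymous", "transition"): ("GGA", 2, "A", "G"),     # Gly -> Gly
    ("synonymous", "transversion"): ("GGA", 2, "A", "C"),   # Gly -> Gly
    ("non_synonymous", "transition"): ("ATG", 2, "G", "A"),  # Met -> Ile
    ("non_synonymous", "transversion"): ("ATG", 2, "G", "T"),  # Met -> Ile
}
_UTR_TEMPLATES = {
    "transition": ("A", "G"),
    "transversion": ("A", "C"),
}


class _MutableContig:
    def __init__(self, contig: Contig):
        self.id = contig.id
        self.seq = list(contig.sequence)
        self.coverage = contig.mean_coverage
        self.read_ids = contig.read_ids
        self.reserved: list[tuple[int, int]] = []  # 0-based half-open

    def free(self, start: int, end: int, margin: int = 10) -> bool:
        if start < 1 or end > len(self.seq) - 1:
            return False
        return all(
            end + margin <= rs or re + margin <= start for rs, re in self.reserved
        )

    def reserve(self, start: int, end: int) -> None:
        self.reserved.append((start, end))

    def write(self, start: int, text: str) -> None:
        self.seq[start : start + len(text)] = list(text)

    def freeze(self) -> Contig:
        return Contig(self.id, "".join(self.seq), self.read_ids, self.coverage)


def plant_variants_and_ssrs(
    contigs: Sequence[Contig],
    n_snp: int = 20,
    n_indel: int = 10,
    ts_fraction: float = 0.66,
    orf_fraction: float = 0.6,
    syn_fraction: float = 0.28,
    n_repeat_adjacent: int = 5,
    ssr_spec: Mapping[str, tuple[int, int]] | None = None,
    seed: int = 0,
    max_retries: int = 50,
) -> tuple[list[Contig], list[VariantRecord], list[OrfAnnotation], SyntheticTruth]:
    """Plant variants and microsatellites with known truth labels.

    Contig sequences are locally rewritten so that every planted item has
    exactly the intended reference context: SSR tracts are written with
    guard bases that stop them extending; ORFs cover the middle of a
    fraction of contigs; coding SNPs get template codons realizing each
    (synonymous/non-synonymous) x (transition/transversion) combination;
    ``n_repeat_adjacent`` extra SNPs are placed immediately after a planted
    homopolymer so the repeat-adjacency filter must remove exactly those.
    ``ssr_spec`` maps motif -> (n_repeats, n_loci).

    After placement the module's own classifiers re-derive every label;
    a placement whose labels disagree is re-drawn, and the fixture is
    rejected after ``max_retries`` failures (larger contigs help).
    """
    if not 0 <= ts_fraction <= 1 or not 0 <= syn_fraction <= 1:
        raise ValueError("fractions must be in [0, 1]")
    ssr_spec = dict(ssr_spec or {})
    for motif, (reps, _) in ssr_spec.items():
        canonicalize_motif(motif)  # validates primitivity and length
        if len(motif) * reps < 8:
            raise ValueError(f"SSR {motif!r} x {reps} too short to be unambiguous")

    rng = _rng(seed, "plant_variants_and_ssrs")
    muts = [_MutableContig(c) for c in contigs]
    big = [m for m in muts if len(m.seq) >= 120]
    if not big:
        raise ValueError("no contig long enough (>= 120 bp) for planting")

    truth = SyntheticTruth(seed=seed)
    orfs: list[OrfAnnotation] = []
    orf_of: dict[str, OrfAnnotation] = {}

    # --- ORFs over the middle third of a fraction of contigs (+ strand)
    for mc in big:
        if rng.random() >= orf_fraction:
            continue
        L = len(mc.seq)
        start0 = L // 3
        span = ((L // 3) // 3) * 3
        if span < 30:
            continue
        orf = OrfAnnotation(
            contig_id=mc.id, start=start0 + 1, end=start0 + span,
            strand="+", source="predicted",
        )
        orfs.append(orf)
        orf_of[mc.id] = orf

    def draw_contig(need_orf: bool | None = None) -> _MutableContig:
        pool = [
            m for m in big
            if need_orf is None or (m.id in orf_of) == need_orf
        ]
        if not pool:
            raise ValueError("no contig satisfies the placement constraint")
        return pool[int(rng.integers(0, len(pool)))]

    def place_clean(mc: _MutableContig, width: int, region: tuple[int, int] | None):
        """A position whose +-(width+margin) window stays repeat-free after
        rewriting; returns start0 or None."""
        lo, hi = region if region else (1, len(mc.seq) - width - 1)
        hi = min(hi, len(mc.seq) - width - 1)
        if hi <= lo:
            return None
        for _ in range(60):
            pos = int(rng.integers(lo, hi))
            if mc.free(pos, pos + width):
                return pos
        return None

    def window_clean(mc: _MutableContig, s: int, e: int, pad: int = 14) -> bool:
        """No repeat tract within 3 bases of [s, e) after the rewrite."""
        lo, hi = max(0, s - pad), min(len(mc.seq), e + pad)
        window = "".join(mc.seq[lo:hi])
        vs, ve = s - lo, e - lo
        return all(
            max(ts - ve, vs - te) >= 3 for ts, te in find_repeat_tracts(window)
        )

    # --- SSR tracts with guard bases
    for motif, (reps, n_loci) in ssr_spec.items():
        unit = len(motif)
        tract = motif * reps
        for _ in range(n_loci):
            placed = False
            for _ in range(max_retries):
                mc = draw_contig()
                pos = place_clean(mc, len(tract) + 2, None)
                if pos is None:
                    continue
                # guards break periodicity on both sides for every unit <= 6
                left_guard = "C" if motif[-1] != "C" else "G"
                right_guard = "C" if motif[0] != "C" else "G"
                mc.write(pos, left_guard + tract + right_guard)
                mc.reserve(pos, pos + len(tract) + 2)
                truth.planted_ssrs.append(
                    {
                        "contig": mc.id, "start": pos + 2,  # 1-based tract start
                        "motif": motif, "n_repeats": reps,
                    }
                )
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"could not place SSR {motif!r} x {reps}; use larger contigs"
                )

    variants: list[VariantRecord] = []

    def plant_snp(kind: str) -> None:
        """kind: 'coding', 'utr', 'repeat_adjacent'."""
        tstv = "transition" if rng.random() < ts_fraction else "transversion"
        for _ in range(max_retries):
            if kind == "coding":
                mc = draw_contig(need_orf=True)
                orf = orf_of[mc.id]
                effect = "synonymous" if rng.random() < syn_fraction else "non_synonymous"
                codon, off, ref, alt = _CODING_TEMPLATES[(effect, tstv)]
                s0, e0 = orf.start - 1, orf.end
                n_codons = (e0 - s0) // 3
                ci = int(rng.integers(0, n_codons))
                cpos = s0 + 3 * ci
                if not mc.free(cpos, cpos + 3):
                    continue
                original = "".join(mc.seq[cpos : cpos + 3])
                mc.write(cpos, codon)
                if not window_clean(mc, cpos, cpos + 3):
                    mc.write(cpos, original)
                    continue
                mc.reserve(cpos, cpos + 3)
                pos0 = cpos + off
                variants.append(VariantRecord(mc.id, pos0 + 1, ref, alt))
                truth.planted_variants.append(
                    {"contig": mc.id, "pos": pos0 + 1, "class": "SNP",
                     "tstv": tstv, "effect": effect, "repeat_adjacent": False}
                )
                return
            if kind == "utr":
                mc = draw_contig()
                ref, alt = _UTR_TEMPLATES[tstv]
                orf = orf_of.get(mc.id)
                # keep UTR SNPs outside the ORF
                region = (1, orf.start - 2) if orf and orf.start > 20 else None
                pos0 = place_clean(mc, 1, region)
                if pos0 is None:
                    continue
                if orf and orf.start - 1 <= pos0 < orf.end:
                    continue
                original = mc.seq[pos0]
                mc.write(pos0, ref)
                if not window_clean(mc, pos0, pos0 + 1):
                    mc.write(pos0, original)
                    continue
                mc.reserve(pos0, pos0 + 1)
                variants.append(VariantRecord(mc.id, pos0 + 1, ref, alt))
                truth.planted_variants.append(
                    {"contig": mc.id, "pos": pos0 + 1, "class": "SNP",
                     "tstv": tstv, "effect": "non_coding", "repeat_adjacent": False}
                )
                return
            # repeat-adjacent: homopolymer AAAA then the SNP right after it
            mc = draw_contig()
            pos0 = place_clean(mc, 7, None)
            if pos0 is None:
                continue
            ref, alt = ("C", "T") if tstv == "transition" else ("C", "G")
            mc.write(pos0, "G" + "AAAA" + ref + "G")
            mc.reserve(pos0, pos0 + 7)
            snp0 = pos0 + 5
            variants.append(VariantRecord(mc.id, snp0 + 1, ref, alt))
            truth.planted_variants.append(
                {"contig": mc.id, "pos": snp0 + 1, "class": "SNP",
                 "tstv": tstv, "effect": None, "repeat_adjacent": True}
            )
            return
        raise ValueError(f"could not place a {kind} SNP; use larger contigs")

    def plant_indel() -> None:
        for _ in range(max_retries):
            mc = draw_contig()
            pos0 = place_clean(mc, 4, None)
            if pos0 is None:
                continue
            # context ACGT: deleting the G cannot left-shift or touch a repeat
            original = "".join(mc.seq[pos0 : pos0 + 4])
            mc.write(pos0, "ACGT")
            if not window_clean(mc, pos0, pos0 + 4):
                mc.write(pos0, original)
                continue
            mc.reserve(pos0, pos0 + 4)
            variants.append(VariantRecord(mc.id, pos0 + 2, "CG", "C"))
            truth.planted_variants.append(
                {"contig": mc.id, "pos": pos0 + 2, "class": "INDEL",
                 "tstv": None, "effect": None, "repeat_adjacent": False}
            )
            return
        raise ValueError("could not place an INDEL; use larger contigs")

    orf_ids = set(orf_of)
    for _ in range(n_snp):
        wants_coding = bool(orf_ids) and rng.random() < 0.5
        plant_snp("coding" if wants_coding else "utr")
    for _ in range(n_repeat_adjacent):
        plant_snp("repeat_adjacent")
    for _ in range(n_indel):
        plant_indel()

    out_contigs = [mc.freeze() for mc in muts]

    _verify_fixture(out_contigs, variants, orfs, truth, ssr_spec)
    return out_contigs, variants, orfs, truth


def _verify_fixture(contigs, variants, orfs, truth, ssr_spec) -> None:
    """Re-derive every planted label with the pipeline's own classifiers."""
    by_id = {c.id: c for c in contigs}
    orf_of = {o.contig_id: o for o in orfs}
    normalized = left_normalize_indels(variants, contigs)
    retained, removed = filter_repeat_adjacent(normalized, contigs)
    removed_keys = {(v.contig_id, v.position) for v in removed}
    planted_adjacent = {
        (p["contig"], p["pos"]) for p in truth.planted_variants if p["repeat_adjacent"]
    }
    if removed_keys != planted_adjacent:
        raise AssertionError(
            "fixture rejected: repeat-adjacency filter disagrees with planting "
            f"(removed {sorted(removed_keys)}, planted {sorted(planted_adjacent)})"
        )
    by_key = {(v.contig_id, v.position): v for v in normalized}
    for p in truth.planted_variants:
        v = by_key[(p["contig"], p["pos"])]
        if p["class"] != v.variant_class:
            raise AssertionError("fixture rejected: variant class mismatch")
        if v.is_snp and p["tstv"] is not None:
            if classify_ts_tv(v) != p["tstv"]:
                raise AssertionError("fixture rejected: Ts/Tv mismatch")
        if v.is_snp and p["effect"] in {"synonymous", "non_synonymous", "non_coding"}:
            orf = orf_of.get(v.contig_id)
            effect = (
                classify_coding_effect(v, orf, by_id[v.contig_id])
                if orf is not None else "non_coding"
            )
            if effect != p["effect"]:
                raise AssertionError(
                    f"fixture rejected: coding effect mismatch at "
                    f"{v.contig_id}:{v.position} ({effect} != {p['effect']})"
                )
    if ssr_spec:
        found = scan_ssrs(contigs)
        planted = {
            (p["contig"], p["start"], canonicalize_motif(p["motif"]))
            for p in truth.planted_ssrs
        }
        found_keys = {(l.contig_id, l.start, l.canonical_motif) for l in found}
        if not planted <= found_keys:
            raise AssertionError("fixture rejected: planted SSR not recovered")


# ---------------------------------------------------------------------------
# Read pool with expression skew (saturation-analysis fixture)
# ---------------------------------------------------------------------------


def sample_read_pool(
    n_transcripts: int,
    n_reads: int,
    expression_sd: float = 1.0,
    seed: int = 0,
) -> tuple[list[ReadAssignment], dict[str, str]]:
    """A read pool over a transcript catalogue with log-normal expression.

    Reads sample transcripts with replacement, weighted by per-transcript
    log-normal abundances (sd on the log scale; 1.0 approximates the
    dynamic range of a normalized cDNA library). Returns the assignments
    (contig id = transcript id — idealized assembly) and the identity
    contig -> reference map, so the number of detectable references equals
    ``n_transcripts`` by construction.
    """
    if n_transcripts < 3 or n_reads < n_transcripts // 100:
        raise ValueError("pool too small to be meaningful")
    rng = _rng(seed, "sample_read_pool")
    weights = rng.lognormal(0.0, expression_sd, n_transcripts)
    weights /= weights.sum()
    picks = rng.choice(n_transcripts, size=n_reads, p=weights)
    assignments = [
        ReadAssignment(read_id=f"r{i:07d}", library_tag="A", contig_id=f"t{t:05d}")
        for i, t in enumerate(picks)
    ]
    contig_to_ref = {f"t{i:05d}": f"ref{i:05d}" for i in range(n_transcripts)}
    return assignments, contig_to_ref


# ---------------------------------------------------------------------------
# Reference hit map
# ---------------------------------------------------------------------------


def build_reference_hit_map(
    contigs: Sequence[Contig],
    reference_size: int,
    hit_prob: float = 1.0,
    seed: int = 0,
) -> dict[str, str]:
    """Best-hit map contig -> reference transcript id.

    Each contig independently has a best hit with probability ``hit_prob``;
    the subject is drawn uniformly from ``reference_size`` reference ids,
    so many-to-one mappings emulate gene families. At most one reference
    per contig (best-hit semantics).
    """
    if reference_size < 1:
        raise ValueError("reference_size must be >= 1")
    if not 0 <= hit_prob <= 1:
        raise ValueError("hit_prob must be in [0, 1]")
    rng = _rng(seed, "build_reference_hit_map")
    mapping: dict[str, str] = {}
    for c in contigs:
        if rng.random() < hit_prob:
            mapping[c.id] = f"ref{int(rng.integers(0, reference_size)):06d}"
    return mapping


# ---------------------------------------------------------------------------
# Complete fixture on disk
# ---------------------------------------------------------------------------


def emit_fixture(
    outdir: str | Path,
    n_transcripts: int = 500,
    p_a: float = 0.5,
    p_b: float = 0.5,
    reference_size: int = 400,
    hit_prob: float = 0.8,
    seed: int = 0,
    **plant_kwargs,
) -> Path:
    """Write a complete fixture directory consumable by every subcommand."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts, truth = generate_population(n_transcripts, seed=seed)
    contigs, assignments, truth = simulate_two_libraries(
        transcripts, p_a, p_b, seed=seed, truth=truth
    )
    contigs, variants, orfs, plant_truth = plant_variants_and_ssrs(
        contigs, seed=seed, **plant_kwargs
    )
    truth.planted_variants = plant_truth.planted_variants
    truth.planted_ssrs = plant_truth.planted_ssrs
    ref_map = build_reference_hit_map(contigs, reference_size, hit_prob, seed)

    write_fasta(outdir / "contigs.fasta", contigs)
    write_assignments(outdir / "assignments.tsv", assignments)
    write_vcf_minimal(outdir / "variants.vcf", variants)
    write_orf_table(outdir / "orfs.tsv", orfs)
    with open(outdir / "contig_ref.tsv", "w") as fh:
        fh.write("# contig_id\treference_id\n")
        for cid, ref in sorted(ref_map.items()):
            fh.write(f"{cid}\t{ref}\n")
    (outdir / "truth.json").write_text(truth.to_json())
    return outdir
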