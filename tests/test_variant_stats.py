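import itertools
import re

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from transcensus.io_formats import Contig, OrfAnnotation, VariantRecord
from transcensus.variant_stats import (
    classify_coding_effect,
    classify_ts_tv,
    filter_repeat_adjacent,
    find_repeat_tracts,
    left_normalize_indels,
    revcomp,
    summarize_variants,
)

BASES = "ACGT"


def apply_variant(seq: str, v: VariantRecord) -> str:
    s, e = v.interval0()
    return seq[:s] + v.alt_allele + seq[e:]


class TestLeftNormalize:
    def test_homopolymer_deletion_shifts_to_first_position(self):
        #      123456789
        seq = "GCAAATTTG"
        contig = Contig("c1", seq)
        # deletion of one A recorded at the last A pair vs further left:
        # both must normalize to the representation anchored at the C
        raw = VariantRecord("c1", 4, "AA", "A")
        lefter = VariantRecord("c1", 3, "AA", "A")
        (norm_raw,) = left_normalize_indels([raw], [contig])
        (norm_left,) = left_normalize_indels([lefter], [contig])
        assert norm_raw == norm_left
        assert (norm_raw.position, norm_raw.ref_allele, norm_raw.alt_allele) == (
            2, "CA", "C",
        )
        assert apply_variant(seq, norm_raw) == apply_variant(seq, raw)

    def test_snp_passes_through(self):
        contig = Contig("c1", "ACGTACGT")
        v = VariantRecord("c1", 3, "G", "C")
        assert left_normalize_indels([v], [contig]) == [v]

    def test_ref_mismatch_rejected(self):
        contig = Contig("c1", "ACGTACGT")
        with pytest.raises(ValueError, match="REF"):
            left_normalize_indels([VariantRecord("c1", 2, "G", "GG")], [contig])

    def test_matches_brute_force_enumeration_oracle(self, rng):
        """The normalized form equals the leftmost parsimonious anchored
        representation among ALL (pos, ref, alt) that edit the sequence to
        the same haplotype, found by exhaustive enumeration."""

        def oracle(seq, v):
            target = apply_variant(seq, v)
            d = abs(len(v.ref_allele) - len(v.alt_allele))
            is_deletion = len(v.ref_allele) > len(v.alt_allele)
            for pos0 in range(len(seq)):  # leftmost wins
                if is_deletion:
                    ref = seq[pos0 : pos0 + d + 1]
                    if len(ref) < d + 1:
                        continue
                    cands = [(ref, ref[0])]
                else:
                    ref = seq[pos0]
                    cands = [
                        (ref, ref + "".join(ins))
                        for ins in itertools.product(BASES, repeat=d)
                    ]
                for r, a in cands:
                    cand = VariantRecord("c1", pos0 + 1, r, a)
                    if apply_variant(seq, cand) == target:
                        return cand
            raise AssertionError("oracle found no representation")

        n_checked = 0
        for _ in range(40):
            seq = "".join(np.array(list(BASES))[rng.integers(0, 4, 20)])
            contig = Contig("c1", seq)
            pos0 = int(rng.integers(1, 15))
            if rng.random() < 0.5:  # deletion of 1-2 bases
                dlen = int(rng.integers(1, 3))
                if pos0 + 1 + dlen > len(seq):
                    continue
                v = VariantRecord("c1", pos0 + 1, seq[pos0 : pos0 + 1 + dlen], seq[pos0])
            else:  # insertion of 1-2 random bases
                ins = "".join(BASES[int(b)] for b in rng.integers(0, 4, int(rng.integers(1, 3))))
                v = VariantRecord("c1", pos0 + 1, seq[pos0], seq[pos0] + ins)
            (norm,) = left_normalize_indels([v], [contig])
            expected = oracle(seq, v)
            assert apply_variant(seq, norm) == apply_variant(seq, v)
            assert (norm.position, norm.ref_allele, norm.alt_allele) == (
                expected.position, expected.ref_allele, expected.alt_allele,
            ), (seq, v)
            n_checked += 1
        assert n_checked >= 30


class TestRepeatFilter:
    def test_snp_immediately_after_homopolymer_removed(self):
        contig = Contig("c1", "GCGTAAAACGTGCGT")  # AAAA at positions 5-8
        snp = VariantRecord("c1", 9, "C", "T")
        retained, removed = filter_repeat_adjacent([snp], [contig])
        assert retained == []
        assert removed[0].filter_flags == {"REPEAT_ADJACENT"}

    def test_distant_snp_retained(self):
        contig = Contig("c1", "AAAAGCGTGCATGCTAGCTG")
        snp = VariantRecord("c1", 15, "A", "G")  # 10 bp from the tract
        retained, removed = filter_repeat_adjacent([snp], [contig])
        assert removed == []
        assert retained == [snp]

    def test_dinucleotide_tract_counts(self):
        contig = Contig("c1", "GGTCACACACACTGCAGTCA")  # AC x 4 at 5-12
        snp_inside = VariantRecord("c1", 7, "A", "G")
        snp_beside = VariantRecord("c1", 13, "T", "C")
        _, removed = filter_repeat_adjacent([snp_inside, snp_beside], [contig])
        assert len(removed) == 2

    def test_three_repetitions_do_not_trigger(self):
        contig = Contig("c1", "GGTCACACACTGCAGTCGAT")  # AC x 3 only
        snp = VariantRecord("c1", 11, "T", "C")
        retained, removed = filter_repeat_adjacent([snp], [contig])
        assert removed == []

    def test_filter_is_idempotent(self, random_contigs):
        rng = np.random.default_rng(4)
        variants = []
        for c in random_contigs:
            for _ in range(5):
                pos = int(rng.integers(0, len(c)))
                ref = c.sequence[pos]
                alt = BASES[(BASES.index(ref) + 1) % 4]
                variants.append(VariantRecord(c.id, pos + 1, ref, alt))
        retained, removed = filter_repeat_adjacent(variants, random_contigs)
        retained2, removed2 = filter_repeat_adjacent(retained, random_contigs)
        assert retained2 == retained
        assert removed2 == []

    def test_matches_regex_enumeration_oracle(self, random_contigs):
        """Removal set equals a regex oracle that enumerates every tract of
        >= 4 repetitions of every 1-6 bp motif."""
        rng = np.random.default_rng(9)
        variants = []
        for c in random_contigs[:10]:
            for _ in range(20):
                pos = int(rng.integers(0, len(c)))
                ref = c.sequence[pos]
                alt = BASES[(BASES.index(ref) + 1) % 4]
                variants.append(VariantRecord(c.id, pos + 1, ref, alt))

        def oracle_tracts(seq):
            spans = []
            for k in range(1, 7):
                for match in re.finditer(rf"(?=((.{{{k}}})\2{{3,}}))", seq):
                    tract = match.group(1)
                    if "N" in tract:
                        continue
                    spans.append((match.start(), match.start() + len(tract)))
            return spans

        for c in random_contigs[:10]:
            spans = oracle_tracts(c.sequence)
            vs_here = [v for v in variants if v.contig_id == c.id]
            retained, removed = filter_repeat_adjacent(vs_here, [c])
            removed_set = {(v.contig_id, v.position) for v in removed}
            oracle_removed = set()
            for v in vs_here:
                s, e = v.interval0()
                for ts, te in spans:
                    if max(ts - e, s - te) <= 0:
                        oracle_removed.add((v.contig_id, v.position))
                        break
            assert removed_set == oracle_removed


class TestTsTv:
    def test_exactly_four_of_twelve_substitutions_are_transitions(self):
        labels = {
            (r, a): classify_ts_tv(VariantRecord("c", 1, r, a))
            for r, a in itertools.permutations(BASES, 2)
        }
        transitions = {k for k, v in labels.items() if v == "transition"}
        assert transitions == {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        assert len(labels) == 12

    def test_non_snp_rejected(self):
        with pytest.raises(ValueError):
            classify_ts_tv(VariantRecord("c", 1, "AT", "A"))


class TestCodingEffect:
    def test_synonymous_third_position(self):
        contig = Contig("c1", "TTGGATTT")
        orf = OrfAnnotation("c1", 3, 5, "+", "predicted")
        snp = VariantRecord("c1", 5, "A", "G")  # GGA -> GGG, Gly -> Gly
        assert classify_coding_effect(snp, orf, contig) == "synonymous"

    def test_nonsynonymous_met_to_ile(self):
        contig = Contig("c1", "TTATGTTT")
        orf = OrfAnnotation("c1", 3, 5, "+", "predicted")
        snp = VariantRecord("c1", 5, "G", "A")  # ATG -> ATA
        assert classify_coding_effect(snp, orf, contig) == "non_synonymous"

    def test_outside_orf_is_non_coding(self):
        contig = Contig("c1", "TTATGTTT")
        orf = OrfAnnotation("c1", 3, 5, "+", "predicted")
        snp = VariantRecord("c1", 8, "T", "C")
        assert classify_coding_effect(snp, orf, contig) == "non_coding"

    def test_codon_with_n_unscorable(self):
        contig = Contig("c1", "TTGNATTT")
        orf = OrfAnnotation("c1", 3, 5, "+", "predicted")
        snp = VariantRecord("c1", 5, "A", "G")
        assert classify_coding_effect(snp, orf, contig) == "non_coding"

    def test_synonymous_fraction_matches_codon_table_enumeration(self):
        """Across all 549 single-base changes of the 61 sense codons the
        classifier must agree substitution-by-substitution with direct
        codon-table lookup."""
        table = dict(standard_dna_table.forward_table)
        sense = [c for c in map("".join, itertools.product(BASES, repeat=3))
                 if c in table]
        assert len(sense) == 61
        n_total = n_syn = 0
        for codon in sense:
            for i in range(3):
                for b in BASES:
                    if b == codon[i]:
                        continue
                    mutated = codon[:i] + b + codon[i + 1 :]
                    n_total += 1
                    oracle_syn = mutated in table and table[mutated] == table[codon]
                    contig = Contig("c1", codon)
                    orf = OrfAnnotation("c1", 1, 3, "+", "predicted")
                    snp = VariantRecord("c1", i + 1, codon[i], b)
                    got = classify_coding_effect(snp, orf, contig)
                    if got == "synonymous":
                        n_syn += 1
                    assert (got == "synonymous") == oracle_syn
        assert n_total == 549

    def test_strand_symmetry(self, rng):
        """A SNP classified on a contig equals the mirrored SNP on the
        reverse complement with the mirrored ORF."""
        for _ in range(30):
            seq = "".join(np.array(list(BASES))[rng.integers(0, 4, 60)])
            contig = Contig("c1", seq)
            orf = OrfAnnotation("c1", 10, 39, "+", "predicted")
            pos = int(rng.integers(10, 40))
            ref = seq[pos - 1]
            alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
            if alt == ref:
                continue
            snp = VariantRecord("c1", pos, ref, alt)
            rc_contig = Contig("c1", revcomp(seq))
            L = len(seq)
            rc_orf = OrfAnnotation("c1", L - 39 + 1, L - 10 + 1, "-", "predicted")
            rc_snp = VariantRecord(
                "c1", L - pos + 1, revcomp(ref), revcomp(alt)
            )
            assert classify_coding_effect(snp, orf, contig) == classify_coding_effect(
                rc_snp, rc_orf, rc_contig
            )


class TestSummaries:
    def make_contig(self):
        # ORF at 7..15 (3 codons), repeat-free sequence
        return Contig("c1", "GACTGAGGACTAATGCTGACGTAGCTAGCTAG"[:30])

    def test_pseudocount_ratio_and_diversifying_flag(self):
        contig = Contig("c1", "TTGGATAGCGATGCTGATCG")
        orf = OrfAnnotation("c1", 3, 11, "+", "predicted")
        variants = [
            VariantRecord("c1", 4, "G", "C"),   # GAT: D->H non-synonymous
            VariantRecord("c1", 7, "A", "T"),   # AGC: S->S? AGC->TGC = Cys, nonsyn
        ]
        summary, _ = summarize_variants(variants, [orf], [contig])
        s = summary.per_contig["c1"]
        assert s.ka == 2 and s.ks == 0
        assert s.ratio == pytest.approx(3.0)
        assert s.diversifying

    def test_no_coding_snps_ratio_is_one(self):
        contig = Contig("c1", "TTGGATAGCGATGCTGATCG")
        variants = [VariantRecord("c1", 18, "T", "C")]
        summary, _ = summarize_variants(variants, [], [contig])
        s = summary.per_contig["c1"]
        assert s.ratio == 1.0
        assert not s.diversifying

    def test_partition_of_retained_snps(self, random_contigs):
        """Every retained SNP lands exactly once in {ts, tv} and once in
        {ka, ks, utr}."""
        rng = np.random.default_rng(13)
        variants, orfs = [], []
        for c in random_contigs:
            orfs.append(OrfAnnotation(c.id, 201, 400, "+", "predicted"))
            for _ in range(8):
                pos = int(rng.integers(0, len(c)))
                ref = c.sequence[pos]
                alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
                variants.append(VariantRecord(c.id, pos + 1, ref, alt))
        summary, removed = summarize_variants(variants, orfs, random_contigs)
        assert summary.retained_snps + len(removed) == len(variants)
        assert summary.ts + summary.tv == summary.retained_snps
        assert summary.ka + summary.ks + summary.utr_snps == summary.retained_snps

    def test_diversifying_iff_ka_exceeds_ks(self, rng):
        from transcensus.variant_stats import ContigVariantSummary

        for _ in range(200):
            ka, ks = int(rng.integers(0, 10)), int(rng.integers(0, 10))
            s = ContigVariantSummary("c", ka=ka, ks=ks)
            assert s.diversifying == (ka > ks) == (((ka + 1) / (ks + 1)) > 1)

    def test_mean_and_density_arithmetic(self):
        # repeat-free 20-mer tiled: the only periodicity is 20 bp, beyond
        # the 6-bp motif range, so no variant can be repeat-adjacent
        unit = "ACGGTCAGTTCAGGCATCGA"
        contigs = [Contig("c1", unit * 5), Contig("c2", unit * 5)]
        variants = [
            VariantRecord("c2", 10, unit[9], "G"),
            VariantRecord("c2", 50, unit[9], "G"),
        ]
        summary, removed = summarize_variants(variants, [], contigs)
        assert removed == []
        assert summary.mean_snps_per_contig == 2  # one SNP-containing contig
        total_len = sum(len(c) for c in contigs)
        assert summary.snp_density == total_len / 2
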