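# Methods

## Study design the package models

Two cDNA libraries, one individual each, sequenced and jointly assembled
with every read labelled by library of origin. The libraries are treated as
two independent samples of one closed transcript population: per-transcript
capture is Bernoulli, independent across transcripts and libraries. All
completeness statements rest on that assumption; biological violations
(sex-specific expression, unequal developmental stage) bias the common
fraction downward and therefore the abundance estimate upward — the
estimated completeness is best read as an upper bound.

## Library partition and in-silico subtraction

A contig is library-specific iff every member read carries one library's
tag; read membership comes from the contig records or from the assignment
table. Subtraction moves disguised shared transcripts into the common
fraction:

- **Direct**: a specific contig with at least one alignment to the opposite
  specific set at query coverage > 0.80 and e-value strictly < 1e-50 moves.
  "More than 80% of their length" is read as a query-side fraction computed
  on the moved contig, which is the query in its own search; the strict
  inequality on the e-value follows the word "below". Only the query moves;
  mutual alignments appear as two directed hits in practice.
- **Indirect** (nucleotide, then protein reference): after filtering hits
  at e ≤ 1e-06 (an inclusive "threshold") and coverage > 0.80, keeping the
  single best HSP per (query, subject), every subject hit from both
  specific sets causes all of its queries on both sides to move. One pass
  per reference collection, no fixpoint iteration: a pair cannot recruit
  further contigs through an already-moved member. Whether coverage should
  instead aggregate HSPs per subject is not determinable from the source
  description; the single-best-HSP rule is the configurable default.

Invariants maintained and tested: the three fractions stay disjoint, their
union is constant, moves only go specific → common, and results are
independent of hit order.

## Capture–recapture

For two occasions the closed-population Mt likelihood reduces to
Lincoln–Petersen, so the estimator is implemented in closed form
(N̂ = n₁n₂/m, SE = √(n₁n₂(n₁−m)(n₂−m)/m³)) rather than through a
model-fitting dependency; the estimate is the integer maximizer of the
hypergeometric likelihood, which a grid-search test verifies. Chapman's
(n₁+1)(n₂+1)/(m+1) − 1 with its standard variance handles m = 0 and small
samples. Confidence intervals are normal-approximation, truncated below at
the number of distinct observed items; the reported abundance rounds
half-up and SE is shown to 3 significant figures. Calibration is checked by
simulation: 200 replicates of a 2,000-transcript population at capture
probability 0.5 per library give a mean estimate within 2% of truth, with
coverage of the nominal 95% interval inside the 90–98% band.

## Rarefaction and the hyperbolic model

The design is 20 evenly spaced subset sizes up to the full pool, 10
replicates each, drawn without replacement (both configurable; the sizes
and replicate counts are read directly from the study design). y is the
number of distinct reference transcripts reachable through the subset's
contigs under a best-hit map (one subject per contig, ties broken by bit
score, then e-value, then subject id). The per-size means are fitted with
y = a·x/(b + x) by bounded least squares, initialized at a₀ = 1.1·max(ȳ)
and b₀ = the x whose mean is closest to a₀/2, with up to 5 jittered
restarts; per-size standard deviations are retained for plotting only. A
fitted b below 10⁻³ of the smallest sampled size means the curve is flat
over the observed range and the fit is flagged unconverged ("boundary").
The slope at the full pool is the analytic a·b/(b+x_max)².

The synthetic read pools used to validate this stage sample transcripts
with log-normal expression weights (sd 1.0 on the log scale). This matters:
under uniform expression the collector's curve is exponential,
R(1 − e^(−x/R)), whose tail the hyperbola extrapolates badly; under
realistic skewed expression the hyperbolic form tracks the curve and the
completeness ratio observed/a lands within 5 percentage points of the true
observed/R on ≥ 10,000-read pools. Shrinking the detectable reference set
(emulating a different reference species) moves a and the observed count
together and changes the ratio by < 5 points, which is the robustness
property that makes the ratio the headline number.

The source study also reports slope values (0.157/0.145/0.140) that are not
reproducible from its printed asymptotes and read counts under
slope = a·b/(b+x)² — the reconstruction gives much smaller values, so the
abscissa convention behind those numbers is ambiguous. The package reports
the analytic slope and makes no claim of matching those figures.

## Variant post-processing

INDELs are left-normalized (right-trim shared trailing bases, extending
left through the contig when an allele empties; left-trim to the single
VCF anchor; anchored at position 1 if a shift reaches the contig start).
Normalization is validated against exhaustive enumeration of all anchored
parsimonious representations of the same haplotype.

The repeat-adjacency filter removes a variant whose affected interval
overlaps, or lies within 1 position of (i.e. immediately beside), a
maximal perfect tandem tract of ≥ 4 repetitions of any 1–6 bp motif,
homopolymers included. The full periodic stretch counts as the tract,
including a partial trailing repetition — equivalently, the union over all
phases of whole-unit windows — which an independent regex-enumeration
oracle confirms. "Beside" has no stated distance in the source; adjacency
(proximity 1) is the default and the distance is configurable. All
downstream statistics are computed on the post-filter set.

Transitions are A↔G and C↔T; the other eight substitutions are
transversions. Coding effect substitutes the allele into its codon in the
ORF's frame (strand-aware, standard genetic code): same amino acid →
synonymous, anything else including stop gain/loss → non-synonymous; SNPs
outside the ORF, in an incomplete trailing codon, or in a codon containing
N are non-coding/unscorable. The classifier is tested against direct
codon-table enumeration of all 549 single-base changes of the 61 sense
codons and for strand symmetry. When a contig has both an
alignment-derived and a predicted ORF, the alignment-derived frame wins.
INDELs are never scored for coding effect; they enter densities only.

Per contig, the ratio (Ka+1)/(Ks+1) uses +1 pseudocounts so Ks = 0 stays
finite; a contig is flagged diversifying iff the ratio exceeds 1, which is
algebraically Ka > Ks. Densities are total supplied-contig length per
retained variant; per-contig means divide by the number of
variant-containing contigs.

## SSR scan

Perfect tandem tracts of primitive 2–6 bp motifs at minimum repeats
6/4/4/4/4 (di- through hexa-). Only whole repetitions are reported, so a
locus spans unit_len × n_repeats; one locus per periodic run (phase-shifted
re-alignments of the same run are not separate loci); degenerate motifs
(e.g. ACAC) are reported under their primitive unit; tracts break at N;
abutting loci (0 intervening bases) are reported separately and flagged
compound. Canonical motifs are the lexicographic minimum over cyclic
rotations of the motif and of its reverse complement, so complementary
families tally together. Mononucleotide runs are excluded here but
included in the variant repeat filter — the two analyses state different
unit ranges. The scanner is property-tested against a brute-force oracle,
including under reverse complement, where reported windows may shift by
the partial-unit remainder of the run (the canonical motif, repeat count
and run identity are preserved exactly).

The source's per-unit SSR counts sum to 5,414 against a stated total of
5,295; the discrepancy (likely compound-locus accounting) cannot be
resolved from the text, so no equivalence is asserted on those counts.
Likewise its SNP retention percentage (94.04%) disagrees with its own
counts (21,791/23,084 = 94.40%); only the INDEL retention percentage is
reproduced.

## Candidate screens

Panel screen: per-HSP filtering at e ≤ 1e-03 and ≥ 50 positive positions
(whether the positives bound should sum across HSPs is not determinable;
per-HSP is the default), best homolog per contig by bit score, candidate
ranking by bit score → mean per-base coverage with singleton contigs
excluded → translated-aligned fraction → optional user-supplied evidence
scores → contig id. The published ranking criteria that require manual
alignment inspection, domain content or annotation judgment are
represented only as those optional evidence scores. Mitochondrial screen:
presence iff any hit at e ≤ 1e-10, reporting the best hit's identity.

## Synthetic data

All emitters are pure functions of (parameters, seed), each drawing from a
stream keyed by (seed, emitter name) so adding an emitter never perturbs
the others. Defaults model the study design: two libraries, log-normal
transcript lengths (mean 500, sd 200, floor 300 bp), GC 0.40, capture
probabilities 0.5, ≥ 1 read per captured transcript. The assembly is
idealized — one contig per captured transcript — to isolate estimator
behaviour from assembler noise; an optional fragmentation mode splits
doubly-captured transcripts into two library-specific halves, the
disguised-shared case indirect subtraction exists to repair. Planted
variants and SSRs are written into the contig sequences with guard bases
and template codons so each item's transition/transversion, coding-effect
and repeat-adjacency label is structurally guaranteed; the generator then
re-derives every label with the package's own classifiers and rejects the
fixture on any mismatch. What the generator does not emulate: sequencing
error (including homopolymer miscalls), chimeric assembly, expression-level
read-count realism beyond the log-normal skew, and paralog collapse during
assembly — so passing tests demonstrate correctness of the estimators and
classifiers under the stated sampling model, not robustness to assembler
artefacts.

## Problem sizes used in validation

Test-suite simulations use populations of 2,000 transcripts (estimator
calibration, 200 replicates), 10,000-read pools (saturation recovery),
1,000 random 2-kb sequences (SSR oracle equivalence) and 55,282-contig
identifier sets (subtraction bookkeeping replay) — sizes chosen to match
the scale of the quantities they validate while keeping the suite fast.
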