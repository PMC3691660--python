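# transcensus

Tools for asking "how much of a transcriptome did we actually sequence?"
from a two-library de novo EST assembly, plus the post-processing that
typically follows: in-silico library subtraction, variant classification,
microsatellite discovery and candidate-gene screening.

The package targets studies in which two cDNA libraries (e.g. one male and
one female individual of a non-model species) are sequenced, jointly
assembled, and every read carries a label of its library of origin. It was
built around a sturgeon gonad/brain transcriptome of this design, but the
operations are generic.

## What it computes

**Library partition and in-silico subtraction.** Contigs are classified by
the origin of their member reads as A-specific, B-specific or common.
Apparently library-specific contigs that actually represent shared
transcripts are then moved to the common fraction in three stages:
*direct* subtraction (mutual cross-library alignment with query coverage
> 80% and e-value < 1e-50), and *indirect* subtraction against a shared
nucleotide or protein reference (both contigs hit the same subject at
e ≤ 1e-06 and coverage > 80%).

**Capture–recapture abundance.** Treating the two libraries as two capture
occasions over a closed transcript population, with n₁ and n₂ transcripts
captured per occasion and m captured by both (the common fraction), the
Lincoln–Petersen estimator gives

    N̂ = n₁·n₂ / m,   SE = √( n₁·n₂·(n₁−m)·(n₂−m) / m³ )

and observed/N̂ is the completeness of the combined catalogue. Chapman's
bias-corrected variant is available for small samples.

**Rarefaction / saturation analysis.** Random read subsets of increasing
size are traced back to contigs and to each contig's best-matching
reference transcript; the distinct-reference count y(x) is fitted with the
hyperbola y = a·x/(b + x). The asymptote *a* estimates the maximum number
of reference transcripts discoverable at infinite depth, observed/*a* is
the sequencing completeness, and a·b/(b+x)² is the residual discovery rate
at the full pool.

**Variant post-processing.** Left-normalization of INDELs, removal of
variants beside ≥ 4 repetitions of any 1–6 bp motif (homopolymers
included), transition/transversion classification, strand-aware
synonymous/non-synonymous calls against ORF annotations, and the
per-contig pseudocounted ratio (Ka+1)/(Ks+1), flagging putatively
diversifying contigs when Ka > Ks.

**SSR scan.** Perfect microsatellites of unit 2–6 bp at minimum repeat
counts 6/4/4/4/4, with primitive-motif reporting and canonicalization over
cyclic rotations and reverse complement (AC ≡ CA ≡ GT ≡ TG).

**Candidate screens.** Threshold-based screening of hit tables for a gene
panel (discard e > 1e-03 or < 50 positive positions; rank candidate
contigs by bit score, coverage with singletons excluded, aligned fraction)
and a mitochondrial 13-gene presence screen at e ≤ 1e-10.

**Synthetic data.** Every stage is exercisable without downloads: a
generator emits transcript populations, two-library capture samplings with
known n₁/n₂/m, paralog families, fragmented transcripts (the case indirect
subtraction repairs), planted variants with verified Ts/Tv, coding-effect
and repeat-adjacency labels, planted SSRs, and skewed read pools for
saturation analysis.

## Worked example

```python
from transcensus import (
    generate_population, simulate_two_libraries, classify_by_origin,
    estimate_abundance, completeness_fraction,
)

population, _ = generate_population(2000, seed=42)
contigs, assignments, truth = simulate_two_libraries(
    population, p_a=0.5, p_b=0.5, seed=42
)
part = classify_by_origin(contigs, assignments)
n1 = len(part.specific_a) + len(part.common)
n2 = len(part.specific_b) + len(part.common)
est = estimate_abundance(n1, n2, len(part.common))
print(f"true N = 2000, estimate = {est.n_hat_rounded} +- {est.se:.0f} (SE)")
print(f"observed {est.observed} distinct transcripts "
      f"= {100 * completeness_fraction(est.observed, est):.1f}% of the estimate")
```

prints

```
true N = 2000, estimate = 2049 +- 49 (SE)
observed 1498 distinct transcripts = 73.1% of the estimate
```

i.e. the two half-coverage libraries together captured 1,498 of the 2,000
transcripts, and the estimator recovers the population size from the
overlap alone (the truth lies within one standard error here).

The same estimator applied to a real two-library partition — 16,951 and
17,079 library-specific contigs plus 21,252 common out of 55,282 — gives
N̂ = 68,905 ± 210 and a completeness of 80%:

```bash
transcensus capture --n1 38203 --n2 38331 --m 21252
```

There is also a full CLI over the other stages (`transcensus partition |
saturation | variants | ssr | screen | simulate | run`); see `--help`.

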