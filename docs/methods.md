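# Methods

This note records the models and conventions `scnovel` implements, the
parameter choices that matter, what the synthetic fixtures emulate, and
the limits of what the tests demonstrate.

## Coordinates and formats

All in-memory coordinates are 0-based half-open; GTF (1-based closed)
and fixedStep WIG (1-based) are converted only at the I/O boundary.
Overlapping or book-ended exon records within one transcript — a common
assembler artifact — are merged with a warning rather than rejected.
Unknown strand `.` is preserved; its semantics are decided by the
classifier, never by the parser. Conservation tracks distinguish a
position with score 0.0 (data) from an absent position (null).

## Transcript classification

A query receives the first matching code in a fixed precedence order:

1. `=` — multi-exon: intron chain (the ordered donor/acceptor pairs)
   identical to a same-strand reference chain. Single-exon: ≥ 80%
   reciprocal overlap with a same-strand single-exon reference. The
   80% cutoff is configurable history-free plumbing: single-exon
   "equality" has no canonical definition, and fragment boundaries are
   noisy at transcript ends.
2. `c` — every query exon contained in an exon of one same-strand
   reference and the query chain a contiguous sub-chain of that
   reference's chain (a single-exon query inside a reference exon
   qualifies: its empty chain is trivially contiguous).
3. `j` — multi-exon query sharing ≥ 1 exact junction with a
   same-strand reference, chain not identical. Junction equality is
   exact coordinate equality: assembled junctions are splice-precise,
   and a fuzz window (default 0) is exposed only as a configuration
   point.
4. `o` — same-strand exonic overlap without a shared junction.
5. `i` — query span fully inside a single reference intron, on either
   strand: an antisense transcript inside an intron is still
   intronic-derived for the novelty partition.
6. `x` — exonic overlap on the opposite strand only. Unstranded
   queries are compared against both strands for rules 1–4 and can
   never receive `x`.
7. `u` — no reference overlap. This rule is also the catch-all: a
   query whose relation to the reference matches none of the above
   (e.g. its intron fully enclosing a reference transcript with no
   exonic contact) is reported `u`. The full cuffcompare alphabet
   (`e`, `p`, `s`, `y`, …) is deliberately not reproduced — the
   novelty pipeline consumes only the partition
   {`u`,`i`,`j`} / {`=`,`c`} / {`o`,`x`}.

Ties among eligible references break deterministically: most shared
junctions, then longest exonic overlap, then lexicographic id.
Classification is therefore independent of reference input order; the
test suite checks 100% agreement with a brute-force oracle that
evaluates the rules per (query, reference) pair on per-base sets.

## Coding potential and the lncRNA gate

Three sequence features summarize coding potential:

- **Longest ORF**: longest ATG→stop open reading frame over the three
  sense frames (length counts both codons; ties go 5'-most). ORFs
  without an in-frame stop are ignored by default.
- **Fickett TESTCODE**: the classical statistic combining four
  position-asymmetry parameters (max/(min+1) of each base's counts in
  the three codon phases) and four composition parameters through the
  published probability/weight lookup tables. It is calibrated for
  sequences ≥ 200 nt; shorter input warns.
- **Hexamer usage bias**: mean log₂ ratio of in-frame (step 3) 6-mer
  frequencies, coding vs noncoding, over the longest ORF; trained from
  labeled sequences with pseudocount 1, 0 when there is no ORF.

A logistic model over (ORF coverage, log₁₀ ORF length, Fickett,
hexamer) maps features to a coding probability; label = coding at
score ≥ 0.5. Three built-in predictor configurations — all features,
composition-only, ORF-geometry-only — are logistic fits trained
deterministically (fixed seed, 300 sequences per class) on the
package's own synthetic coding/noncoding generator, giving three
partially independent views of the same evidence in place of external
ML tools, whose calls can be supplied as TSV and enter the same
consensus.

The gate follows the unanimous-vote convention. "Sufficient
expression" is CPM ≥ 1 in ≥ 3 cells (the standard single-cell
detection floor; configurable), evaluated from the cell matrix. The
lncRNA length rule is strictly greater than 200 nt: 201 passes, 200 is
`excluded_short`. Mixed votes are `ambiguous` and excluded from both
novel sets by default.

## Conservation

A transcript's conservation is the mean of per-base track scores over
its exonic bases only (matching the behavior of averaging a
conservation signal over an exon BED); bases without data are excluded
from numerator and denominator, and a transcript with no covered base
has a null mean. ECDFs are evaluated at observed scores only
(`stat_ecdf` semantics), right-continuous, with null means counted
separately.

## Specificity and markers

Per-type mean CPM profiles (linear scale — JSD needs a probability
vector) are normalized to sum 1; specificity toward type t is
1 − √JSD(p, e_t) with log₂ entropies and 0·log 0 = 0. This is the
Cabili-style score used by cummeRbund's `csSpecificity`; s_t = 1 iff
the transcript is expressed in type t alone. A transcript is a marker
of its best type when max_t s_t ≥ 0.6, it is detected (count > 0) in
≥ 25% of that type's cells, and its mean CPM there is ≥ 2× the mean
over the remaining types. The three defaults are documented
conventions, not fitted values; all are configurable, and no attempt
is made to reproduce any particular published marker count.

## novelScore

Features are ranked per cell by expression, descending, with average
ranks for ties (deterministic; AUCell's random tie-breaking is
reproducibility-hostile). The full-integral mode is the normalized
Mann–Whitney U — exactly the printed ∫ TPR dFPR over the whole
ranking — and satisfies AUC(G) + AUC(Gᶜ) = 1 and invariance to
monotone transforms of the expression vector. The top-fraction mode
integrates the recovery curve over the top ⌈f·N⌉ ranks (tied ranks
split linearly) and min–max normalizes, reducing exactly to the full
integral at f = 1; default f = 0.05 mirrors the AUCell convention.
Both modes are reported with their label since they answer slightly
different questions (global enrichment vs top-of-ranking enrichment).

Threshold exploration offers mean + k·sd (k = 3), the crossing point
of a two-component Gaussian mixture (posterior 0.5 on a 2001-point
grid between the component means), and a fixed percentile; constant
score vectors fall back to the percentile with a warning. Cells are
assigned by strict `>`.

## Coexpression and drug correlation

Pearson r against the target across cells with two-sided t-test
p-values, Benjamini–Hochberg adjusted over the non-degenerate
features; "coexpressed" applies the 0.05 cutoff to the *adjusted* p by
default (a `--raw-p` flag restores the literal raw-p reading, which
the adjusted form strictly dominates for error control).
Zero-variance features are excluded from the FDR family. Signature
scores on bulk cell-line panels default to mean per-feature z-scores
(rank-AUC is noisy when the marker set is large relative to the
measured features); the AUC route is available for cross-checks. Drug
correlations require ≥ 3 shared lines per drug and are BH-adjusted
across drugs.

## Synthetic fixtures

The generator is a pure function of a manifest; identical seeds give
byte-identical files. Reference genes are spaced multi-exon loci
(3–5 exons of 90–300 nt, introns 420–800 nt, ≥ 800 nt intergenic gaps)
with coding sequence (biased codon usage, short UTRs) written into
their exons; planted queries realize each class code geometrically
(copies, contained fragments, single-junction shifts ≥ 4 nt, intronic
and straddling exons, intergenic slots), so the planted code is
provably the rule outcome, and introns are deep enough that intronic
plants exceed the 200-nt lncRNA floor. Counts are negative binomial
(dispersion 3) around lognormal base means with per-type Dirichlet
profiles — flat α = 3 for background, α = 40 on one type for markers —
times independent Bernoulli retention (10% dropout). Conservation
draws annotated exon bases from Beta(5, 2) and novel (u/i) bases from
Beta(2, 5), encoding the annotated-above-novel contrast. The drug
panel plants one compound with population correlation −0.7 to the
per-line signature score among Gaussian nulls (30 lines, 20 drugs).
The `gbm_like` profile scales the study shape to the desk: 1,000
transcripts with 52.7% unannotated, six major cell types at 97 cells
each plus a rare "stemness-like" subtype at 3%, and 30 planted markers
per type.

Problem sizes throughout the tests and the acceptance script (500
oracle queries, 1,000 AUC rankings, 500 conservation fixtures,
300–500 FDR simulations, 100 drug replicates) were chosen as the
smallest sizes at which the checked properties are statistically
sharp.

What the fixtures do **not** emulate: full-length-protocol coverage
bias, UMI structure, ambient RNA, batch effects, correlated dropout,
real codon usage or splice-site sequence signals, and real phastCons
spatial autocorrelation. Passing tests demonstrate correctness of the
computations and recoverability of planted structure under the stated
noise model — not performance on any real dataset.

## Numerical choices and degenerate inputs

CPM normalization errors on zero-total cells rather than silently
producing NaN. JSD values are clipped at 0 before the square root to
absorb −1e−17-scale float error. All-zero transcripts have undefined
specificity and are flagged null, never scored 0. Gene sets covering
none or all matrix features are rejected (TPR/FPR undefined); members
absent from the matrix are dropped with a counted warning. The
expression unit for ranking and specificity defaults to CPM computed
from the matrix itself (assembler-reported FPKM/TPM are equally
acceptable inputs; ranks are invariant to per-cell monotone rescaling,
so the AUC is unaffected by the choice).

## Known limitations

- The classifier's alphabet is the seven codes the novelty partition
  needs; exotic cuffcompare relations collapse into `o`/`u`.
- The built-in coding predictors are trained on synthetic sequence and
  are not a substitute for dedicated tools on real transcripts; the
  consensus logic, not the predictors, is the contribution, and
  external calls plug in via TSV.
- Specificity uses hard cell-type labels; probabilistic assignments
  are out of scope.
- bigWig binary tracks are not parsed in-core; convert to bedGraph or
  fixedStep WIG first.
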