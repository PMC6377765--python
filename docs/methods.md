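# Methods

## Model and procedure

The pipeline treats cis-regulation as a pair-level classification
problem. For each lncRNA or antisense transcript `L` and each
protein-coding gene `G` on the same chromosome with nearest-edge
distance ≤ `window` (default 400,000 bp; overlap counts as distance 0),
it assembles an LCP and accumulates independent evidence layers:

1. **Coexpression.** Spearman rank correlation of the two expression
   vectors (midranks for ties, two-sided p), with Benjamini–Hochberg
   adjustment applied once over all pairs of the run. BH family scope is
   a genuine modelling choice: adjusting per-lncRNA would make adjusted
   p-values incomparable across loci, so one family per dataset is used.
2. **Neighbourhood structure.** Within each lncRNA's pair set, ρ values
   are standardised (sample sd, n−1); |z| > 1 flags the gene that is
   more than one sd more (or less) correlated than the rest — the
   "mono-correlated" signature. A frequency matrix tallies lncRNAs by
   (total paired genes, genes with adj p < 0.01) to expose
   poly-correlated loci.
3. **Chromatin.** Per histone mark, the signal attached to an LCP is the
   maximum −log10 peak p over ChIP-seq peaks overlapping the lncRNA
   interval (the gene's own chromatin is deliberately not consulted:
   the question is whether the *lncRNA locus* looks like an enhancer or
   an active promoter). The ChIA-PET score is the maximum over
   interactions with one anchor on the lncRNA and the other on the gene.
   Max-aggregation is robust to peak fragmentation and preserves the
   input scale.
4. **Localization.** Nuclear fraction = nuclear/(nuclear+cytoplasmic)
   FPKM; classes Nuclear (≥ 0.7), Cytoplasmic (≤ 0.3), Both (between).
   Boundaries are assigned to the single-compartment classes because
   "between 30 and 70%" reads as an open interval.

These layers feed two closed-form scores (README for the formulas). The
offsets (+0.001 inside the log; +0.1, +0.01, +1 on the factors) exist so
that missing annotation — no fraction record, no peak, no loop —
substitutes as 0 without zeroing the product; both scores are monotone
non-decreasing in every argument, and the enhancer score has floor 2.
The log is base 10, consistent with every other −log10 quantity in the
pipeline; `--log-base e` is available for comparison against
implementations that read the formula with a natural log.

## Cutoffs and quadrants

Scores are ranked ascending (missing values take the lowest ranks;
ties break uniformly at random under the run seed, so ranked outputs
are reproducible). The cutoff is found geometrically: fit an ordinary
least-squares line of score against rank and locate the uppermost
crossing where the empirical curve passes the line from below (residual
sign change − → +, with a relative tolerance of 1e-9 to ignore
float-level residuals). The cutoff is the score at the last point still
*below* the line at that crossing, so the entire above-line tail —
including the first point of the crossing itself — counts as high under
the strict `score > cutoff` test. Residuals can change sign several
times on noisy curves; the uppermost crossing is used because the
cutoff's purpose is to isolate the high-score tail. Two degenerate
cases are defined explicitly: a near-linear curve (no residual above
tolerance) and a curve that never crosses from below both yield
cutoff = max(score), i.e. nothing passes, and the condition is logged.
Cutoffs are computed on raw scores; scaling to a 0–100 range
(`100·s/max`) is for output and plotting only. Scores exactly equal to
a cutoff count as low. Quadrants: Q1 neither high, Q2 enhancer only,
Q3 both, Q4 transcript only.

## RBP interactome

Only eCLIP records carrying the maximal score encoding (1000) are
binding evidence; lower-scored records never contribute. A cell line
"shows binding" when any replicate has such a record over the lncRNA;
the pair is bound when both cell lines show binding or both replicates
of one line do. `--strict-binding` switches the cross-line clause to
require both replicates per line, the more conservative reading of an
ambiguous rule. Distinct binding sites are merged overlapping-or-
abutting intervals of qualifying records; density is sites per kb of
the lncRNA's input-table span. Span, not spliced length, is used
because the input format carries no exon structure; an exon-aware
length would be a strict improvement where annotation exists.

Concordance scoring anchors signs to the lncRNA compartment (+ =
nuclear side), matching the ±2 pattern: +2/−2 when the RBP's
immunofluorescence compartments include the lncRNA's class, +1/−1 when
they do not, 3 when both molecules occupy both compartments, 0 when
unbound. Two combinations are not covered by the printed rules — a
Both-class lncRNA facing a single-compartment or unannotated RBP. These
score ±1 by the shared compartment (+1 when no compartment is shared,
keeping the nuclear-side anchor) and are flagged `EXTENDED_RULE` in the
output so users can filter them.

## Synthetic data generator

`fixtures.FixtureSpec` declares a toy dataset: default 2 chromosomes of
5 Mb, 20 lncRNAs and 60 coding genes laid out in deterministic blocks
(one lncRNA plus three genes every 200 kb, so each lncRNA has ~9–12
coding neighbours inside the window), 48 expression samples. Expression
is log-normal; planted pairs share a Gaussian copula at the target ρ
before exponentiation — a monotone transform, so the planted *rank*
correlation is preserved exactly in distribution. Planted chromatin
marks, loops, eCLIP patterns, fractions and IF compartments are written
into the corresponding tracks, and every planted fact is recorded in a
manifest for assertion. The generator emulates track formats and
planted effect structure, not real data's properties: no distance-decay
of correlation, no spatial autocorrelation of chromatin, no expression-
level dependence of eCLIP coverage, uniform null correlation. Passing
recovery tests therefore demonstrates that the rules are implemented
and detectable signals propagate end to end — not field performance on
real cohorts.

## Problem sizes and numerical choices

Recovery suites run at the generator's default scale: sensitivity of
planted ρ = 0.9 pairs (10 planted + 40 null pairs, n = 48 samples,
100 seeds; recovery demanded at adjusted p < 0.05 with ≥ 95%
sensitivity) and quadrant placement of planted mechanisms (20 seeded
full-pipeline runs, ≥ 18/20 required). Determinism is asserted
byte-for-byte on all output files. Correlation of pairs with a constant
expression vector or fewer than 3 samples is undefined: such pairs are
excluded from the BH family and written with NA statistics rather than
dropped. Sort-order validation of the input applies to the rows that
survive per-row rejection, using effective (post-swap) coordinates when
`--swap-malformed` is active. Coordinates are 0-based half-open
throughout; overlap means ≥ 1 shared bp, so abutting intervals do not
overlap (but abutting eCLIP sites do merge, because a site split across
records is still one site).

## Known limitations

- TAD boundaries are parsed and reported per LCP but do not constrain
  pairing; the window is a fixed distance, not topology-aware.
- Annotation joins are by exact NAME string; mixed symbol/ENSEMBL
  inputs will silently miss fraction or strand records.
- The inflection cutoff assumes one dominant convexity; heavy-tailed
  score distributions with several regimes may place the cutoff at an
  interior crossing of the uppermost run.
- RBP expression in the interactome table is filled only when the RBP's
  gene appears in the user expression table.
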