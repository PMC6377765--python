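# plaidoh

Integrative cis-regulatory scoring of lncRNA–coding-gene pairs.

Most long non-coding RNAs have no known function, yet many sit in loci
with strong circumstantial evidence of transcriptional regulation:
correlated expression with a neighbouring coding gene, enhancer-like
chromatin, chromatin loops to a promoter, nuclear retention, or dense
RNA-binding-protein (RBP) occupancy. `plaidoh` combines these signals
into rankable scores so that experimentalists can prioritise lncRNAs for
follow-up. It is aimed at regulatory-genomics groups with a bed-like
expression matrix in hand and public annotation tracks (histone ChIP-seq
peaks, enhancer catalogues, ChIA-PET loops, fractionation RNA-seq, eCLIP
peaks) on disk.

## Method

For every lncRNA (or antisense transcript) the pipeline enumerates all
protein-coding genes within a ±400 kb flanking window — each such
**LCP** (lncRNA–coding-gene pair) is the unit of analysis. Per LCP it
computes the Spearman correlation ρ of expression across samples with a
Benjamini–Hochberg adjusted p-value (one family per run), a per-lncRNA
Z-score of ρ that flags the gene whose correlation stands apart from the
rest of the neighbourhood (|z| > 1), and two evidence scores:

```
transcript cis score = 10 · |−log10(adj_p + 0.001)| · (H3K4me3 + 0.1) · (fraction + 0.01)
enhancer score       = ((H3K4me1 + 1) + (H3K27ac + 1)) · (1 + ChIA/100)
```

where H3K4me1/H3K27ac/H3K4me3 are the maximal −log10 peak p-values of
ChIP-seq peaks overlapping the lncRNA locus, ChIA is the strongest
ChIA-PET interaction bridging the lncRNA and the gene, and fraction is
nuclear FPKM / (nuclear + cytoplasmic FPKM). Each score vector is ranked
and cut at its geometric inflection point (where the ranked-score curve
crosses its own least-squares line); the two cutoffs partition LCPs into
quadrants Q1 (neither score high) through Q3 (both high), with Q2
(enhancer-high) suggesting enhancer-element-mediated regulation and Q4
(transcript-high) suggesting regulation by the lncRNA transcript itself.

A separate interactome stage calls an RBP bound to a lncRNA when ENCODE
eCLIP shows maximal-score (1000) peaks in both K562 and HepG2, or in
both replicates of either line, and scores localization concordance:
+2/−2 when lncRNA and RBP are both nuclear / both cytoplasmic, +1/−1
when they disagree, 3 when both occupy both compartments, 0 when
unbound.

## Worked example

The package ships a synthetic-data generator with planted ground truth:

```
plaidoh fixtures --outdir demo_data --seed 1
plaidoh run --input demo_data/expression.tsv --config tracks.yaml \
    --outdir demo_out --seed 1
```

(`tracks.yaml` maps track names to the generated files; see
`tests/test_cli.py` for the exact keys.) On the demo dataset — 80
transcripts on 2 toy chromosomes, 48 samples — the run reports 216 LCPs
and the quadrant split Q1: 196, Q2: 15, Q4: 5. The planted
enhancer-driven pair lands in Q2 exactly as designed:

```
LNC002–GENE004  H3K4me1=9.0  H3K27ac=10.0  ChIA=90.0
                enhancer score = (9+1 + 10+1)·(1+90/100) = 39.90   → Q2
```

and the planted transcript-driven pair in Q4
(`LNC006–GENE016`: adj p = 1.4e-22, H3K4me3 = 8.0, nuclear fraction
0.9, transcript cis score 221.13). The interactome table recovers the
planted paraspeckle-like pattern — a nuclear lncRNA bound by two nuclear
RBPs:

```
LNC_NAME  RBP_NAME  BOUND  DENSITY_PER_KB  CONCORDANCE  LNC_CLASS  RBP_COMPARTMENTS
LNC010    NONO      1      0.5             2            Nuclear    Nuclear
LNC010    SFPQ      1      0.5             2            Nuclear    Nuclear
LNC012    PUM2      0      NA              0            Both       Cytoplasmic
```

Concordance 2 means bound with matching nuclear localization; PUM2 has
only a single-replicate eCLIP peak, so the binding rule rejects it and
the pair scores 0.

## Outputs

A run writes `lcps.tsv` (34-column main table: identifiers,
coordinates, distance, ρ/p/adjusted p/Z, per-mark signals, ChIA score,
nuclear fraction, positional and enhancer classes, both raw and scaled
scores, cutoffs, quadrant, RBP counts), `misc.tsv` (transcripts with
other TYPE values), `interactome.tsv` and `interactome_matrix.tsv`,
plus plot-ready tables (frequency matrix, Z-score vs distance, ranked
scores with cutoff flags, enhancer lncRNA densities) and `run.log` with
per-stage record accounting. `plaidoh compare` joins several runs'
tables into a cross-dataset conservation matrix of significant LCPs.
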