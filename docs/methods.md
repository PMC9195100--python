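# Methods

## Scope and data model

The package analyses per-cytosine methylation count tables (8-column
CGmap-style TSV: chrom, Watson-strand nucleotide, 1-based position, context,
dinucleotide, level, methylated reads, total reads) for a treatment/control
pair, together with a reference genome (FASTA) and gene models (GFF3), and
joins the results with a replicate-level FPKM expression matrix. All
in-memory coordinates are 0-based half-open on the Watson strand; strand is
encoded by the Watson nucleotide (C = plus, G = minus). Read trimming,
alignment and transcript assembly are out of scope: the package starts from
counts.

## 5-mC calling

Non-conversion is estimated as Σmeth/Σtotal over an organelle chromosome
assumed unmethylated; its complement is the conversion rate. The per-site
call is a one-sided exact binomial test, P(X ≥ m | n, r), because under
the error model an excess of methylated reads is the only signal of
methylation; no per-site multiple-testing correction is applied at this
stage (α = 0.001 is a raw cutoff; FDR control enters at the region level).
The minimum assayed depth defaults to 5 reads — sites below it are
"unassayed", never "unmethylated" — mirroring the 5-read coverage filter of
the region caller; the value is configurable. Watson and Crick cytosines
are separate sites in all summaries, matching the granularity of the input
files.

Context classification inspects the two bases 3′ of the cytosine on its own
strand (CG if the next base is G, CHG if the base after next is G, else
CHH). Cytosines whose triplet runs off the contig end are unclassified and
skipped; the vectorised scanner is tested base-by-base against a string
oracle.

## DMR detection

Counts of sites assayed in both samples are pooled per fixed 100-bp tile
and context (no sliding offset pass; fixed tiling keeps bins disjoint and
output deterministic). "Covered by five reads" is read as mean
per-cytosine depth ≥ 5 in each sample: at ~25× a per-bin total-read
threshold of five would be vacuous. The bin level is the pooled
(read-weighted) proportion Σmeth/Σtotal — the same quantity the Fisher
table tests — rather than a mean of per-site levels.

The two-sided Fisher exact p-value is the sum of probabilities of all
tables with the observed margins no more probable than the observed table.
For tables with ≤ 500 total reads the hypergeometric weights are exact
integers (`math.comb`), so tie decisions are exact and the test agrees with
full enumeration to the last bit; larger pooled tables switch to log-gamma
arithmetic with a 1 + 1e-7 relative tie tolerance (the convention scipy
uses). Any zero margin gives p = 1. Q-values are Benjamini–Hochberg within
each context × comparison. The fold criterion is the ratio of the two bin
levels with the smaller level floored at ε = 0.01, since an unmethylated
denominator would otherwise dominate the criterion.

The ≥3-differential-cytosine redundancy rule is applied as a post-filter on
bins. The supporting cytosines are counted at **raw** per-site Fisher
p < 0.05 with a ≥ 0.20 level difference. This is a deliberate choice: at
~25× depth a true 0.4 level shift yields per-site p-values around 10⁻²–10⁻³,
so demanding genome-wide per-site FDR would disable the redundancy rule
entirely and with it the region caller, whereas the multiple-testing control
of a DMR call already lives at the bin level where the test is powered. A
separate site-level DmC caller with BH q < 0.05 within context is exposed
for reporting site-level landscapes; it is a surrogate — the per-site
testing machinery used upstream of tools in this space is rarely specified
exactly — and is flagged as such.

Swapping treatment and control flips every call's direction with
bit-identical p and q values (the Fisher kernel canonicalises tables over
their row/column/transpose symmetries, so this holds exactly).

## Gene territories

Eleven mutually exclusive labels: three promoter tiers (<1 kb, 1–2 kb,
2–3 kb upstream of the TSS in transcription direction), 5′ UTR, first exon,
other exons, first intron, other introns, 3′ UTR, downstream (0–1 kb past
the gene end) and distal intergenic. Overlap resolution is by label
precedence — UTRs > exons > introns > promoter tiers > downstream — then
nearest TSS, then gene id; how overlapping territories of neighbouring
genes should be resolved is genuinely open, and genic features were given
priority because a base inside a transcript is better explained by that
transcript than by a neighbour's promoter. DMR intervals are assigned by
midpoint so that territory fractions sum to one; an any-overlap report can
be built from the same index. Promoters anchor at the annotated transcript
start (not the translation start); 5′/3′ UTR intervals from the GFF3 are
used when present. The longest transcript represents each gene.

## Integration with expression

Differential expression is a Welch two-sample t-test on log2(FPKM+1)
replicates with log2 fold change computed from pseudocounted condition
means; "up"/"down" require |log2FC| ≥ 1 and p < 0.05. This is a surrogate
for a full RNA-seq DE pipeline (which is out of scope) and is documented as
such. Expression strata for the metagene methylation profiles default to
quartiles; each gene contributes its flanks (2 kb in 20 windows each) and
its positionally scaled body (40 windows), oriented 5′→3′, and every
cytosine's counts are pooled into the single scaled window containing it —
for point data this coincides with fractional-overlap weighting except for
genes shorter than the window count, which the positional mapping still
handles.

For the DMR × DEG join, one record is produced per (gene, context) with at
least one DMR; the DMR in the highest-precedence territory (promoter tiers
first) decides the methylation direction, reflecting that promoter
methylation is the primary regulatory signal of interest. Category
percentages use the number of genes in the DEG table as denominator (the
natural population here; the raw counts are returned so any other
denominator can be recomputed). 2^−ΔΔCt is computed from replicate-mean
Ct values and is invariant to adding a constant to all four means.

## Synthetic data generator

The generator emulates the statistical structure of a high-coverage plant
WGBS experiment; defaults are the study conditions the pipeline is
validated under:

- genome: i.i.d. bases at GC fraction 0.44 (rice-like), nuclear
  chromosomes plus a 30 kb unmethylated organelle surrogate; genes
  (1–4 kb, 1–4 exons, short terminal UTRs) placed without overlap and with
  3.2 kb flanking margins so neighbouring promoters stay distinct.
- coverage: negative binomial per site (mean 25, size 5), independent
  across sites and samples; only the ~25× mean is dictated by the emulated
  study design, the dispersion is a realistic choice for WGBS depth
  heterogeneity. Zero-coverage sites are absent from a sample's table.
- methylation levels: per-context beta mixtures — CG bimodal (most mass
  near 0 and near 0.9), CHG mostly low with an intermediate component, CHH
  low — CpG dyads strand-symmetric, CHG/CHH independent per strand. The
  mixture weights are calibrated so the binomial caller reports ~15%
  genome-wide 5-mC with CG > CHG > CHH, inside the 13–17% range typical of
  rice; this is a soft calibration, not an asserted invariant.
- error model: a methylated cytosine is never reported converted; an
  unmethylated one is reported methylated at the non-conversion rate
  (default 0.005, i.e. conversion > 99.5%). Reads are Binomial(n, L+(1−L)r).
- spiked DMRs: 100-bp bin-aligned regions whose baseline is redrawn
  uniformly (one draw per CpG dyad) on the window keeping both baseline and
  baseline+Δ inside [0.05, 0.95], so the realised per-site shift equals Δ
  exactly instead of being eroded by clipping — a hypomethylation spike on
  a near-zero CHH baseline would otherwise be unobservable. Spike bins must
  contain ≥3 CG, ≥3 CHG and ≥6 CHH cytosines so every context is testable.
- expression: log2 abundances ~ N(4, 1.5) with N(0, 0.25) replicate noise
  (3 replicates); a linked gene's stress mean shifts by −slope × Δ_promoter
  (default slope 2, promoter spike Δ = −0.6, so expected log2FC = +1.2 —
  strong stress-induced promoter demethylation that clears the 2-fold DEG
  threshold). 30% of genes are linked by default.

What the generator does **not** emulate: read-level artefacts (mapping
bias, PCR duplicates, M-bias), co-methylation correlation along the genome
outside spiked regions, transposable-element structure, and library-size
effects in expression. Passing tests therefore demonstrate the
correctness of the statistical machinery and its power under idealised
count data, not performance on real libraries.

## Benchmarks and problem sizes

Two canonical studies drive the validation suite and
`scripts/acceptance.py`: a 1 Mb genome at 25× with 100 spiked regions at
|Δ| = 0.4 for DMR recovery (recall is scored per spiked bin, recovered when
any context yields a DMR with the spiked direction, over spiked bins that
passed the bin filters; false discovery is the fraction of calls on
unspiked bins), and a 600 kb genome with 60 genes, 30% of them
expression-linked, for the integration join. These sizes exercise ~450,000
cytosine sites and ~30,000 tested bins per run while keeping a full
validation pass in well under a minute per study.

## Numerical notes

- Fisher p-values from the exact-integer path are correctly rounded
  rationals; enumeration-oracle agreement is tested at 1e-12 over all
  tables with margins ≤ 30.
- BH q-values come from statsmodels (`fdr_bh`); q ≥ p always, q = p for a
  single test.
- Degenerate inputs: zero-depth sites are dropped at ingest (logged);
  all-unassayed call sets and empty assignment sets raise; empty DMR lists
  write a header-only BED; a zero margin in a Fisher table returns p = 1.
- Determinism: a single `numpy.random.Generator` seeded from
  `SimulationParams.seed` drives genome, spikes, counts and expression in a
  fixed order; identical parameters give byte-identical FASTA/GFF3/CGmap/
  TSV/BED outputs.
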