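# Methods

## Scope and coordinate conventions

All genomic intervals are held 0-based half-open (BED convention); GTF is
read and written 1-based inclusive. The TSS of a gene is the 5'-most base
of its *canonical* transcript — the transcript with the largest summed
exon length, ties broken by lexicographically smallest id (public
annotations rarely say which TSS a pipeline used; fixing the longest
transcript makes the choice reproducible). On the minus strand the TSS is
the interval's end boundary (`end − 1` internally).

Peak–TSS distance uses two anchors on purpose: the proximal/distal call
measures from the peak *boundaries* (a peak overlapping or within 1 kb of
a TSS, inclusive at exactly 1000 bp, is proximal; beyond that, distal),
while link distances and feature classification use the *summit*, the
single base best supported by coverage. Feature labels resolve
multi-feature overlaps with the fixed priority promoter-TSS > exon >
intron > intergenic; intron ordinals count from the TSS side, so "first
intron" means the same thing on both strands.

## Peak merging

Per-sample peaks are pooled and clustered by single linkage on summit
distance: summits strictly less than 1 kb apart (same chromosome) are
linked, and linkage chains transitively. In one dimension this reduces to
grouping consecutive sorted summits with gaps < 1 kb. A chain's genomic
span can therefore exceed 1 kb — accepted behavior, since any cutoff on
pairwise summit distance either chains or splits arbitrarily. The
consensus summit is the constituent with the highest caller signal
(narrowPeak column 7), ties to the leftmost; the merged interval is the
union. Merging an already-merged set is a no-op (consensus summits of
distinct clusters are ≥ 1 kb apart by construction), which the test suite
checks along with equivalence to a brute-force union-find oracle.

## Signal quantification

Raw coverage of a merged peak is the number of read intervals overlapping
it by ≥ 1 bp under half-open semantics (an interval ending exactly where
the peak starts does not count). ChIP and input are each normalized by
total mapped reads (per million) and peak length (per kb); the normalized
input is subtracted to correct fragmentation bias and negative values are
floored at zero — an input can out-cover a weak peak by chance, and a
signed "acetylation depletion" signal has no meaning for a mark that is
either present or not.

## The NB Wald test

Counts are modelled as NB(μ, variance μ + αμ²). With 3 replicates per
group, per-feature moment estimates of α are extremely noisy, so the
pooled within-group estimate (floored at 1e-8) is moderated halfway
(weight 0.5) toward the across-feature median — without moderation the
test is badly miscalibrated at this sample size; with it, the null
rejection rate at p < 0.05 sits near 0.08 on 10,000 null features
(α = 0.1, mean 100), which the acceptance suite checks against the band
[0.02, 0.09]. The fold change `log2((m_B + ½)/(m_A + ½))` uses a 0.5
pseudocount to keep zero means finite; the Wald statistic divides by a
delta-method SE, `Var(m_g) ≈ (m_g + α m_g²)/n_g` propagated through the
log, and is referred to a standard normal, two-sided. Features with zero
mean in both groups return p = 1, log2FC = 0.

Deliberate differences from the reference DESeq2-style analysis: no
dispersion trend fitting, no Cox–Reid adjustment, no LFC shrinkage, no
independent filtering. These keep the test self-contained and exactly
testable; the calibration and power properties above document the cost.

Two significance rules coexist, as published: genes use adjusted
P ≤ 0.05, peaks use raw P < 0.05 (both with |log2FC| ≥ 1). The raw-p peak
rule is anticonservative by construction — on 10,000 peaks with 500
planted effects it yields sensitivity ≈ 1.0 but an empirical FDR around
0.6, numbers the acceptance script reports rather than hides. For the
peak test, normalized input-subtracted signal is rounded to the nearest
integer (the NB model needs count-like input) and size factors are fixed
at 1, since depth normalization has already been applied; estimating
factors again on subtracted signal would double-correct.

## Peak–gene linking

Candidate pairs are (differential peak, gene) with summit–TSS distance
≤ 1 Mb, same chromosome. The link statistic is the Pearson correlation
between the peak's normalized signal and the gene's FPKM across the
matched samples, with the two-sided p from t = r·√((n−2)/(1−r²)) on n−2
df; constant vectors make r undefined and the pair is rejected with a
recorded reason. A link needs |r| > 0.8 and p < 0.01. At n = 6 the
p-threshold dominates (|r| ≳ 0.917), so the nominal r cutoff is inert —
a property the null-calibration test exploits: uncorrelated pairs are
retained at ≈ 1%.

"Top target genes" are computed per peak direction by sorting links on p
ascending, then |r| descending, then gene id, de-duplicating genes on
their best link before truncating to k = 100 (the published ordering "by
Cor and P-value" does not specify the composite; p-then-|r| is the
deterministic reading).

## Enrichment

PWM probabilities are clamped at 1e-4 and renormalized at load so
log-odds scores stay finite. A window is a hit when its log-odds score
(vs a uniform background) reaches 80% of the matrix's maximum achievable
score, on either strand; windows containing N are skipped, and a
zero-information matrix (max score ≤ 0) is rejected as unscannable.
Motif enrichment counts sequences with ≥ 1 hit and applies the one-sided
upper-tail hypergeometric test, drawing the target-set size from the
pooled target+background collection; the default background is the
non-differential merged peaks. This replaces a ZOOPS-binomial style
motif statistic with one that is exactly testable by enumeration; motif
p-values are therefore not comparable to published motif-tool outputs.
Gene-set over-representation uses the same hypergeometric tail over a
GMT, BH-corrected across sets.

## qPCR arithmetic

Percent input: the input aliquot is a fraction f of the ChIP chromatin,
so its Ct is first advanced by log2(1/f) cycles; then
%Input = 100·2^−(Ct_ChIP − Ct_input,adj), reported on a 0–100 scale.
Fold enrichment: ΔΔCt = ΔCt_negative − ΔCt_positive and fold = 2^ΔΔCt,
oriented so that stronger enrichment at the positive locus gives
fold > 1 (the subtraction order is stated explicitly because the two
plausible orientations differ only in sign and are easy to mix up).
Relative expression is the standard 2^−ΔΔCt against a reference gene and
calibrator condition. The input dilution fraction is a required user
parameter — there is no safe default.

## The synthetic-data generator

The generator emulates the target study design: two groups × 3
replicates profiled by RNA-seq and by H3K27ac ChIP-seq with matched
input libraries on the same samples. It produces a packed toy genome
(non-overlapping genes of 2–6 exons, random strands, spread over the
chromosome by rescaled random gaps so placement never overflows),
consensus peak locations spaced ≥ 3 kb with per-sample calls jittered by
≤ 150 bp (so the 1-kb summit criterion re-merges them 1:1), and NB count
tables with variance μ + αμ² and lognormal(0, 0.1²) per-sample depth
factors; recorded total mapped read counts scale with the same factors
so depth normalization is genuinely exercised. Defaults: α = 0.05,
RNA base mean 100, ChIP base mean 500 (giving normalized subtracted
signal of order 10, the scale a ~35M-read library produces on a 1-kb
peak), input at half the ChIP baseline with no group effect, 5% of
features planted at |log2FC| = 2 (half up, half down).

Planted links rewrite a nearby gene's expression as an affine function
of the peak's normalized subtracted signal plus Gaussian noise scaled to
a target Pearson r (default 0.99), with the pair constrained to 1 Mb.
Motif instances are drawn from the PWM conditional on scoring at least
the hit threshold (rejection sampling, consensus as a fallback) and
embedded at a random position in a configurable fraction of differential
peak sequences; unconditioned sampling from a realistic PWM would leave
a fifth of "planted" sequences without a detectable hit, which would
make planting-rate guarantees meaningless.

Every output is a pure function of the config: one global seed feeds a
named, CRC-keyed RNG stream per sub-generator, so changing the number of
peaks does not perturb the RNA draws.

What the generator does **not** emulate: read-level data (FASTQ/BAM), GC
and mappability bias, dispersion–mean trends, correlated fragmentation
between ChIP and input, overlapping genes, alternative TSSs. Passing the
recovery tests therefore shows the statistical machinery is correct
under its own model, not that real libraries meet that model.

## Problem sizes and study conditions in the validation suite

Calibration and differential-recovery checks use 10,000 features with
500 planted effects, 3 vs 3. Link recovery uses ~200 planted pairs at
target r = 0.99 on a deliberately sparse genome (2 × 3 Gb chromosomes,
~900 peaks, ~225 differential at |log2FC| = 1): with 6 samples, any two
peaks that respond to group share most of their variance, so a gene
planted on one differential peak also correlates with any other
differential peak within 1 Mb. Spacing differential peaks far apart and
keeping their group effect moderate isolates the property under test —
that the correlation filter recovers planted pairs — from this inherent
confound of correlation-based linking, which remains a documented
limitation for dense real genomes. The end-to-end demo uses 400 genes
and 600 peaks, large enough for stable counts and small enough to run in
seconds.

## Known limitations

* The Wald normal reference undercovers slightly at n = 3 per group even
  with moderation; the null rate sits near 0.08, not 0.05.
* The raw-p differential-peak rule inflates the peak FDR (reported, not
  asserted, by the validation suite).
* Correlation linking cannot distinguish a true target from any gene
  whose expression tracks the group difference; with 6 samples the
  effective |r| cutoff of ~0.917 is the only guard.
* Proximal/distal percentages depend on the distance anchor (boundary vs
  summit); other tools may bin peaks differently near the 1-kb border.
* Size factors are fixed at 1 for the peak test after depth
  normalization; estimating them post-subtraction is a defensible
  alternative not taken here.
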