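# Methods

`pionuc` models and analyses a two-genotype regulatory-genomics study: a
wild type in which a pioneer transcription factor is present, and a mutant
in which it is absent.  The scientific question is how the pioneer factor
converts intrinsically nucleosome-favoring enhancer sequence into
accessible chromatin that a downstream patterning factor can bind.  This
note documents the models, the estimators, the synthetic-data generator,
and the numerical choices, in enough detail to reproduce or challenge any
of them.

## Coordinate and overlap conventions

All intervals are 0-based half-open (BED-native).  Two regions overlap iff
they share at least 1 bp; half-open abutment is not overlap.  Peaks are
unstranded and carry an absolute single-bp summit; narrowPeak files store
the summit as an offset from the interval start and are converted on load.
A peak is "non-TSS" iff both of its boundaries lie more than 1 kb from
every annotated TSS (boundary distance, not summit distance, is used for
classification; summits are used for profile anchoring).

## Track normalization

MNase coverage (per-bp count of covering fragment spans) is transformed as
`z = (log2(c + 1) - mu) / sigma` with `mu`, `sigma` fitted over all genome
positions.  The pseudocount of 1 keeps zero-coverage positions finite; a
`stride` parameter can subsample the fitting pixels on large genomes
(default 1, i.e. every bp).

ChIP coverage is divided by the genome-wide median (zero positions
included), then Z-scored using the mean and standard deviation of
positions *outside* the combined peak set, so the background fit is not
contaminated by signal.  This makes the normalized track exactly invariant
to uniform depth rescaling.  Both normalizations are monotone, so rank
statistics are unaffected.

## Peak sets

The built-in caller is deliberately simple: per-bp Poisson upper-tail
p-value of the ChIP count against `max(local input mean over 1 kb, global
input mean)` scaled to ChIP depth; contiguous significant runs closer than
100 bp are merged; the summit is the leftmost maximum of ChIP coverage in
the run.  Externally called narrowPeak files can be used instead at every
entry point.

"Combined peaks" are peaks called on pooled replicates that overlap (>= 1
bp) at least one peak in each individual replicate.  "Enriched" peaks
additionally have mean normalized ChIP >= mean normalized input over
summit +/- 100 bp (the whole peak when shorter than 200 bp).  Pioneer-bound
regions further require the summit-region mean of the Z-scored
log2(ChIP/input) track to reach 1.6445 (one-sided P < 0.05 under a normal
background).  The union of the two genotypes' enriched peak sets — with
overlapping intervals merged, each merged region inheriting the summit of
its highest-scoring contributor — defines the regions tested for
differential binding, so both genotypes are compared on identical
coordinates.

## Differential binding

Fragments are assigned to regions by midpoint within summit +/- 125 bp
(whole region when shorter than 250 bp).  Size factors are
median-of-ratios against the geometric-mean pseudo-reference over regions
with all-positive counts.

The test models genotype count sums as negative binomials with matching
first two moments (`mu = q s`, `var = q s + alpha q^2 sum(s_j^2)`, where
`q` is the common per-unit-size mean under the null and `s` the summed
size factors), conditions on the total, and doubles the smaller tail of
the conditional distribution (observed split included).  Dispersion is
estimated per region by the method of moments pooled across genotypes,
with a gamma-family mean trend `a0 + a1/mean` fitted by least squares on
the log scale.  Two refinements matter in the 2+2-replicate regime:

1. The log-scale trend fit is rescaled to match the first moment of the
   raw estimates.  Without this the fitted level is biased low (Jensen's
   inequality applied to a noisy, right-skewed estimator) and the test
   becomes about twofold anticonservative near p = 0.01.
2. The per-region estimate is shrunk toward the trend with
   df-proportional weights (residual df over residual df + prior df of 4)
   before the final conservative rule `alpha = max(shrunk, trend)` is
   applied.  The raw max rule discards no noise and costs real power.

Measured behavior under the calibration conditions used throughout (2000
regions, mean 200, dispersion 0.1, 2+2 replicates, 20 seeds): fraction of
regions at FDR < 0.1 is ~2e-5, pooled p-value KS distance from uniform
0.026; a planted 4-fold decrease in 10% of regions is recovered with power
0.83 and 4.5% wrong-sign calls.  Benjamini-Hochberg FDR is applied across
all regions jointly.

Groups: I = log2FC(mutant/wild type) < 0 and FDR < 0.1; III = log2FC > 0
and FDR < 0.1; II = everything else.  A model-free cross-check — the
difference of mean normalized ChIP in the same windows — is computed
alongside, and its sign agreement with the NB direction is reported.

The test uses ChIP counts only; counting ChIP/input ratios is exposed as
an option but not used by default, since the input's role in the original
two-sample design is underdetermined.

## Delta-MNase

`delta = mean(mutant) - mean(wt)` of normalized MNase over summit +/- 250
bp (125 bp for the motif-count analyses).  Positions whose *raw* count is
zero in a track are excluded from that track's mean (per-position mode,
the default): the log/Z transform of an unsequenced position carries no
occupancy information.  A per-region mode (drop the region if either track
has zero total reads in the window) is selectable; the two differ only at
very low coverage.  Positive delta means the region gains nucleosome
occupancy when the pioneer factor is absent.  The statistic is exactly
antisymmetric under genotype swap.

## Nucleosome calling and anchoring

MNase coverage is low-pass filtered per chromosome by zeroing all but the
lowest 2% of Fourier components — the retained band is length-independent
(periods >= 100 bp survive), which keeps nucleosome-scale structure while
suppressing sub-nucleosomal noise.  Local maxima of the filtered signal,
after per-chromosome max-normalization (making calls invariant to uniform
coverage scaling), become dyads when they exceed `min_score` (default
0.2); maxima closer than 120 bp keep only the higher.

Dyads are called on the *mutant* MNase (the genotype without the pioneer
factor, where positioning reflects sequence preference); a summit with a
dyad within 75 bp is anchored at that dyad ("nucleosomal"), otherwise at
itself ("non-nucleosomal").  Metaprofiles are arithmetic per-offset means
across anchored windows; windows crossing chromosome ends are dropped, not
padded, to avoid edge artifacts.

## Intrinsic occupancy model

The sequence-intrinsic nucleosome preference is a logistic function of
147 bp-windowed composition:

    occupancy = expit(alpha (GC - gc0) - beta ATrun)

with GC the windowed GC fraction, ATrun the windowed fraction of positions
inside A/T homopolymers of length >= 5, and defaults alpha = 12, gc0 =
0.45, beta = 6.  This is not a trained duration-HMM; it is a deliberately
minimal stand-in that reproduces the one contrast the analyses rely on —
GC-rich sequence favors nucleosomes, AT-rich homopolymer-laden sequence
disfavors them.  Externally computed occupancy tracks can be imported
(bedGraph) wherever the built-in model is accepted.

## Rank-and-bin enrichment

Pioneer-bound non-TSS regions are ranked three ways — summit reads
(normalized ChIP at the summit) descending, wild-type MNase (summit +/-
250 bp mean) ascending, delta-MNase descending — with ties broken by
input order (stable sort), then cut into sequential bins of 500 (the
remainder joins the last bin; 6008 regions give 12 bins, the last with
508).  Per bin, the observed count of members overlapping an annotation is
divided by the expected count.  Expected is the unweighted across-bin
average by default; a size-weighted variant (overall rate x bin size) is
available and makes the size-weighted mean of enrichments across bins
exactly 1.  Motif enrichment per bin is mean per-bp motif density in
summit windows over the genome-wide density.  Hotness of a region is the
maximum hotness of any overlapping HOT-annotation interval (HOT = hotness
>= 8).  Correlations report Pearson r with both an analytic p and a
two-sided permutation p (add-one estimator).

## Motif analyses

IUPAC patterns are scanned on the forward sequence and, for the reverse
strand, via the reverse-complemented pattern on the forward sequence; a
palindromic pattern matching both ways over one interval is counted once.
Hit position for all window tests is the motif midpoint, with inclusive
window boundaries.  The default pioneer motif set is the eight
CAGGTAG-family heptamers (CAGGTAG, CAGGTAA, CAGGCAG, CAGGTAT, CAGGTAC,
TAGGTAG, CAGGCAA, CAGGTCG) and the patterning set the four GGGW-family
degenerate motifs; both are config-overridable, and all analyses depend
only on the set being used consistently.

Configuration classes around a summit: "central" = at least 2 hits within
125 bp and none further out within 400 bp; "flanking" = exactly 1 central
hit and at least one more within 400 bp; "other" = the rest.  The
in-silico mutation maps C to T and G to A within hit footprints (union of
intervals, hence idempotent), acting on the plus-strand representation for
hits on either strand.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions under which every recovery claim is measured.

Genome: two 1 Mb chromosomes of GC 0.40 background.  800 bp enhancer
regions (GC 0.58; about five nucleosome footprints) carry 1-4 planted
heptamer motifs (probabilities 0.2/0.3/0.3/0.2) at recorded offsets within
+/- 100 bp of the region center, random strand.  Open regions (400 bp, GC
0.22, periodic A/T runs of 6-10 bp) come in two flavors: 200 promoter-like
regions with a TSS at the center, and 150 TSS-distal open regions — the
latter matter because the ranked pioneer-bound set must contain
intrinsically open non-enhancer members for the openness-vs-binding
contrast to be observable.  150 control regions are plain background.
After planting, chance motif occurrences anywhere in the genome are
rewritten until the scanner's output equals the planted placement set
exactly (a closed loop that makes motif-recovery tests sharp).
Region placement uses shuffled non-overlapping slots (2.4 kb spacing);
over-filled genomes raise an error rather than overlap regions.

Occupancy: the intrinsic model above, minus — in the wild type only — a
depletion field that is a sum of Gaussian footprints (depth 0.25 occupancy
units, sd 125 bp) centered on each planted motif copy, saturating at 0.75.
The per-motif value is a free simulation parameter, not an empirical
claim; it is chosen so that 1-4 motifs span partial to near-complete
depletion.  Because the footprint follows the motif layout, tightly
clustered motifs deplete locally while spread-out motifs deplete a wider
span — reproducing the central-vs-flanking footprint contrast end to end.

MNase: candidate dyads every 185 bp are weighted by the genotype's
occupancy landscape (plus a 0.02 floor); fragments have N(147, 10) lengths
and N(0, 12) center jitter, 2 x 10^6 per sample, with a per-replicate
depth jitter of +/- 10% shared across genotypes (so genotype totals stay
comparable).  Replicates differ only by their sampling streams — Poisson
resampling plus the depth jitter.

ChIP: a two-component mixture.  The background component is uniform with a
mild intrinsic-accessibility bias (amplitude 0.2) and is what input
samples draw from.  The region component gives each region a mass:
patterning factor, wild type = motif count x accessibility (1 -
occupancy at the summit), open regions 0.3, controls 1.0; mutant =
motif count x intrinsic accessibility at enhancers (a roughly 4-fold mean
drop whose exact size grows with motif count — this coupling is what
makes delta-MNase anticorrelate with log2FC among decreased regions), with
80% of the freed mass redistributed to open regions in proportion to their
accessibility and the remainder to background.  Total mass is conserved,
so the mutant's gains are exactly the wild type's losses (mass action at
fixed nuclear concentration).  The wild-type peak component holds 40% of
reads.  The pioneer factor binds enhancers in proportion to motif count in
both genotypes, open regions at 0.4, controls at 0.3.  Fragment centers
are N(summit, 60), fixed 150 bp length.

Hotness: the 150 most motif-rich enhancers carry a HOT annotation with
hotness 6 + motif count + Poisson(0.5), so binding strength and TF
co-occupancy are positively coupled by construction.

All randomness derives from one seed through tagged substreams
(`default_rng([seed, crc32(tag)])`); a fixed seed reproduces every file
byte for byte, and stages can be re-simulated independently.

What the generator does *not* emulate: mappability and GC bias, MNase
digestion bias, read-level errors, chromatin-state heterogeneity across
cells, replication timing, and any TF besides the two modelled ones.
Passing recovery tests therefore demonstrates that the estimators are
correct under the stated generative model, not that they are robust to
every artifact of real sequencing data.

## Problem sizes

Recovery and calibration claims are computed at: 2 Mb genome, 800 planted
regions (300 enhancers), 2 x 10^6 fragments per sample, 20 x 2000 regions
for the null calibration, and a 100 kb dyad array at 30x coverage — sizes
at which every quantity of interest is estimated with comfortable margin
while a complete run stays around a minute.  Rank-bin analyses on the
synthetic fixture use bins of 50 regions (about 12 bins over the ~600
called pioneer regions, mirroring the 500-region bins used at 6008-region
scale); the 500-region default applies whenever region counts warrant it.

## Known limitations

- The simplified Poisson peak caller has no dynamic local lambda beyond
  the 1 kb window and no subpeak deconvolution; at very high peak density
  nearby events merge.
- The conditional NB test covers the two-genotype design only; covariates
  or paired designs are out of scope.
- The intrinsic-occupancy stand-in is qualitative; absolute occupancy
  probabilities should not be interpreted.
- Dyad calling assumes well-separated nucleosomes (>= 120 bp); closely
  overlapping alternative positioning is reported as a single call.
- The observed flanking-nucleosome phasing shift between genotypes is
  reported by the metaprofile machinery but not asserted anywhere: it is a
  data observation, not a computable target.
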