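# Methods

## Scope and data flow

The package infers a per-chromosome karyotype from two independent
summaries of whole-genome sequencing evidence — the allele-frequency
distribution (AFD) of heterozygous sites and normalized coverage
depth — and locates contiguous regions whose sites depart from the 1:1
allelic ratio. Around that core sit a pileup-level variant caller, a
set of genome compactness statistics, a microsynteny block finder, and
a synthetic-data generator that produces inputs with the statistical
structure the analysis assumes.

```
GenomeSpec ─ generate_reference ─→ FASTA/GFF3 + region classes + truth
                   │
            simulate_pileup ─→ per-site allele counts + depth track
                   │
            call_variants ─→ VariantSite list (VCF/TSV)
              │                         │
   classify_afd + depth_copy_number     window_tracks → detect_skewed_segments
              └──── karyotype ──────────┘
```

## Variant retention

A pileup row keeps one candidate alternate allele: the highest-count
non-reference allele, ties broken lexicographically (each polymorphic
site is assumed biallelic; a third allele is treated as noise). The
site is retained iff

* alternate-allele frequency ≥ `min_var_freq` (default 0.2),
* alternate-supporting reads ≥ `min_reads2` (default 50),
* the position lies outside the repeat mask (0-based half-open
  intervals, applied before calling).

The frequency denominator is ref + alt rather than total depth, so
noise reads on a third allele do not deflate *f*; `denominator="depth"`
switches to the total-depth convention. Both thresholds are monotone:
raising either can only shrink the retained set. Indels are carried as
single-position records with VCF anchor-base alleles and the same
frequency model as SNPs.

## AFD classification

Retained frequencies are truncated to [0.2, 0.8] — the caller cannot
report below its minimum variant frequency, and the mirror bound keeps
the balanced model symmetric. Each component is a Beta distribution
parameterized by mean m and concentration κ (a = mκ, b = (1−m)κ),
renormalized over the truncation interval; ignoring the truncation
biases the 1/3 mode upward. Two fixed-mean models are fitted by
maximum likelihood (bounded scalar search over log κ; Nelder–Mead for
the mixture weight) and compared by BIC:

* **balanced-1:1** — one component, mean 1/2 (1 parameter);
* **bimodal-1:2** — components at 1/3 and 2/3 sharing κ, free weight
  (2 parameters).

Free-mean variants of both models are fitted and reported (they are
what an experimenter reads off a histogram) but never decide the label,
to avoid overfitting chromosomes with few sites. A chromosome whose
fraction of sites inside detected skewed segments exceeds
`composite_trigger` (default 0.2) is relabelled **composite**; fewer
than `min_sites` (default 20) usable frequencies yields **uncallable**
rather than an exception.

Numerical notes: κ is searched in [2, 1e8] on a log scale, so a
zero-variance point mass at 0.5 resolves to the balanced model at the
upper bound; mixture responsibilities are combined with log-sum-exp;
component log-densities use `scipy.special` primitives directly
(`betaln`, `betainc`, `xlogy`) for speed.

## Depth normalization and the karyotype

The depth baseline is the **median** of per-chromosome mean depths:
with at most a few aneuploid chromosomes the median is the depth of a
two-copy chromosome, avoiding the circularity of averaging "the
chromosomes present in two copies". Fractional copy number =
2 × depth / baseline, rounded half-away-from-zero; integers outside
{1, 2, 3, 4} are reported unresolved. Fractional copies are invariant
under rescaling all depths. The final call combines both tracks:
concordant evidence passes through; discordance is flagged with both
values (depth wins the reported number); composite AFDs defer to depth,
so a two-copy chromosome with a skewed segment stays at two copies.
Organelle copies = baseline copies × organelle depth / nuclear
baseline, reported fractional and rounded.

## Segment detection

Site categories follow integer-percent bins: balanced 40–60, skewed
20–39 and 61–80, extreme outside (reported, in neither bin). The
integer percent is round-half-down of 100 f (computed after rounding to
6 decimals to suppress binary-float fuzz), so f = 0.395 is skewed while
f = 0.405 is balanced. Windows are genome-anchored, 10 kb with a 5-kb
step by default, half-open internally; the last partial window is kept
and length-normalized in the per-kb column.

A window **flags** when it holds ≥ `min_sites` (default 5) sites and
its skewed fraction among balanced+skewed sites exceeds
`min_skew_fraction` (default 0.5). Windows below the site minimum are
**uninformative**: they neither flag nor break a run. This matters at
realistic densities — at 0.5 sites/kb a 10-kb window holds
Poisson-mean 5 sites, so ~44% of windows are below the minimum, and
letting them interrupt runs would shred every real segment into
fragments. Runs of ≥ `min_windows` (default 3) flagged windows,
tolerating `max_gap` (default 1) interior *informative* balanced
windows, become segments spanning first-flagged-window start to
last-flagged-window end. All four thresholds are exposed; the defaults
are pragmatic choices (the original cluster was identified visually,
with no published segmentation rule). Formal changepoint methods
(HMM, CBS) are out of scope.

Edge precision is limited by site sparsity: at 0.5 sites/kb the first
and last windows over a planted segment flag with probability ~0.56
each, so recovered edges wander by one to a few 5-kb steps, and a
420-kb planted segment is recovered to within roughly ±20 kb; at
≥2 sites/kb edges are reliable to within a single step.

## Synteny

Ortholog pairs (anchors) link when both members are on one contig per
genome, at most k genes are interspersed between consecutive anchors in
either genome, and the anchors agree in relative orientation. Links
chain into maximal blocks, labelled collinear (same strands, order
preserved) or inverted (opposite strands, order reversed) — both are
counted, separately labelled, since either is a conserved arrangement.
Links are computed between anchors adjacent along genome A, so blocks
are unambiguous and the linked-pair set is monotone in k, as is the
largest-block size. Orthology input must be one-to-one; many-to-many
tables are rejected with a pointer to best-hit pre-filtering. The
colocalization matrix simply tallies ortholog pairs per contig pair;
row sums equal per-contig ortholog counts.

## Compactness statistics

Densities are count/(span/1000) with percent divergence
100 × count/span; the default denominator is the full assembly length
(not the unmasked length). A variant on a class boundary belongs to the
class of its 1-based start. Gene statistics are genes/kb, introns/gene
and mean intron length (undefined, reported as None, for intronless
sets). A gene is expressed when the mean RNA-seq depth over all its
exon bases is ≥ 1.0 (missing positions count as zero; a zero-exon-length
gene is an error). GC windows are 1 kb / 500 bp; Ns are excluded from
numerator and denominator and windows over 50% N are "no-data";
anomalies are GC < 48% or > 70%, merged per polarity. Telomere arrays
are exact tandem repeats of the unit (default CCTAAAAA) within the
terminal 1 kb, reverse-complemented at the 3′ end; mismatch tolerance
is opt-in. Reported densities round to two decimals and percentages to
one, matching the precision conventions of the descriptive statistics
they reproduce.

## Synthetic genomes: what they emulate, and what they do not

`GenomeSpec` defaults encode the study conditions: 57.5% GC, telomeric
unit CCTAAAAA (10 copies per end, reverse complement at 3′), 0.50
genes/kb with Poisson(0.5) introns of ~152 ± 30 bp, gene (coding) spans
~1.5 kb so coding covers ~74% of the genome, and a haploid depth
baseline of 36.5× (73× for a two-copy chromosome; 185× reproduces the
~370× short-read regime). Per-class heterozygous-site densities are
free parameters; the defaults (coding 0.30/kb, intron 1.14/kb,
intergenic 1.08/kb) reproduce the ~3.6–3.8-fold coding deficit and a
genome-wide density near 0.5/kb. Indels are 22% of sites, matching the
published SNP/indel ratio. Skewed segments assign sites allele-copy
configurations drawn from their spec (default 1-of-3 / 2-of-3).

Depth is Poisson with mean = haploid baseline × copy number
(negative-binomial overdispersion available, off by default, since only
mean depths were reported); alternate counts are Binomial(depth,
alt copies / total copies) with no sequencing-error alleles by default.
Windowed and per-chromosome mean depths in sites-only mode use the
Poisson-sum identity (the sum of n iid Poisson(μ) draws is
Poisson(nμ)) rather than materializing per-base draws — 
distributionally identical and far cheaper. Every output is a
deterministic function of the spec seed.

Not modeled: read-level artifacts (FASTQ, mapping ambiguity, base
qualities, error spectra), linked allele phase between neighboring
sites, repeat content (the repeat mask is an input), GC-coverage bias,
and UTRs (exon ≡ coding). Passing tests therefore demonstrate correct
recovery under the stated sampling laws, not robustness to mapping
artifacts or biased coverage in real libraries.

## Problem sizes

The test suite and the acceptance script run genome simulations at
reduced scale — chromosomes of 0.1–1 Mb, 200–2000 sites per
distribution fit, 20–50 replicate genomes — sizes at which every
statistical check (3-SE recovery bands, ≥98% karyotype recovery, BIC
selection consistency) has comfortable power while a full run stays in
the minutes range on one core.

## Coordinates and conventions

1-based inclusive in GFF3, VCF, pileup and truth tables; 0-based
half-open in BED outputs, masks and window tracks. Rounding of copy
numbers is half-away-from-zero. Chromosomes are named chrI…chrXX in
descending size order.
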