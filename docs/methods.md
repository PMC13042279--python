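# Methods

This note records the models, conventions and numerical choices behind each
module, what the synthetic data does and does not emulate, and the known
limitations.

## Synthetic data: what it emulates

The generator reproduces the *design* of a two-genotype worm RNA-seq study:
5 biological replicates per genotype of paired-end 150-nt reads, circRNA
junction counts following a negative-binomial law (variance μ + φμ², default
φ = 0.05, the typical bulk RNA-seq biological-replicate scale), PCR
duplicates as byte-identical read pairs at a default 10% fraction, linear
splicing events with genotype-specific inclusion, and lifespan/qPCR/viability
tables. The default fixture plants the effects such a study looks for: a
focus locus with two alternative 3′ splice acceptors 6 nt apart (205/211-nt
exon isoforms, each circularising), whose long-isoform circle drops 2-fold in
the mutant while the A3′SS inclusion falls from 0.6 to 0.3; a handful of up-
and down-regulated circles (log2FC ±1 at base mean 30 junction pairs per
sample); one circle at mean ≈ 1 to exercise the <12 pooled-read filter; and
one gene carried by both the circRNA and the splicing programme to populate
the overlap. Survival defaults are Weibull (shape 4, wild-type scale 18 d —
mean ≈ 16.3 d, typical for N2 at 20 °C) with the mutant scale 1.1475× the
wild-type, i.e. a 14.75% mean-lifespan extension, and ~10% censoring split
among rupture/bagging/walling.

Reads are emitted only over junction-informative windows (back-splice and
linear splice-junction scaffolds), never as whole-transcript shotgun. That
choice removes any need for a gapped aligner — exact matching is sufficient
and exhaustive — while preserving precisely the quantities the analysis
consumes (junction-spanning read counts). Consequences to keep in mind:

- there is no sequencing error, no quality model, no intron/exonic
  background, and no coverage outside junctions; passing tests show the
  *quantification logic* is exact, not that the pipeline is robust to
  noisy alignment;
- duplicates are byte-identical pairs, the toy-scale equivalent of
  coordinate-based duplicate marking;
- the first mate is emitted in transcript orientation (a stranded library);
  the BSJ caller uses that to vote on strand.

Every emitted quantity is recorded in a `SimTruth` ledger (unique BSJ pairs
per circle per sample, inclusion/skipping counts per event, true PSI,
genotype map, seed), so downstream checks can demand exact equality. BSJ
pairs are drawn *without replacement* over fragment placements so "unique
after dedup" equals the recorded count with zero tolerance. The fixture also
nudges single bases at circle boundaries so that every back-splice breakpoint
is unique up to rotation — without this, a circle whose first base equals the
base following its last is only defined up to a coordinate rotation, an
ambiguity real callers resolve with splice-site signals (out of scope here).

## circRNA quantification

**Scaffold layout.** 100 nt on each side of the seam (seam at offset 100,
total 200 nt); circles shorter than 100 nt per side are tiled circularly.
Symmetric seam placement maximises the detectable overhang on both sides.

**Caller.** Exact k-mer anchoring (k = 20) of the read prefix and suffix; a
prefix anchor strictly downstream of the suffix anchor on one contig is the
back-splice signature. The breakpoint comes from maximal extension of the
prefix match, verified by exact match of the read remainder at the putative
circle start. K-mers occurring more than 4 times are ambiguous: the read is
skipped and tallied. Loci need ≥ 2 supporting reads. Strand is taken from
the orientation in which the first mate matched.

**Counting and dedup.** A pair counts for a circle when its first mate
matches a seam-spanning scaffold window exactly with ≥ 8 nt on both sides of
the seam. Duplicates collapse on the (scaffold, sorted mate-offset pair)
key. First mates matching multiple scaffolds are dropped and tallied
(configurable to credit all). Matching is orientation-agnostic, so
reverse-complementing every read leaves counts unchanged.

**Filter.** The <12 junction-read rule is applied to *pooled* unique counts
across samples (per-sample filtering at 5-replicate depth would discard most
toy features); a per-sample mode exists.

## Differential expression

TMM normalisation: reference column closest to the mean log library size,
M-values trimmed 30% two-sided, A-values 5%, inverse-asymptotic-variance
weights, factors centred to geometric mean 1. An all-zero sample is an
error naming the sample.

Per-feature NB dispersion is estimated by Cox–Reid adjusted profile
likelihood (golden-section on log φ ∈ [1e−6, 20]) and smoothed against
abundance with lowess (global geometric mean below 20 features). The
genotype contrast is a quasi-likelihood F-test: deviances of the null and
two-group fits at the trended dispersion; the denominator variance
s² = deviance/df is moderated across features by fitting a scaled-F prior by
moments on log s² (inverse-trigamma solved by Newton); F is referred to
F(1, df_res + d₀). Measured type-I error at the study design (2,000 null
features, φ = 0.05, 5v5) is ≈ 0.047 at nominal 0.05, and the implementation
agrees with Bioconductor edgeR's glmQLFit/glmQLFTest on a seeded matrix
(Spearman ρ of P-values > 0.99, |Δlog2FC| < 0.1; see
tests/test_edger_concordance.py).

log2FC is log2(mutant/wild-type) — positive means up in the mutant, the
least-surprise convention; `classify_de(..., invert_contrast=True)` negates it
for workflows whose contrast runs the other way. Fold changes are damped by
a prior count of 0.125 *on the counts-per-million scale*, which keeps
log2FC finite at zeros and exactly invariant under joint rescaling of
counts and library sizes. Classification gates on raw P by default (with
the BH-adjusted FDR always reported and a flag to gate on it instead),
thresholds |log2FC| > 0.5 and P < 0.05; 2^0.5 ≈ 1.41 is the implied minimum
detectable fold change.

## Splicing PSI

Each event reduces to junction sets: SE (two inclusion junctions, one
skipping), A3′SS/A5′SS (one vs one, the long-exon form is "inclusion"), RI
(two contiguous exon–intron boundary windows vs the spliced junction), MXE
(two vs two). Scaffolds are 100 nt per side in genomic orientation; matching
is orientation-agnostic. A read matching both forms (possible only by
sequence coincidence) is dropped and tallied. Effective lengths count the
distinct seam-spanning read-start positions per form (51 per junction at
read length 150, overhang 8); `jcec` mode adds exon-body start positions for
inclusion-specific exons.

The group test is a beta-binomial likelihood-ratio test on (I, S) across
replicates: H0 one inclusion proportion, H1 one per group, common
overdispersion ρ under both, maximised by Nelder–Mead on (logit p, log r)
with r = (1−ρ)/ρ clamped to log r ∈ [−5, 15] (the upper clamp is the
binomial limit and keeps the likelihood finite on underdispersed data). The
alternative fit is warm-started from the null optimum so the statistic is
never negative and never inflated by uneven convergence. The statistic is
referred to **F(1, n−2)** (n = informative samples) rather than χ²(1): with
5 replicates per group the overdispersion MLE's small-sample bias makes the
χ²(1) reference anticonservative (measured level 0.08–0.095 at nominal
0.05), while the F reference — the standard correction when a nuisance
variance is estimated from few observations, as in QL F-tests — restores
calibration (measured 0.048–0.062 over three 1,000-event batches). With
ρ pinned at 0 the test collapses to the closed-form binomial LRT.

ΔPSI is wild-type minus mutant, so inclusion loss in the mutant is
positive. Samples with I + S = 0 are dropped for that event; an event that
is all-inclusion or all-skipping everywhere returns P = 1 by convention.
Significance requires FDR ≤ 0.05 and |ΔPSI| ≥ 0.2.

## YCAY motifs

Overlapping occurrences are counted by a pure sliding window — the simplest
well-defined rule, pinned by an exhaustive 4-mer enumeration oracle in the
property tests. YCAY is not reverse-complement symmetric, so minus-strand
genes are reverse-complemented (exon order reversed) before scanning; a
planted plus/minus fixture pair asserts this. Per-exon counts use spliced
exon sequences; sites spanning an exon–exon boundary in the spliced form go
to a separate junction-spanning tally. For a designated (alternatively
spliced) exon the flanking-intron counts are reported, as is the unspliced
gene-body total, so any of the common counting conventions can be read off
one profile. Density bins: <20 low, 20–59 intermediate, ≥60 enriched; the
boundary value 60, which the bin labels leave unassigned, goes to enriched
(configurable). Set comparison is a two-sided Fisher exact test on the 2×2
table at a ≥20-site cut.

## Overlap

Defined at the host-gene level (not coordinate intersection): a gene enters
the circ set if any of its circles is called up/down and the splice set if
any event passes the filter. Circles without a host-gene mapping are warned
about and treated as their own single-circle locus. Records list every circ
call and event (with type and ΔPSI) per shared gene.

## Phenotype statistics

2^−ΔΔCt: ΔCt = Ct_target − Ct_housekeeping within sample, ΔΔCt subtracts
the reference-group mean ΔCt per target; any per-sample additive shift
hitting target and housekeeping alike cancels. The housekeeping gene id is a
parameter, never hard-coded. "Mean lifespan" is reported two ways because
assay reports rarely define it: the KM-restricted mean truncated at the last
observed event (the headline, robust to censoring) and the arithmetic mean
of uncensored deaths. The log-rank test is lifelines' Mantel–Cox. Viability
uses an equal-variance unpaired two-tailed t-test on replicate percentages
(replicate counts are tiny, typically 3; Welch by flag). qPCR panels are
compared per transcript on log2 folds rather than by a two-factor ANOVA.

## Orchestration and determinism

`run_pipeline` wires fixture → reads → circ → DE → PSI → motif → overlap →
pheno, all thresholds surfaced with the canonical defaults
(min_junction_reads 12, |log2FC| 0.5, α 0.05, FDR 0.05, |ΔPSI| 0.2, YCAY
bins 20/60). Every output is plain text; FASTQ is gzipped with a zeroed
mtime; the manifest stores a SHA-256 per file plus the full config (minus
the run directory) so one seed reproduces the run bit for bit. Stage wall
times go to a separate run.log excluded from hashing. Derived seeds stay
small offsets of the run seed (fixture = seed, reads = seed+1, …).

## Problem sizes

The default fixture is ~23 kb of genome, 15 genes, 11 circles, 7 events and
~12,000 read pairs per run — sized so the demo completes in seconds and the
full test suite (including the 2,000-feature and 1,000-event calibration
sweeps and a 500-seed log-rank uniformity check) stays around a minute.

## Known limitations

- Exact matching only: a single mismatch loses a read, so sequencing-error
  robustness is untested by design.
- The BSJ caller does not check GT–AG splice signals and cannot resolve
  rotation-ambiguous breakpoints; the generator avoids creating them.
- The beta-binomial LRT and NB QL test share no machinery with rMATS or
  edgeR; they are stand-ins with the same test shape, validated by
  calibration simulations (and, for the NB route, by direct concordance
  with edgeR).
- Multi-exon circles are not modelled; circularised length equals the
  genomic span of one exon.
- The five event classes are quantified from annotated event definitions;
  novel-junction discovery from reads is out of scope.
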