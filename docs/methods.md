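# Methods

`polylnc` analyses the fate of long non-coding RNAs (lncRNAs) during
interspecific hybridisation and allopolyploidisation in plants: which
loci produce lncRNAs, which of those loci are shared between parental
(sub)genomes, how transposable elements (TEs) contribute to them, how
hybrid expression deviates from the additive mid-parent expectation,
and how small-RNA and DNA-methylation landscapes move with lncRNA
activation.  Because the real sequencing data behind such a study is
far beyond desk scale, the package pairs every analysis stage with a
synthetic-data generator that plants known ground truth, so the whole
pipeline is validated by parameter recovery.

## Coordinate model

All coordinates are 0-based half-open internally.  GTF/GFF3 (1-based
closed) and BED (0-based half-open) conventions are converted only in
`polylnc.io`.  Strand `.` is allowed for TE features (repeat
annotations frequently omit strand) but required for transcripts.
Transcripts sharing a gene identifier form one locus; transcripts
without one are merged into loci by same-strand exonic overlap — a
stand-in for assembler locus identifiers, which are not available
here.

## lncRNA identification

Candidate transcripts are filtered by a conjunction of criteria:

* positional class relative to coding annotation — `u` (intergenic:
  no exonic overlap with any coding locus span), `x` (antisense:
  exon-level overlap with a coding exon on the opposite strand, or
  full containment in an intron on the opposite strand), `i`
  (intronic: full containment in a single intron, same strand);
  anything else touching a coding gene in sense is excluded;
* spliced length ≥ 200 nt;
* coding potential: score ≤ 0 kept; transcripts with a protein-domain
  hit (E < 0.001) excluded.  External scores are accepted as input; a
  built-in stand-in scores a transcript positive when its longest ORF
  across six frames reaches 100 codons, with magnitude
  `(longest − 100)/100`;
* per locus, only the longest surviving isoform is retained.

Because the criteria are a pure conjunction, the kept set is
independent of evaluation order (tested).  Transcripts with no coding
evidence are kept and logged: unlike the original tooling chain, the
evidence file is optional input here.

## Synteny and ST/SA classification

Anchors are protein-coding genes only.  Reciprocal-best hits (both
E < 1e-10) between two (sub)genomes are chained by dynamic programming
over gene-rank space: a chain may step at most `max_gap` (default 25)
ranks in either genome, with a consistent direction in the second
genome; chains are extracted best-first, each anchor used at most
once, and chains shorter than `min_anchors` (default 5) are dropped.
The chaining is verified against exhaustive enumeration of monotone
chains for small anchor sets.

Each intergenic lncRNA locus of genome A inside a block's A-span is
mapped to a corresponding B-span by linear interpolation between the
flanking anchors (padded 5 kb; within-block coordinate transfer is
approximate by construction).  Its best qualifying hit inside that
span decides the label:

* **ST** — the hit overlaps a transcribed B lncRNA locus (RPKM > 0.5
  in ≥ 1 sample of genome B);
* **SYN_PCG** — the hit overlaps a coding exon of B;
* **SA** — homology exists in the corresponding span but no B lncRNA
  is transcribed there;
* **NON_SYN** — outside all blocks, or no in-span hit.

NATs and intronic lncRNAs are excluded from this analysis because
they overlap coding genes.  The headline summary is the SA share of
syntenic homologous loci, `n_SA / (n_SA + n_ST)`.

The repo contains no aligner; hits are an input format.  For synthetic
data a naive exact-13-mer seed matcher with ungapped X-drop extension
(`polylnc.align`) generates hits — valid there because simulated
divergence is substitution-only, so every true homology lies on one
alignment diagonal.  It is not a general-purpose aligner.

## TE overlap and enrichment

Each locus is decomposed into strand-aware upstream 2 kb, exons,
introns and downstream 2 kb (flanks clipped at chromosome ends).  TEs
overlapping a region by ≥ 1 bp compete; the longest annotated TE
fragment wins, with ties broken by leftmost start then lexicographic
identifier (the tie-break beyond "longest" is this package's choice,
made for determinism).  Family proportions are per-locus (one TE per
region), not per-bp.

Family enrichment between ST and SA loci uses a two-sided Fisher
exact test per family on the has/lacks × ST/SA table.  The effect
size is `log2((p_ST + ε)/(p_SA + ε))` with a pseudo-proportion guard
ε = 0.5/n per class.  Raw p at 0.01 is the default decision rule, with
Benjamini–Hochberg q-values reported alongside.

## Expression dynamics

RPKM is `count × 10⁹ / (spliced length × library size)`.  A locus is
"expressed" at RPKM > 0.5 in at least one member of a contrast.

The in silico mid-parent is built at count level: per replicate pair,
parental counts are depth-normalised to the mean parental library
size and averaged.  Under equal depths this is algebraically identical
to mixing reads 1:1 (tested as an RPKM identity).

The differential test is a pooled exact conditional binomial test:
replicate counts are pooled per side after median-of-ratios
normalisation (or explicit library sizes when the locus set is too
small for the ratio median), and the pooled count of side A is tested
against Binomial(total, normalised depth share of A), two-sided.
Fold change uses normalised means with a 0.5 pseudo-count.  Classes:
Up (p < 0.01, FC > 2), Down (p < 0.01, FC < 0.5), Equal (expressed,
neither), NotExpressed.

This test ignores biological overdispersion, so its type-I error is
calibrated, not nominal: on negative-binomial nulls with dispersion
0.1 it is approximately correct in the low-expression regime typical
of lncRNA (per-replicate means around 5; measured rejection at
α = 0.01 stays within [0.002, 0.05]) and becomes anti-conservative at
high counts, where the fold-change gate carries the specificity (the
recovery suite verifies FDR ≤ 0.1 at four-fold planted effects under
deep counts).  Replicate-aware dispersion estimation is explicitly
out of scope.

## Methylation, metaprofiles, DMRs

Weighted methylation of an interval is `Σ meth / Σ total` over
cytosines of one context — the coverage-weighted estimator, not the
mean of per-site ratios (the distinction is tested).  No coverage
masks the value.

Metaprofiles scale each feature body to `body_bins` equal fractions
(fractional widths for short features) with fixed-width flank bins,
reverse minus-strand features, and average per bin across features,
NaN-aware.  Binning is verified against a per-bp averaging oracle.

The DMR caller is a stand-in (the study design it emulates imported
DMRs): sliding windows (100 bp, step 50) per context with ≥ 4 covered
cytosines in both samples are tested by two-sided Fisher exact on
pooled (meth, unmeth) counts; windows with p < 0.01 and |Δ| ≥ 0.1 are
merged with overlapping same-direction neighbours.  An import path
for externally called DMRs (TSV) makes the stand-in bypassable.
DMRs are associated to a lncRNA locus by greatest overlap with the
locus span ± 2 kb (ties flagged to both loci).

The methylation–expression association subsets differentially
expressed loci and reports Spearman correlation (Pearson by flag)
between the per-locus methylation-level change and log2FC, per
context.

Small-RNA reads are filtered to 20–25 nt and ≤ 50 mapped loci (plus an
optional structural-RNA blacklist), and coverage tracks weight
multi-mapped reads 1/n.

## The synthetic study design

`SimConfig` defaults define the study conditions; they are chosen once
to echo the statistical structure of a two-diploid + hybrid cotton
comparison at desk scale and are not tuned per analysis:

* two genomes (A, D) of 2 × 400 kb sharing a fully collinear coding
  scaffold of 100 genes; 120 lncRNA loci on A (8% NAT, 4% intronic by
  planted class);
* sequence divergence: 3% for coding genes (frame-preserving) and 12%
  for lncRNA homologs, echoing the observation that syntenic lncRNA
  identity is far below mRNA identity;
* TE landscape Gypsy-dominant with LINEs a ~2% minor component;
  two-thirds of lncRNA loci TE-overlapped, with LINEs skewed toward
  ST loci and Gypsy toward SA loci in the planted family mix;
* synteny classes planted by deterministic counts: 80% SA among
  syntenic loci, 5% syntenic-to-coding, 25% non-syntenic;
* counts negative-binomial (dispersion 0.1) at locus level, library
  size 300k, two replicates per sample; one-third of lncRNA loci
  reprogrammed in the hybrid with |log2 deviation| uniform on [1, 3]
  from the mid-parent (the effect-size distribution is a stand-in;
  the recovery benchmark plants a fixed four-fold effect);
* per-cytosine binomial methylation (mean depth 12×) with
  class-dependent baselines (TEs high; lncRNA-overlapped LINEs low in
  all contexts, below lncRNA-overlapped Gypsy); reprogrammed loci get
  a per-context methylation delta;
* the methylation delta is coupled to the planted log2FC through a
  Gaussian copula whose mixing weight is calibrated per dataset
  (deterministic bisection against the fixed noise vector) so the
  realised planted Spearman equals `meth_expr_rho_target` (−0.6): at
  ~45 reprogrammed loci the uncalibrated copula would realise the
  target with a standard deviation of ~0.15, making the planted
  condition itself unreliable;
* small-RNA reads drawn from a per-bp weight map: TE bodies 5×
  background, coding-gene bodies depleted with enriched flanks,
  lncRNA-overlapped TEs at 0.3× the TE weight.

One root seed spawns independent child streams per data type
(genome, counts, methylome, small RNA), so adding a data type does
not perturb the others; identical seeds give byte-identical outputs.

What the generator does **not** emulate: realistic TE sequence
structure (LTRs, target-site duplications), read-level data,
alignment artefacts, indels, assembly errors, or tissue effects.
Passing recovery tests therefore demonstrates correctness of the
pipeline's logic and statistics under substitution-only divergence
and clean annotations — not performance on real libraries.

## Problem sizes and numerical choices

Tests and the acceptance script run the full analysis on the default
2 × 2 × 400 kb design (seconds per dataset), with 2–3 datasets per
recovery measurement, 20 replicates for the differential-test null
calibration (2000 loci each) and 50 replicates for the planted-DMR
detection check — sizes chosen so the whole suite completes in
minutes on one CPU while keeping Monte-Carlo error well inside the
stated tolerances.  Ties in the longest-TE rule, best-hit selection
and longest-isoform collapse all break deterministically
(documented in the respective docstrings).  Division-by-zero cases
(no ST+SA loci, no expressed loci, constant correlation inputs,
uncovered intervals) return flagged `None`/NaN rather than raising.

## Known limitations

* The differential test is depth-share binomial: at high counts its
  raw p-values overstate significance under biological dispersion;
  interpret DE classes jointly with the fold-change gate, or import
  results from a replicate-aware NB framework.
* The DMR caller is window-based with a fixed |Δ| ≥ 0.1 gate; its
  parameters are stand-ins and externally called DMRs can be imported
  instead.
* Within-block coordinate transfer is linear interpolation between
  anchors; inversions inside a block are not modelled.
* The exact-seed matcher must not be used on real genomes (no gapped
  alignment, no composition-adjusted statistics).
* min_anchors defaults to 5; a value of 4 also appears in the
  literature this design follows — both are exposed in configuration.
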