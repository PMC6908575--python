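# Methods

## Scope and data model

The package operates on per-CpG methylation counts (forward-strand C
position, 0-based half-open intervals internally), transcript models with
sorted non-overlapping exons, repeat elements, amplicon references with
explicit CpG and SNP positions, and rooted newick species trees. Bismark
coverage files are 1-based inclusive and converted on input; bedGraph is
0-based. A bedGraph carrying only a percent column is stored as fractions
with coverage flagged unknown; region summaries then fall back to
unweighted means.

## igDMR screen

A candidate maternal igDMR must be hypermethylated in oocytes (> 0.70),
hypomethylated in sperm (< 0.30), retain methylation in the blastocyst
(> 0.25, applied only when a blastocyst track is supplied), and show an
intermediate level (closed window [0.35, 0.65]) in at least one
placenta or somatic track. The three one-sided cutoffs are strict
inequalities. An alternative blastocyst cutoff of 0.35 is available as
`ScreenThresholds.blastocyst_35_preset()`; both figures circulate for
this screen and the lower one is the default here.

Region summaries are coverage-weighted means (equal to pooled
count_meth / coverage) over sites with coverage ≥ 1; an unweighted mean
is available by flag. A region with fewer than 5 covered CpGs
(configurable) is flagged undefined, and any undefined required tissue
makes the candidate status undetermined rather than false. Weighting and
the minimum-CpG floor are this package's choices — the screen itself does
not prescribe an aggregation rule — motivated by the low, uneven coverage
of pooled-oocyte WGBS.

The intermediate-placenta criterion is applied to region means; read-level
bimodality is handled separately by the allelic module, and a full
validation composes both (screen first, then per-read analysis of the
survivors).

Conservation classes between two species over a synteny map:
`conserved` (candidate on both sides), `species_A/B_specific` (candidate
on exactly one side), `undetermined` (either side undetermined),
`no_synteny` (unpaired), plus `neither` for paired regions that are
candidates on no side — a class added so that every paired status
combination has a defined label.

## LIT annotation and enrichment

A transcript is `Up` when its TSS lies inside a repeat, `UpEdge` when the
TSS is within 100 bp (configurable) outside a repeat on the transcript's
upstream side (adjacent = 1 bp), else `none`. Ties among overlapping
repeats are broken by distance from the TSS to the repeat 5′ boundary,
then repeat length, then coordinates. Manual splice-site inspection in
the original workflow is replaced by these deterministic rules; evidence
notes carry the borderline information instead of adjudicating it.

A region is associated with a LIT when it overlaps the transcript's
exon-or-intron span (`embedded`) or begins within 2 kb (configurable)
past the transcript 3′ end (`downstream_within_window` — the "immediately
downstream" notion given a concrete default). Configuration is `sense`
when transcript strand equals the region's gene strand.

Hypermethylated domains are maximal runs of CpGs ≥ 0.70, tolerating up to
3 consecutive below-threshold sites inside a run, discarding runs of
fewer than 10 CpGs; all three parameters are defaults of this package.

Enrichment is a 1-degree-of-freedom chi-square goodness of fit of the
foreground split against the background (CGI) proportion, upper-tail,
without continuity correction. This formulation was verified to
reproduce both published example p-values from their printed counts
(1.17e-17 and 7.42e-219) before being frozen; a 2×2 contingency
chi-square does not reproduce them and is not offered. An exact binomial
upper tail is available via `method="binomial"`. When the background has
zero hits but the foreground does not, the statistic is reported as
infinite with p = 0.

## Bisulfite amplicon analysis

Alignment is global affine-gap dynamic programming (match +1,
bisulfite-consistent substitution +1 and excluded from the mismatch
count, mismatch −1, gap of length L costs 2 + (L−1)), with free
leading/trailing reference ("fit" alignment of a read inside the
amplicon) and deterministic leftmost tie-breaking. The scoring numbers
are this package's defaults — the web tools used for such data do not
publish their internals — and are exposed in `AlignScores`; the
load-bearing contract is the bisulfite-consistency rule. The kernel is
numba-jitted; tests check it against an independent pure-Python
full-matrix DP.

Read selection keeps the first 400 forward (R1) reads in file order
("top" interpreted as file order, configurable), drops reads exceeding
the mismatch allowance (default 10, with a per-reference override
mirroring the one locus in the source protocol that needed 20), and
drops reads without a unique best reference. Only top-strand chemistry
is simulated by default, matching forward-read sequencing; bottom-strand
calling is supported by flag.

Per read, each reference CpG position is called methylated (C),
unmethylated (T) or missing; the conversion rate is the converted
fraction of non-CpG reference cytosines. Reads below 90% conversion
(configurable) are dropped; reads with no non-CpG C are retained and
flagged. A control reference (e.g. lambda spike-in) yields an
independent global conversion estimate.

## Bimodal / allelic / imprinted calls

Reads are classed hyper (> 0.7), hypo (< 0.3) or intermediate by mean
methylation. Bimodality requires ≥ 10 classified reads, each extreme
class ≥ 25% of reads, intermediates ≤ 20%, and the mean of read means
within [0.35, 0.65]. All numeric cutoffs are this package's defaults for
verbally defined classes; the overall-mean window reuses the screen's
intermediate band as the concrete reading of "methylated at ~50%".

Allele assignment at the SNP is bisulfite-aware (a genomic C allele on
the top strand legitimately reads as T); C/T SNPs on the top strand (G/A
on the bottom) are intrinsically confounded and always ambiguous. The
allelic test builds the allele × {hyper, hypo} table (intermediate
strands excluded, since the allelic definition concerns fully hyper- or
hypomethylated strands), requires ≥ 5 reads per allele, and calls
`allelic` when concordance with a one-allele-methylated pairing is
≥ 0.9 and a two-sided Fisher exact p < 0.05. No multiple-testing
correction is applied across regions by default.

Parental origin comes from trio genotypes: informative only when the
offspring is heterozygous and the parents admit a unique assignment; an
offspring allele absent from both parents raises a Mendelian error. The
final lattice is monotone: imprinted (maternal/paternal) iff allelic and
origin informative; allelic without origin → `allelic_origin_unknown`;
bimodal without SNP support → `bimodal_only`.

## LTR evolution

Divergence from a family consensus is computed from a global pairwise
alignment (Biopython PairwiseAligner; match +1, mismatch −1, gap open
−10, extend −0.5). The stiff gap opening prevents clustered
substitutions from being absorbed into spurious indel pairs, which at
20% substitution density would bias the estimate low by >1 point. Each
contiguous indel counts as a single event in both numerator and
denominator (`gap_policy="events"`); `"ignore_gaps"` drops indels
entirely, and RepeatMasker milliDiv values can be carried through on
`RepeatElement.divergence` when alignment-free divergence is preferred.
Element filtering keeps lengths strictly greater than 450 bp, the
published cutoff for the 533-bp-consensus MT2A family.

Colonization nodes assume a single gain: the MRCA of all present species
(`no_data` ignored). When species under the imputed node are scored
absent — requiring independent gains or losses under that assumption —
the report flags the locus `discontiguous_presence` rather than deciding
between scenarios.

## Synthetic data: what it emulates, and what it does not

The generator plants igDMRs (default 20% of 200 regions, 30% of those
LIT-driven) on a single synthetic chromosome: every region is a 20-CpG
grid at 50-bp spacing; LIT-driven regions get an upstream LTR repeat and
a transcript starting inside it and spanning the region; non-LIT igDMRs
are transcribed from a non-repeat promoter; background regions are
untranscribed. Tissue truth means (igDMR vs background) default to
oocyte 0.90/0.10, sperm 0.05/0.05, blastocyst 0.45/0.10, placenta and
liver 0.50/0.10 — an igDMR profile that satisfies the screen with margin
and a background that fails the oocyte criterion. Counts are
beta-binomial per CpG (concentration 50, coverage 20, both exposed); the
simplest overdispersed count model, since no noise model is prescribed
by the analysis itself. `beta_concentration = inf` is the noise-free
(infinite-coverage) limit: counts are the deterministic rounding of
coverage × truth mean, exact with the defaults because all means sit on
a 0.05 grid at coverage 20.

Amplicon simulation: a 200-bp reference with 10 evenly spaced CpGs,
scattered non-CpG cytosines for conversion QC, and an A/G SNP; maternal
reads (probability 1/2, carrying the reference allele) methylate each
CpG at 0.9, paternal at 0.05; unmethylated and non-CpG cytosines convert
C→T with probability 1 − 0.01; uniform base errors at 0.002 are applied
last. The per-CpG counts in the amplicon defaults (10–11 CpGs) mirror
the targeted assays this emulates. An `allele_independent_bimodal` mode
draws each read's hyper/hypo template independently of its allele — a
bimodal but non-allelic locus, the null of the allelic test. Trios are
opposite-homozygous (informative) or double-heterozygous
(uninformative), with the maternal allele pinnable for joint
amplicon+trio simulations.

Not emulated: read-level WGBS (tracks are per-CpG counts), PCR
duplicates and paired-end structure, indel sequencing errors,
within-region methylation heterogeneity, linked SNP haplotypes beyond a
single site, and realistic genome composition around the planted
regions. Passing tests on this generator therefore demonstrate
correctness of the decision rules and estimators under the assumed
statistical structure, not robustness to artefacts absent from it.

## Problem sizes and numerical choices

The validation suites run at sizes chosen to make their checks exact or
statistically decisive while remaining quick: 200-region bundles for the
screen (noise-free limit for exact truth recovery), 500 random ≤ 30-bp
pairs against the brute-force aligner oracle, 100 seeded replicates of
the 400-read amplicon recovery, 500 replicates of the 100-read null
calibration, and exhaustive enumeration for the 27 trio genotype
combinations and all 31 presence subsets of a 5-leaf tree. Seeds fix all
randomness; identical seeds give byte-identical outputs. Ties in the
aligner and in repeat/LIT selection are broken deterministically
(leftmost placement; distance, then length, then coordinates).
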