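# Methods

This note documents the models, estimators and numerical choices behind
`mitopop`, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## Coordinate and format conventions

Internal coordinates are 0-based half-open everywhere. GFF3 (1-based
inclusive) is the single conversion surface, handled once in
`mitopop.io`; coverage tables follow the BED-like convention. Readers
validate strictly and reject malformed input rather than repairing it.
`N` is a legal sequence character but marks the containing CDS as
*ambiguous*: ambiguous genes are excluded from the allele database and
their isolates from "complete profile" counts, mirroring the common
practice of restricting profile/phylogeny analyses to isolates without
ambiguous bases.

## Synthetic populations

The generator's purpose is ground truth: every downstream stage can be
tested against a record of what was planted.

**Master-grid model.** A single "master" genome — the reference with
*every* registry intron present — defines one fixed-length coordinate
grid. Lineage mutations, admixture crossovers and introgression
replacements all operate on this grid; intron absence is an excision
applied only when a genome is emitted. This keeps all haplotypes
colinear (no alignment step is needed to know the truth) at the price of
excluding indel evolution, which is out of scope.

**Genome composition.** The reference carries the eight canonical CDSs
at their S288C lengths (ATP6 780, ATP8 147, ATP9 231, COB 1158,
COX1 1605, COX2 756, COX3 810, VAR1 1197 nt), two rRNAs (the large one
hosting the omega intron with its homing endonuclease), 24 tRNAs, three
free-standing endonuclease/ORF elements, GC-cluster insertions in
intergenic DNA, eight optional COX1 intron sites and six COB sites.
Coding sequences are random AT-leaning codons with no internal stop
under the yeast mitochondrial code; intergenic DNA is drawn at AT
fraction 0.82 (configurable), matching the genome's strongly AT-rich
character. Default genome length is 85 kb.

**Substitution model.** Independent per-site substitution at a
per-branch probability: `per_site_mutation_rate_cds` on exonic CDS,
`per_site_mutation_rate_intergenic` elsewhere. Replacement bases are
uniform over the three alternatives in CDS and AT-biased outside, so
intergenic composition is stationary. The defaults (0.00425 / 0.0085)
were chosen so that two random lineages differ at ≈ 2 × 0.00425 ≈ 0.0085
of CDS sites, the diversity scale reported for this system. The
closed-form pairwise expectation used in tests is
P(diff) = 1 − [(1−p)² + p²/3].

**Population structure.** Founder lineages diverge independently from
the reference (star tree); each isolate adds private mutations at
`within_lineage_rate_scale` times the branch rate; a configurable
fraction of isolates are single-generation crossovers between two
lineage haplotypes at uniformly drawn breakpoints. Intron gain/loss is
applied per lineage per site (presence inherited through admixture from
whichever haplotype contributes the site's locus). The donor species is
the same master evolved at `donor_divergence` (default 0.02
substitutions/site in CDS), which must exceed the intraspecific rate so
diagnostic markers exist.

**Cellular state and coverage.** Ploidy is drawn from a configurable
distribution (default mostly diploid), per-haploid copy number from a
Gamma with mean 18 and CV 0.25, and petite status with probability
0.015 (of which 13 % are rho− retaining 1–2 random genes, the rest
rho0), matching the roughly 15-in-1000 incidence and the 2-of-15 rho−
share observed in natural panels. Feature depth is the median of
per-site Poisson draws with mean `nuclear_depth_per_haploid × ploidy ×
per_haploid_cn` for mitochondrial features (noise floor 0.05× for lost
genes) and `× ploidy` for nuclear chromosomes (2 000-site sample per
chromosome). All randomness flows from one root seed through
fixed-order child streams (master, population, donor, coverage, cohort
truth, reference intron presence), so identical configs give
byte-identical FASTA/GFF/TSV output.

**What the generator does not emulate.** Indels; GC-cluster mobility;
read-level artefacts (chimeras, mapping bias — depths are ideal
Poisson); selection (all sites neutral, so simulated dN/dS ≈ 1, unlike
real mitochondrial CDSs under purifying selection); recombination
hotspots; and sequence loss in petites (petite isolates still emit full
assemblies; their state lives in the coverage/truth tables). Passing
tests therefore demonstrate correctness of the estimators under a clean
generative model, not robustness to assembly or mapping error.

## Allele profiling

Allele IDs are 1-based integers per gene in first-seen order; the
emitted per-gene multi-FASTA (`gene_alleleID` headers) records the
sequence↔ID mapping, so re-encoding the same input order is stable and
re-building from the database's own output is idempotent.

CDS extraction prefers annotations (gene span minus nested introns,
reverse-complemented for minus-strand genes). Without annotations, the
full reference CDS is located by infix alignment (edlib, both strands,
default identity ≥ 0.70). This search cannot bridge introns, so
intron-containing genes in unannotated genomes are reported missing —
supply annotations for COX1/COB. Element and intron presence uses
full-query infix alignment with identity = 1 − edits/|query| at the
classic 90 %/90 % cut-off; full-length alignment makes query coverage 1
by construction, with unaligned ends charged to the edit distance.

GC clusters are maximal runs of 20-nt windows with GC ≥ 0.70 (both
defaults configurable; no standard criterion exists, so these are
package choices). Orientation is the strand of the best motif
alignment; two or more non-overlapping motif copies in one cluster are
flagged as a tandem duplication.

## Diversity statistics

π is the mean over unordered pairs of (differing comparable sites /
comparable sites). Columns containing a gap are counted as indel
positions and excluded; N is deleted pairwise (a "pairwise" gap policy
and complete-deletion alternatives are exposed). π of a two-sequence
alignment equals their distance exactly, and the implementation is
checked against a brute-force double loop to 1e-12.

dN/dS is Nei–Gojobori (1986): per-codon synonymous site fractions
(stop-codon mutations excluded from the denominator), pathway-averaged
difference counts that avoid stop-passing pathways, Jukes–Cantor
correction, under NCBI translation table 3 (the organellar code of the
organism; e.g. TGA = Trp, CTN = Thr, ATA = Met). The reported statistic
is the median over isolate-vs-reference pairs (an all-pairs mode is
available); pairs with dS = 0 and dN > 0 are undefined, excluded and
counted. No published tool/pairing is asserted to match numerically —
the choice is documented, not calibrated.

Distances are proportions of differing comparable sites over the
concatenated CDSs (indel columns excluded). Isolates missing any gene
are dropped from the concatenation with a warning.

## Trees and concordance

Neighbour joining is the Saitou–Nei algorithm; Q-matrix ties break at
the lowest index pair, and negative branch lengths are clamped to zero
with a warning (on additive input no clamping occurs and leaf-to-leaf
path lengths reproduce the input to 1e-9). Bootstrap resamples
alignment columns with replacement; support is the fraction of
replicates containing each bipartition. The implementation is
cross-checked against scikit-bio's NJ in the test suite.

CADM ranks each matrix's upper triangle (mean ranks on ties) and
computes Kendall's W with tie correction,
W = 12·S / (m²(n³−n) − m·ΣT). The permutation null relabels the
isolates of every matrix except the first; p = (count ≥ observed + 1) /
(permutations + 1). Defaults: 999 permutations, mandatory seed.
W(m, m) = 1 exactly; two exactly reversed tie-free rankings give
W = (1 + ρ)/2 at ρ = −1, i.e. 0.

## Introgression calling

Markers are positions not invariant across the union of the two species
panels where the species' major alleles (most frequent non-N base, ties
broken A<C<G<T — relevant because allele frequencies near 50 % occur)
differ. Painting states are conspecific / foreign / other / missing.
Segments are maximal runs of ≥ `min_run` (default 5) consecutive
foreign markers; missing markers are transparent (assembly gaps should
not split a segment — a conservative choice that can lengthen calls and
is logged), while 'other' breaks a run. Boundaries are midpoints
between the outermost foreign marker and the nearest flanking
non-missing marker, in concatenated-CDS coordinates (runs touching a
catalogue end extend to the CDS end). `min_run = 5` keeps isolated
false-foreign markers — expected under incomplete lineage sorting — from
seeding calls; it is a flag, not a law. Per-gene classification is
*full* when every one of the gene's markers lies in the segment,
*partial* otherwise.

## Intron analysis

The site registry is fixed to the named COX1 (ai1…ai5β) and COB
(bi1α…bi5) sites; rare sites get no special-casing. Frequencies are
present / (present + absent) with unknowns excluded. Mutually exclusive
pairs (both present somewhere, never together) carry a hypergeometric
P(0 co-occurrences | marginals). The boundary scan computes per-column
minor-allele frequencies within ±70 nt of each insertion offset and
summarises elevation as mean MAF in the adjacent 20-nt windows over
mean MAF in the remaining flank, with a label-permutation p-value; the
near/far-ratio statistic is this package's explicit formulation of a
signal usually only plotted. An invariant flank yields a missing ratio
rather than an error.

## Copy number and petites

Per-haploid CN = mean(median depth of ATP6, COX2, COX3) /
median-over-chromosomes of per-chromosome median depth; total CN =
per-haploid × ploidy. The three marker CDSs are the intron-less,
well-mapping choice and are configurable. The estimator is
scale-invariant in depth. Gene retention for petite classification uses
depth ratio ≥ `presence_threshold` (default 0.05) × population-median
per-haploid CN; no published rho−/rho0 cutoff exists, so this rule is
an explicit stand-in, exposed as a flag. Coverage tables are assumed
pre-filtered (mapping quality etc.) upstream; no GC correction is
applied.

## Structure

Inversions: features shared by reference and query (protein-coding,
rRNA, tRNA; a kind filter is exposed) form a signed permutation, which
is decomposed greedily into maximal collinear blocks; a
descending-index, strand-flipped block is an inversion. Only simple
(single-block) inversions are modelled; anything else is surfaced as
complex/unresolved rather than force-fitted. Breakpoints are the
flanking intergenic intervals — never points, because the AT-rich
repeat-rich intergenic regions where real breakpoints fall cannot be
delimited precisely. Size decomposition partitions each genome into
exonic CDS, intron, other genic and intergenic components that sum
exactly to the total, and reports OLS r² of total length against each
component (NaN under zero variance).

## Pipeline

A single YAML/JSON config (unknown keys rejected) drives the stages in
dependency order; every tunable named above is reachable from it. Each
run writes a manifest with sha256 hashes of all outputs and per-stage
timings; identical config + inputs give byte-identical manifests.

## Problem sizes in the shipped checks

The shipped verification runs use 20×500 nt alignments for the π
oracle, 30 isolates for introgression recovery, 500 depth-only isolates
for copy number, 300 for ploidy scaling, 40 genomes for intron-matrix
recovery, 200 isolates for the boundary scan and 100 random inversions
— sizes at which the stochastic checks have comfortable margins while
the whole battery completes in well under a minute.

## Known limitations

- Population-scale headline values from real panels (overall π, the
  mito/nuclear CADM W, marker counts, petite counts, genome-size
  ranges) depend on the real sequencing data and are not reproduced
  here; the package verifies the estimators, not the dataset.
- Annotation-free extraction of intron-containing CDSs is unsupported
  (see above); splicing follows annotations, and exon-edge placement may
  differ from manually curated alignments.
- The NJ implementation is O(n³) with dense matrices — fine for
  hundreds of taxa, not for tens of thousands.
- `detect_inversions` assumes each anchor feature occurs once per
  genome; duplicated features are rejected rather than resolved.
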