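# Methods

## Scope and model

`hybdiag` implements the diagnostic chain used to validate a putative
natural hybrid between two parental taxa from population samples of directly
sequenced loci.  The underlying genetic model is deliberately simple and
matches what direct Sanger sequencing of a polyploid, largely apomictic
study system can support:

- Each nuclear locus is a non-recombining aligned block.  An individual's
  consensus row is the column-wise IUPAC collapse of its (up to two distinct)
  allelic sequences; a heterozygous position appears as a two-fold ambiguity
  code ("superimposed peaks").
- Allele **presence/absence** is observable; dosage is not.  A tetraploid
  AABB and ABBB both read as the same additive consensus, so hybrid classes
  are defined on presence/absence only, and generations beyond the first
  backcross (F2, Fn) are not distinguishable.  This limitation is inherent
  to the data type, not to the implementation.
- The chloroplast is uniparentally (maternally) inherited and effectively
  haploid: one haplotype per individual, ambiguity codes there are treated
  as data errors.

## Fixed differences

A column is a *fixed substitution* when every parent-A sample carries the
same unambiguous base, every parent-B sample the same different unambiguous
base, and no parental sample shows a gap, an ambiguity code, or (in strict
mode) an N.  A *fixed indel* is a maximal run of columns in which one
parental taxon is entirely gapped and the other entirely ungapped; the run
counts as one mutational event whatever its length, and a ragged gap
boundary within the gapped taxon (individuals whose gap run ends at
different columns) disqualifies the event.

`min_per_taxon` (default 2) is the minimum number of parental samples per
taxon: below two, "fixed" is not defined, and with 2–4 samples a warning is
emitted because fixation may be a sampling artefact.  The study design this
package mirrors used 18–26 individuals per parental taxon.  Missing-data
handling is strict by default (any parental N disqualifies the column); a
`missing_tolerance` fraction can relax this, since no standard rule exists
for consensus exports.

Indel heterozygotes cannot be written in a single FASTA consensus row (the
trace is frame-shifted downstream of the indel).  The convention here is:
the row carries the full-length allele, and a sidecar flag
(`locus:start-end` in the fourth column of the sample map TSV) records that
the gapped allele is also present.  Additivity scoring treats a flagged
candidate as heterozygous for that indel.

## Additivity

At a diagnostic site with parental bases a and b, a candidate character c is
*additive* iff expand(c) = {a, b}; it is parent-like iff expand(c) = {a} or
{b}; anything else — including three-fold codes, N and gaps — is *other*.
Three-fold codes can never satisfy a two-parent test and are deliberately
not rescued.

## Phasing

Phasing is parsimony anchoring to parental references, not statistical
phasing: with k heterozygous columns the 2^(k−1) consistent haplotype pairs
are enumerated and the pair minimising the summed Hamming distance of each
member to its nearest parental reference is returned.  A non-unique minimum
returns an explicit `unphaseable` flag — the method never guesses, which
keeps the downstream evidence exact and the behaviour deterministic.  The
reference set is the homozygous parental rows observed at the locus, which
in low-diversity selfing/apomictic populations is essentially the parental
haplotype pool.  Columns inside flagged het-indel runs are excluded from the
distance (they are unresolved until the indel alleles are assigned); after
substitution phasing, the member nearer a gap-carrying parental reference
receives the gapped allele.  The enumeration cap (`phasing_cap`, default 12
in the library; the pipeline passes 16) bounds the exponential cost; 16 het
columns cost 2^15 evaluations over the het columns only, a few milliseconds.

Haplotype labels are assigned per (taxon, locus) in order of descending
carrier count, ties broken lexicographically by sequence, so outputs are
stable across runs.

## Hybrid classes, maternal parent, clonality

Per nuclear locus: all diagnostic evidence additive/heterozygous → AB; all
parent-A-like → AA; all parent-B-like → BB; any internal contradiction or
`other` site → other.  Multilocus: all AB → F1; AB+AA only → backcross
toward A (symmetrically B); all AA → parental A; otherwise complex; loci
with `other` evidence above `other_tolerance` (default 0) → ambiguous.  A
backcross call requires both one AB and one homozygous-parental locus, so
single-locus data can never yield one.

Maternal assignment is exact chloroplast haplotype matching against the
parental inventories: a match to exactly one parent assigns it (a
single-carrier match is annotated as a rare variant); matches to both
parents are uninformative; matches to neither leave the sample unassigned.

Clonality partitions candidates into groups of identical multilocus
genotypes (sorted phased pair per nuclear locus + chloroplast haplotype).
A single group covering all candidates is reported as "consistent with a
single clonal (apomictic) lineage" — sequence identity cannot by itself
prove single origin, so the wording is deliberately conservative.

## Median-joining networks

Characters are the variable alignment columns with gap as a fifth state;
each registered or inferred multi-column gap run is collapsed to one binary
presence/absence character so a long indel costs one step.  Construction
iterates: (1) pairwise Hamming distances; (2) the minimum-spanning network —
every link whose length is within ε of the single-linkage merge level of its
endpoints (ε = 0 default, the common published choice); (3) quasi-median
(consensus) vectors of connected triples (per character the majority state;
all-distinct characters branch over the three states), greedily adding the
candidate that most reduces the spanning (MST) cost, ties broken by
lexicographically smallest vector; (4) removal of medians whose deletion
leaves the cost unchanged; repeated to a fixed point.  A final
minimum-subset cleaning step keeps only medians appearing in some
minimum-cost solution; it is exponential in the median count and defaults
to on for networks of ≤ 12 nodes, off above.  All tie-breaks are
deterministic, so identical inputs yield byte-identical networks.

## Ploidy

Peak finding: modes of a Gaussian KDE on log fluorescence; events are
assigned to the nearer mode before statistics are computed so neighbouring
peaks do not pollute each other; peak means are trimmed means within ±2 SD.
Trimming resists the debris tails real suspensions produce.  Fewer than two
modes, under-populated peaks (< 200 events) or separation below twice the
pooled SD are errors, not guesses.  The internal standard's peak is the one
inside a declared channel window.  Then
`2C = peak_sample/peak_standard × standard_2C` (scale-invariant by
construction) and ploidy = nearest integer of
`reference_ploidy × 2C/reference_2C`, flagged low-confidence when the
pre-rounding value deviates from the integer by more than 0.25.  Ploidy is
strictly *relative*: a reference taxon of known ploidy (here the diploid at
1.09 pg, anchored by published chromosome counts) must be supplied.

## Synthetic data generator

The generator emulates the study design the pipeline assumes: a shared
random background sequence per locus (uniform ACGT, seeded), diagnostic
substitutions drawn without replacement outside indel ranges, fixed indels
as contiguous gap blocks in one parent, within-taxon variants as
single-substitution neighbours of the taxon core haplotype at non-diagnostic
positions (matching the shallow one-step structure of the observed
networks), F1 consensus rows as column-wise IUPAC collapses of one haplotype
per parent, byte-identical apomictic clones, chloroplast haplotypes copied
from the designated maternal parent, and two-Gaussian flow streams.  One
seed drives everything; the same config is byte-reproducible.

Three generator choices matter for interpreting test results:

- **Parental individuals are homozygous** at nuclear loci.  The taxa
  emulated are predominantly selfing or apomictic, and homozygous parents
  make per-locus haplotype counts exactly recoverable.  Real outcrossing
  populations would contain heterozygous parents, whose phasing is harder;
  passing tests therefore say nothing about parental-phasing accuracy in
  outcrossing systems.
- **Backcross gametes are conditioned on diagnosability**: draws are
  repeated (seeded) until at least one locus is heterozygous and one
  homozygous-parental.  An unconditioned backcross can by chance inherit the
  hybrid's same-parent allele everywhere and become genotypically parental —
  no presence/absence method could recover it, and the generator's truth
  table only promises classes that are recoverable in principle.
- **Truth clone groups are the realized identity partition** of the emitted
  genotypes, which is exactly the quantity the clonality assessment
  estimates.
- An optional per-site allele-dropout rate (default 0) simulates genotyping
  noise for robustness probes; it is off in all shipped analyses.

What the generator does *not* emulate: recombination within loci, gene flow
after the initial hybridization, PCR/sequencing error, alignment error, and
coalescent within-taxon genealogies.  Passing recovery tests therefore
demonstrate the pipeline's correctness under its own model, not robustness
to violations of it.

## Reference dataset

The built-in case study re-encodes the published per-taxon states at every
diagnostic position of the 11 loci (aligned lengths 840, 568, 461, 645, 811
nuclear; 1036, 891, 662, 648, 415, 316 chloroplast), with monomorphic
background elsewhere, drawn once from a fixed seed.  Two source defects are
handled explicitly: the six NA2 site labels exceed that locus's aligned
length and are therefore placed at shifted positions with the printed states
preserved, and the chloroplast position labels are typographically corrupt
in the source, so chloroplast positions are nominal — per-locus
distribution, states and event counts (14 substitutions, 3 indels) are the
meaningful content.  The minor chloroplast haplotype of the B parent is
carried by exactly one sampled individual and the hybrid matches it,
exercising the rare-variant maternal annotation.

## Problem sizes in the shipped analyses

The analysis scripts and test suite run the full pipeline on the 96-sample,
11-locus reference dataset (seconds), a study-design simulation of the same
shape, 1,000 random network instances of ≤ 5 haplotypes × ≤ 8 characters
against an exhaustive oracle, and 100 mixed-composition simulated datasets
(3 nuclear + 2 chloroplast loci, 12 parental samples, 13 candidates) for
class/maternal/clonality recovery.  These sizes keep the whole suite around
ten seconds while exercising every code path at population scale.
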