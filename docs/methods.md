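# Methods

## Pairwise conservation

Each non-human CDS is aligned to every human CDS with a local affine-gap
aligner (biopython's `PairwiseAligner`): match +1, mismatch −2, gap open −5,
gap extend −2, where a gap of length L costs `open + (L−1)·extend`. These
defaults approximate a nucleotide BLAST search; the downstream results are
driven by the identity/coverage filters, not by raw scores. One
highest-scoring local alignment per subject is considered and a single best
subject is returned per query, with deterministic tie-breaks (score, then
percent identity, then lexicographically smallest subject id). Percent
identity is identities divided by alignment columns *including* gap columns
(the blastn convention); coverage is the aligned span on the human CDS
divided by the human CDS length, so the human sequence is always the
reference frame.

The search is exhaustive over all subjects by default. An optional
shared-word prefilter (`seed_word`, e.g. 12) aligns only subjects sharing an
exact word with the query; it reproduces the exhaustive result whenever true
orthologs share at least one word, but short, highly diverged orthologs can
slip through a 12-mer seed, so exhaustive search is the default and the
prefilter is an explicit opt-in for large inputs.

Filters use inclusive boundaries ("at least 50%"): identity ≥ 50.0 and
coverage ≥ 0.5 retain a hit. A human CDS is conserved iff retained in all
five species comparisons; all 31 non-empty five-bit membership patterns are
counted (upset-style). Identity vectors are compared with a classical
one-way ANOVA plus all pairwise two-sample t-tests, Bonferroni-multiplied
and capped at 1. Degenerate all-constant input reports F = 0, p = 1.

## Progressive alignment

Conserved groups are aligned by profile–profile global alignment (three-state
Gotoh) following the guide tree's postorder. Column scores are average
pairwise substitution scores (match +1, mismatch −2; a gap symbol inside a
profile contributes 0). Gap penalties are deliberately stiff — open −16,
extend −4 — in the ClustalW tradition for DNA: with cheaper gaps, a pair of
compensating gaps can shift a segment out of register whenever a few columns
match by chance, which corrupts downstream SNP columns; at −16 a double-gap
excursion must beat the homologous diagonal by more than 32, which chance
similarity essentially never achieves, while true indels of ≥ 3 nt remain
far cheaper to align as gaps than to force out of register. Pre-aligned
rows may be supplied instead; they are validated to de-gap exactly to the
input sequences.

Alignments are human-referenced throughout. Columns gapped in the human row
are skipped when extracting variant columns (the analysis frame is the human
coordinate system); a gap in a non-human row counts as a difference for
variant detection but never as an allele match. CDS positions are counts of
non-gap human characters up to a column; genomic positions come from walking
the exon intervals in transcription order (descending genome coordinates
within each exon on the − strand). All coordinates are 1-based inclusive.

## Catalog matching

Catalog SNPs are matched by locating every catalog locus that falls inside a
conserved block (genome → CDS → column), not only at cross-species variant
columns: a human polymorphism exists independently of whether any model
species differs there, and at realistic divergences a large fraction of
catalog sites are invariant across the six sequences. A SNP is identified in
species S iff S's base at the column equals the catalog major allele. If the
human base at a catalog locus disagrees with the catalog major allele, the
locus is excluded and logged, never silently matched. Duplicate catalog
positions are an error.

## Disease profiles

Disease identity is the case-folded disease-name string, counted once per
species regardless of supporting SNPs or genes. Conserved diseases are the
five-way intersection; species-specific diseases appear in exactly one
species' set, with a species that has zero records contributing an empty set
(so the intersection is correctly empty). Category percentages are over
unique diseases (per-pair counting is available behind a flag) and sum to
100 per species whenever the disease set is non-empty; an empty set yields
an all-zero profile with a warning. Per-chromosome top genes break ties by
higher unique-disease count, then alphabetical gene symbol.

## Phylogeny and synteny

Blocks are concatenated in human chromosome order (numeric 1–22, then X,
then Y; then 5′ exon start). Distances use pairwise deletion — only sites
ungapped (and non-N) in both rows of a pair are compared — as p-distance or
the Jukes–Cantor correction d = −¾ ln(1 − 4p/3), which is undefined at
p ≥ 0.75 (error). Neighbor joining is the canonical Q-matrix algorithm with
ties broken on (Q, lexicographically smallest cluster pair), negative branch
lengths clamped to zero with a log note, and the final three clusters joined
by the three-point formulas. On additive matrices NJ recovers the
generating tree exactly. Topologies are compared by Robinson–Foulds
distance over non-trivial bipartitions. Bootstrap support and
maximum-likelihood inference are out of scope.

The synteny table counts, per (human chromosome, species), the conserved
CDSs mapped from each species chromosome, ordered by descending count (ties
by label order); a human chromosome is intact in a species when a single
source chromosome carries all of its conserved CDSs.

## Synthetic data

The generator emulates the statistical structure the analysis assumes: one
ancestral CDS per ortholog group (uniform {A,C,G,T}, length a multiple of 3
drawn from 300–900 nt), evolved independently down a six-taxon species tree
under Jukes–Cantor — on a branch of length d each site substitutes with
probability p = ¾(1 − e^(−4d/3)), uniformly among the three alternatives.
Indels are optional Poisson events (rate per site per unit branch length),
in multiples of 3 by default so coding frames stay plausible; frame-breaking
indels sit behind a flag for robustness tests. A deletion that would empty a
CDS is resampled and logged. Every lineage carries a per-site map to
ancestral coordinates, which yields exact truth labels: a species carries a
planted SNP's major allele iff its base at the site descending from the same
ancestral site equals the human base.

The default tree nests (human,(macaque,marmoset)) with pig, and (mouse,rat)
outermost, with branch lengths ranked so the human-to-leaf path lengths
order macaque < marmoset < pig < mouse < rat, scaled so the maximum
leaf-to-leaf path is 0.3 substitutions/site — deep enough that rodent
identities fall near 80% while everything still passes the 50/50 filters.
Human CDSs receive 1–5 exons on a toy coordinate system with both strands
represented; non-human chromosomes are a per-species relabelling of the
human set with a 10% scramble rate so synteny tables show both intact and
mosaic chromosomes. The major allele of a planted SNP is defined as the
human reference base; 1–2 distinct minor alleles are drawn. Diseases
(default 40) each get exactly one of 24 fixed DisGeNET-style categories and
one gene, supported by 1–3 SNPs from that gene. All randomness flows from a
single seed through named substreams, so identical configurations produce
byte-identical outputs.

What the generator does *not* emulate: codon structure and selection,
GC/mutation-rate heterogeneity, rate variation across sites, gene
families/paralogy, population allele frequencies beyond a major/minor
dichotomy, and annotation noise. Passing tests therefore demonstrate the
pipeline's correctness (coordinates, set logic, recovery, determinism) and
its behaviour under the assumed divergence structure — not performance on
real genomes, where paralogs and assembly artefacts would stress the
best-hit step in ways this generator does not.

## Problem sizes and defaults

The default configuration — 100 CDS groups of 300–900 nt, indel-free, 500
planted SNPs, 40 diseases over 24 categories, tree depth 0.3 — is the
package's desk-scale study condition: large enough that per-species counts
are well separated and the supermatrix (~60 kb) determines the topology
essentially without sampling error, small enough to run in a couple of
minutes. Topology-recovery checks use 25-group supermatrices across 20
seeds; the Jukes–Cantor divergence check uses ≥ 30 kb per branch length so
the closed form is tested within three standard errors.
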