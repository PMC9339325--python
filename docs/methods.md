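# Methods

This note records the models, conventions, and numerical choices behind
each module, what the synthetic generators do and do not emulate, and the
design decisions taken where the design was genuinely open.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open on named scaffolds; GFF3
(1-based closed) and BED (0-based half-open) are converted at the I/O
boundary, so round-trips are identities.  Interval merging treats
touching intervals (`end == start`) as adjacent-and-merged: flanked gene
regions that abut belong to one cluster region, and documented merging is
what makes region counts reproducible.  Overlap requires at least one
shared base on the same scaffold; strand is ignored for region overlap
because TE proximity is strand-agnostic.  Flanked regions are clipped to
`[0, scaffold_length)` when scaffold lengths are supplied.

## Translated search and gene models

The search emulates a translated homology search (tblastn-style) by
*exhaustive* local alignment: each query protein is aligned against all
six frame translations of each scaffold with BLOSUM62, gap open 11,
extend 1 (Biopython's `PairwiseAligner`, plain Smith–Waterman).  A raw
score threshold (`min_score`, default 60) plays the role of an e-value
cutoff; determinism and checkability against a quadratic DP oracle were
preferred over heuristic seeding, which desk-scale genomes do not need.
Within one (query, frame) pair, hits are found best-first and the aligned
stretches masked with a strongly penalised character before re-searching,
so every paralogous locus in the frame is reported.  Only the aligned
blocks are masked — the long internal gaps of an alignment that jumps
across an intervening locus remain searchable.

Alignments are split into exon-candidate HSPs wherever the genome-side
gap exceeds 15 aa (45 bp): smaller gaps are ordinary indels, larger ones
intron candidates.  Chaining then assembles collinear HSPs (query and
genome order both increasing; genomic gap ≤ `max_intron_bp`, default
50,000 bp, a standard RNA-mapping intron bound) by dynamic programming.
Three conventions matter in tandem arrays, where cross-locus chains score
as well as true ones:

* a gap penalty of 10 score units per kb of intron prefers compact models
  when scores tie;
* consecutive HSPs may overlap by up to 60 aa on the query (alignment
  trimming slack), with overlapping columns discounted at 4 units each;
* a chain may not skip across another HSP of the same query lying wholly
  inside the implied intron — a genuine intron does not contain a
  high-scoring exon hit, but the next tandem paralog does.

Best chains are extracted greedily; models with > 50% reciprocal overlap
of the shorter span are reduced to the higher-scoring one (one gene per
locus).  Because a local alignment can never align a stop codon and often
trims a mismatched N-terminus, accepted models are completed like a
curator would: scan at most 15 codons downstream for an in-frame stop and
upstream for the farthest ATG not separated by a stop.  Splice-site
dinucleotides are *not* enforced: chaining is purely score-driven.

The discovery loop re-searches with each round's newly accepted proteins
until a round adds no locus; accepted loci never overlap previously
accepted ones, so the loop is bounded by the number of loci.  Output is
independent of seed ordering (queries are processed in sorted order and
locus identifiers derive from coordinates).

## Curation rules

Pairwise identity is computed on a global alignment (BLOSUM62, gap open
11 / extend 1, free end gaps) as identical positions over aligned
non-gap-pair columns.  Allele collapse single-links records at ≥ 90%
identity — single linkage because each newly annotated sequence is
compared against all previously annotated ones — and keeps the longest
protein per cluster (ties broken by lexicographically smaller id, for
determinism).  Classification: any internal stop codon ⇒ pseudogene;
else start codon AND terminal stop AND protein length strictly > 350 aa ⇒
complete; else partial.  The `TYhhhhhQF` motif check uses hydrophobic set
{A,V,L,I,M,F,W,C,Y} (Kyte–Doolittle-positive residues plus aromatics) and
searches the C-terminal 100 aa, where transmembrane domain 7 lies; a
missing motif is a verification flag, never a rejection.

Summary tables: category percentages are whole-number percentages of the
total; clade percentages are clade_total / (complete + partial) × 100 at
one decimal.  Two published cells are knowingly not reproduced by this
arithmetic (a complete-gene percentage printed as 73% where 275/373
rounds to 74, and a clade percentage printed as 86.9% where the counts
give 85.6%); the functions compute the defined arithmetic and the tests
flag rather than imitate those cells.  The flow-cytometry helper is the
standard 2C-ratio formula against a 328-Mbp 1C standard.

## TE enrichment

The counting units are merged universe regions (every gene ± 10 kb,
overlaps combined); a universe region is a query member if it shares
≥ 1 bp with any query region, and "has" a TE family if any copy overlaps
it by ≥ 1 bp (no minimum TE length).  Per family, the 2×2 table
(query × family-overlap) is tested with a one-sided (greater) Fisher's
exact test — one-sided because enrichment is the direction of interest —
via `scipy.stats.fisher_exact`; the reported odds ratio is the sample
estimate ad/bc (infinite when bc = 0).  FDR correction is
Benjamini–Hochberg below 100 tests and a Storey estimator (single
λ = 0.5, π₀ capped at 1) above, applied within each level (consensus
family, and order-aggregated) of each scan.

## Reconciliation

Standard LCA-mapping duplication–loss parsimony on rooted binary trees;
non-binary nodes are rejected with an explicit error, and gene-tree
leaves resolve to species via a longest-prefix map.  A gene node is a
duplication iff it maps to the same species node as one of its children.
Losses: for each gene edge, every speciation passed without leaving a
descendant in the sibling subtree records one loss on the branch into
that sibling (when the parent is a duplication, its own species node
counts as passed).  Gains on a species branch are the duplications mapped
to the branch's child node; duplications mapping to the species root are
reported on a stem branch above it.  The family originates at the gene
root's mapping: ancestral counts are zero outside that subtree, the
origin node counts the founding lineage plus its branch's gains, and
every branch below obeys `count(child) = count(parent) + gains − losses`;
leaf counts always equal the observed per-species repertoire sizes.
Rearrangement of weakly supported gene-tree nodes is out of scope — input
topologies are taken as correct.

## Codon models and the selection cascade

The GY94 generator sets `q_ij ∝ π_j · κ^[transition] · ω^[nonsynonymous]`
for single-nucleotide codon changes over the 61 sense codons, zero
otherwise, scaled so the equilibrium expected substitution rate is one
per codon site; for site-class mixtures all classes share one scale
factor (the background-mixture average), as codeml does.  Codon
frequencies default to F3x4 estimated from the alignment (with a 0.5
pseudocount per nucleotide cell); F1x4-style uniform frequencies are
available.  Likelihoods are computed by Felsenstein pruning with site
patterns compressed, gaps treated as missing data, per-node rescaling
against underflow, and transition matrices from a symmetrised
eigendecomposition cached per (κ, ω-classes) during optimisation.
Pruning is validated against explicit summation over all internal-node
states on small instances.

Fits use box-constrained L-BFGS-B (function tolerance ~1e-6 on the
log-likelihood) with branch lengths re-optimised under every model.  The
M8 beta distribution is discretised into 10 equal-probability classes
represented by their conditional means.  M8 is warm-started from the M8a
optimum (plus a seeded hotter start), and the null is then re-fitted from
the alternative's projection: the models are nested, so this two-way
warm-starting guarantees `lnL_M8 ≥ lnL_M8a` and protects the LRT from
null under-fitting.  Branch-site model A frees ω₂ ≥ 1 on the designated
foreground branch (classes 2a/2b in proportions p0 : p1); its null pins
ω₂ = 1.  Both LRTs use a plain χ²(df = 1), which is conservative against
the 50:50 boundary mixture; site identification uses naive empirical
Bayes posteriors (> 0.95) for the positive-selection classes, not BEB.

The cascade gate semantics are exact: the M8-vs-M8a comparison runs only
when the clade's M0 ω exceeds 0.3; branch-site tests run only when that
comparison is significant at 0.05; q-values are computed across the
terminal-branch tests *within* each clade (the pooling scope is a
convention — pooling across clades would be the alternative); every
skipped stage records the gate value that caused the skip.

## Synthetic data: what it emulates, and what it does not

The genome generator plants tandem clusters of two-exon, ~400-aa receptor
genes diverged from a common ancestor by per-site amino-acid substitution
(default 0.30 substitutions/site — recognisably paralogous but
non-allelic), with allele copies at 95% identity and 95% length planted
in a dedicated zone outside the cluster (8% of genes), pseudogenes by
internal-stop injection (5%), and boundary-truncated partials (5%) made
by cutting the scaffold mid-gene.  Background (non-family) genes are
planted in tandem groups of 3–7 on a grid, kept two flank-widths clear of
family regions, so that query and non-query universe regions have
comparable footprints — without this, region-count enrichment would
confound TE density with region length.  TE copies are placed by a
piecewise-constant Poisson process: a background intensity per kb,
multiplied by the enrichment factor inside cluster ± 10 kb windows.
Default intensities (SINE 0.008/kb, LINE 0.012/kb, TIR 0.008/kb over
4 × 1.2 Mb) put per-region overlap probabilities in the informative
mid-range.  Not emulated: real TE sequence content (intervals and labels
suffice for locus-overlap testing), indel evolution, GC heterogeneity,
and assembly error beyond scaffold truncation — so passing tests show the
statistical machinery is correct, not that real-genome annotation
artefacts are handled.

Gene families evolve by a Gillespie birth–death process per lineage along
the species tree (duplications create binary nodes; losses prune);
extinct replicates are resampled with a counter, and per-branch event
truth is emitted.  Codon alignments evolve by sampling exact `exp(Qt)`
transition probabilities per site class down the tree, with truth for
every site's ω class; an ω = 0 regime provably never changes the protein,
which the tests use as a forbidden-event check.

Identity-controlled protein sets use a star design: each copy substitutes
sites at rate (1 − target)/2 from a random ancestor, giving pairwise
identities within about ±0.02 of the target; targets below ~0.2 are
rejected as unreachable for a 20-letter alphabet.

## Problem sizes used in the tests

The test suite validates at deliberately reduced scales chosen as the
smallest sizes at which each property is statistically meaningful:
exhaustive Fisher checks at margins ≤ 12; region/merging properties on
200 random instances; enrichment recovery on 20 simulated genomes
(factor 10) and null calibration on 500 neutral families against a
3,000-region universe (300 query); reconciliation exhaustively on all
gene trees with ≤ 5 leaves over a three-species tree plus 200 birth–death
replicates; M0 recovery at 2,000 codons on six taxa; the M8-vs-M8a
type-I study on 100 null replicates of 150 codons on three taxa
(optimiser capped at 50 iterations with the two-way warm start, which
biases the test conservative, never liberal); and the cascade gate on two
engineered clades (ω = 0.29 at 4,000 codons; a mixture calibrated to a
one-ratio ω ≈ 0.33 at 500 codons with ~9% of sites at ω_s = 3.5).

## Known limitations

* The annotation stage is exact but quadratic; it is meant for desk-scale
  genomes (a few Mb) and query sets in the tens, not whole assemblies.
* Chaining resolves tandem ambiguity by conventions (gap penalty,
  intron-blocking rule) that are documented rather than learned; heavily
  fragmented alignments at paralog divergence > 0.4 can still split or
  fuse occasional models.
* Reconciliation is plain parsimony: no branch-support-aware
  rearrangement, transfers, or dating.
* The selection machinery implements M0, M8/M8a, and branch-site model A
  only; no BEB, no M1a/M2a/M3/M7, and df-1 χ² rather than boundary
  mixtures for the LRTs.
* Storey's π₀ uses a single λ rather than the spline estimator; with few
  tests the package falls back to Benjamini–Hochberg.
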