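# grevol

Chemosensory gene-repertoire dynamics in insect genomes: iterative
homology annotation and rule-based curation of large receptor families,
transposable-element (TE) proximity enrichment around gene clusters,
duplication–loss reconciliation of gene trees, and a gated dN/dS
positive-selection screen — all exercisable end to end on synthetic
genomes with known truth.

## Who this is for

Comparative genomicists working on rapidly evolving multigene families —
the motivating case is the gustatory receptor (GR) repertoires of
polyphagous *Spodoptera* moths, which run to hundreds of genes organised
in tandem clusters, rich in alleles, pseudogenes, and scaffold-truncated
fragments.  Each analysis track is an importable library module; short
narrative scripts under `examples/` show one capability each, and a thin
`grevol` command-line wrapper covers file-based use.

## The methods in brief

**Annotation and curation.**  Known family proteins are searched against
all six reading frames of the genome by exhaustive Smith–Waterman local
alignment, hits are chained into exon/intron gene models, and every newly
found protein re-enters the query set until a round adds no new locus.
Curation then applies the field's standard rules: sequences sharing ≥ 90%
protein identity are alleles of one gene (only the longest is kept);
internal stop codons mark pseudogenes; a gene is complete when it has a
start codon, a stop codon, and > 350 amino acids; the conserved
C-terminal `TYhhhhhQF` motif (transmembrane domain 7) is checked as a
verification flag.

**TE enrichment.**  Every gene is expanded by a 10-kb flank and
overlapping regions are combined; the regions built from all genes form
the *universe*, those built from the family of interest the *query*.
Each universe region is scored for query membership and ≥ 1-bp overlap
with each TE consensus family, giving a 2×2 table tested by a one-sided
Fisher's exact test with Benjamini–Hochberg (or Storey, for large test
families) FDR correction.

**Reconciliation.**  Rooted binary gene trees are reconciled against a
rooted species tree by LCA-mapping parsimony: a node mapping to the same
species node as one of its children is a duplication; skipped speciations
imply losses on the sibling branches.  The resulting duplication+loss
cost is provably minimal, and per-branch gains/losses yield ancestral
repertoire sizes satisfying
`count(child) = count(parent) + gains − losses`.

**Selection screen.**  GY94 codon-model likelihoods (Felsenstein pruning
over the 61 sense codons, F3x4 frequencies) drive a three-stage cascade
per clade: the one-ratio model M0 estimates a global ω = dN/dS; only when
ω > 0.3 is the site-model pair M8 vs M8a compared by a df-1 LRT; only
when that is significant are branch-site model A tests run on every
terminal branch, with q-value correction within the clade and empirical
Bayes identification of high-posterior sites.

**Synthetic data.**  `grevol.simulate` generates (a) genomes with planted
tandem clusters, alleles, pseudogenes, boundary-truncated genes, and TE
copies placed by a piecewise-constant Poisson process with a controllable
cluster-flank enrichment factor; (b) birth–death gene-family histories
along a species tree; (c) codon alignments evolved by exact GY94
transition probabilities under M0/M8/branch-site regimes.  Every
generator is seed-deterministic and emits truth tables.

## A worked example

```bash
python examples/selection_cascade.py
```

```
clade          n  omega_M0   p(M8vM8a)  branch-site
mixed          6   0.33188     9.1e-05  NS
purifying      6   0.28836           /  /
  purifying: omega_M0=0.28836 <= gate 0.3: site test skipped
```

Two simulated clades of six sequences: the `purifying` clade, generated
with a global ω of 0.29, never reaches the site test — its one-ratio ω
sits under the 0.3 gate, and the report records exactly why.  The `mixed`
clade carries a planted class of sites at ω = 3.5; its one-ratio ω
(0.332) clears the gate, the M8-vs-M8a likelihood-ratio test is strongly
significant (p ≈ 9×10⁻⁵), and the cascade proceeds to test all six
terminal branches — here none is individually significant after q-value
correction (`NS`), the expected outcome when selection is spread across
the clade rather than concentrated on one lineage.

The other example scripts follow the same pattern:
`annotate_repertoire.py` (iterative discovery plus curation on a planted
genome), `te_enrichment.py` (the planted SINE family reaches q < 0.05,
neutral families do not), `reconcile_family.py` (inferred duplications
and losses against simulation truth), and `repertoire_tables.py`
(repertoire summary arithmetic for three published species columns).

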