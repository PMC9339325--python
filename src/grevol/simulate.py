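"""Synthetic data with the statistical structure each pipeline stage assumes.

Three generators cover the three analysis tracks:

* :func:`simulate_genome` — a small genome with tandem-duplicated receptor
  clusters containing alleles (>=90% identity), pseudogenes (injected
  internal stops), scaffold-boundary-truncated partial genes, background
  (non-family) genes for the enrichment universe, and TE copies placed by a
  piecewise-constant Poisson process with a controllable enrichment factor
  in cluster flanks;
* :func:`simulate_gene_family` — a birth–death gene-family history along a
  species tree, emitting the gene tree and the true per-branch gains/losses;
* :func:`simulate_codon_alignment` — codon evolution under the GY94 process
  (M0/M8/branch-site regimes) by exact transition probabilities, emitting
  the true omega class of every site.

Every generator is seed-deterministic and returns machine-readable truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .codon import CODON_TO_AA, EigenQ, gy94_rate_matrix, translate, uniform_frequencies
from .intervals import GenomicInterval
from .records import GeneRecord, TEAnnotation
from .selection import CodonAlignment, SiteClasses, _TreeIndex

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: codons per amino acid, for back-translation
_AA_TO_CODONS: dict[str, list[str]] = {}
for _c, _a in CODON_TO_AA.items():
    if _a != "*":
        _AA_TO_CODONS.setdefault(_a, []).append(_c)


# ---------------------------------------------------------------------------
# Genome simulation

@dataclass
class TEFamilyConfig:
    name: str
    te_class: str = "I"
    order: str = "SINE"
    background_per_kb: float = 0.05
    enrichment: float = 1.0  # intensity multiplier inside cluster flanks
    min_len: int = 80
    max_len: int = 500


@dataclass
class GenomeSimConfig:
    """Study-condition defaults for the desk-scale genome.

    The family is planted as tandem clusters of ~400-aa receptor genes
    (two exons each); category rates echo the repertoire composition seen
    in polyphagous-moth receptor repertoires: a few percent pseudogenes,
    mid-single-digit allele pairs, some scaffold-boundary partials.
    """

    seed: int
    scaffold_count: int = 4
    scaffold_length: int = 1_200_000
    cluster_count: int = 8
    genes_per_cluster: int = 5
    paralog_divergence: float = 0.30  # aa substitutions/site between paralogs
    allele_pair_rate: float = 0.08
    allele_identity: float = 0.95
    pseudogene_rate: float = 0.05
    boundary_truncation_rate: float = 0.05
    #: background genes are planted in tandem groups (sizes drawn around
    #: genes_per_cluster) so universe regions match query regions in size;
    #: otherwise region-count enrichment would confound family density with
    #: region length
    background_gene_groups_per_scaffold: int = 22
    background_group_size_range: tuple[int, int] = (3, 7)
    gene_length_aa: int = 400
    intron_length: int = 700
    cluster_flank: int = 10_000
    te_families: list[TEFamilyConfig] = field(
        default_factory=lambda: [
            TEFamilyConfig("SINE_sim1", "I", "SINE", 0.008, 1.0),
            TEFamilyConfig("LINE_sim1", "I", "LINE", 0.012, 1.0, 500, 3000),
            TEFamilyConfig("TIR_sim1", "II", "TIR", 0.008, 1.0, 200, 1500),
        ]
    )

    def __post_init__(self) -> None:
        rates = (
            self.allele_pair_rate,
            self.pseudogene_rate,
            self.boundary_truncation_rate,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        if not 0.0 <= self.allele_identity <= 1.0:
            raise ValueError("allele_identity must lie in [0, 1]")
        if any(f.background_per_kb < 0 or f.enrichment < 0 for f in self.te_families):
            raise ValueError("TE densities and enrichment factors must be >= 0")


@dataclass
class SimulatedGenome:
    genome: dict[str, str]
    genes: list[GeneRecord]           # planted family members, truth categories
    background_genes: list[GenomicInterval]
    tes: list[TEAnnotation]
    gene_truth: pd.DataFrame
    te_truth: pd.DataFrame
    cluster_spans: list[GenomicInterval]
    config: GenomeSimConfig

    def all_gene_intervals(self) -> list[GenomicInterval]:
        fam = [g.span() for g in self.genes if g.exons]
        return fam + list(self.background_genes)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate_protein(rng: np.random.Generator, prot: str, rate: float) -> str:
    out = list(prot)
    for i, aa in enumerate(out):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != aa]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _backtranslate(rng: np.random.Generator, prot: str) -> str:
    return "".join(
        _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))] for aa in prot
    )


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def simulate_genome(config: GenomeSimConfig) -> SimulatedGenome:
    """Plant clusters, alleles, pseudogenes, truncated genes, and TEs."""
    rng = np.random.default_rng(config.seed)
    scaffolds = {
        f"scaffold_{i + 1}": list(_random_dna(rng, config.scaffold_length))
        for i in range(config.scaffold_count)
    }
    scaffold_names = list(scaffolds)
    genes: list[GeneRecord] = []
    truth_rows: list[dict] = []
    cluster_spans: list[GenomicInterval] = []
    clade_letters = "ABCDEFGHIJK"

    gene_nt_len = 3 * (config.gene_length_aa + 1) + 3 + config.intron_length
    spacing = gene_nt_len + 2500
    ancestor = _random_protein(rng, config.gene_length_aa)

    slots_per_scaffold = -(-config.cluster_count // len(scaffold_names))
    gene_counter = itertools.count(1)
    allele_cursor: dict[str, int] = {}  # next free bp for allele copies
    for ci in range(config.cluster_count):
        scaf = scaffold_names[ci % len(scaffold_names)]
        slot = ci // len(scaffold_names)
        anchor = (slot + 1) * config.scaffold_length // (slots_per_scaffold + 1)
        cluster_end = anchor + config.genes_per_cluster * spacing
        if cluster_end + config.cluster_flank + 5_000 > config.scaffold_length:
            raise ValueError("scaffolds too short for the requested clusters")
        clade = clade_letters[ci % len(clade_letters)]
        cluster_proteins: list[tuple[str, str]] = []
        for gi in range(config.genes_per_cluster):
            gid = f"simGR{next(gene_counter)}"
            prot = _mutate_protein(rng, ancestor, config.paralog_divergence)
            cluster_proteins.append((gid, prot))
            start = anchor + gi * spacing
            _plant_gene(
                rng, scaffolds[scaf], scaf, start, prot, gid, clade, config,
                genes, truth_rows,
            )
        cluster_spans.append(GenomicInterval(scaf, anchor, cluster_end))
        # allele copies: near-identical duplicates planted in a dedicated
        # zone after the cluster, advanced by a cursor so copies never
        # overwrite each other
        for gid, prot in cluster_proteins:
            if rng.random() < config.allele_pair_rate:
                allele_prot = _mutate_protein(
                    rng, prot, (1.0 - config.allele_identity)
                )[: int(len(prot) * 0.95)]
                zone_start = cluster_end + 8_000 + int(rng.integers(0, 2_000))
                astart = max(zone_start, allele_cursor.get(scaf, 0))
                if astart + gene_nt_len + 1_000 < config.scaffold_length:
                    _plant_gene(
                        rng, scaffolds[scaf], scaf, astart, allele_prot,
                        gid + "a", clade, config, genes, truth_rows,
                        force_category="allele", allele_of=gid,
                    )
                    allele_cursor[scaf] = astart + gene_nt_len + 2_500

    # background (non-family) genes for the universe: tandem groups on a
    # grid, sized like the family clusters, so query and non-query universe
    # regions have comparable footprints
    background: list[GenomicInterval] = []
    lo, hi = config.background_group_size_range
    for scaf in scaffold_names:
        # keep background groups clear of family regions by two flank widths:
        # both features are flanked before merging, so regions closer than
        # 2 x flank would fuse and distort query-region sizes
        margin = 2 * config.cluster_flank + 2_000
        family_spans = [
            (g.span().start - margin, g.span().end + margin)
            for g in genes
            if g.scaffold == scaf
        ]
        n_groups = config.background_gene_groups_per_scaffold
        step = config.scaffold_length / (n_groups + 1)
        for i in range(n_groups):
            group_start = int((i + 1) * step + rng.uniform(-0.1, 0.1) * step)
            k = int(rng.integers(lo, hi + 1))
            for j in range(k):
                start = group_start + j * spacing
                end = start + int(rng.integers(500, 2_000))
                if end >= config.scaffold_length or start < 0:
                    continue
                if any(s < end and start < e for s, e in family_spans):
                    continue
                background.append(GenomicInterval(scaf, start, end))
    background.sort(key=lambda iv: (iv.scaffold, iv.start))

    # TE placement: piecewise-constant Poisson intensity
    tes: list[TEAnnotation] = []
    te_rows: list[dict] = []
    te_counter = itertools.count(1)
    for fam in config.te_families:
        for scaf in scaffold_names:
            length = config.scaffold_length
            flanks = [
                (max(0, cs.start - config.cluster_flank), min(length, cs.end + config.cluster_flank))
                for cs in cluster_spans
                if cs.scaffold == scaf
            ]
            base = fam.background_per_kb / 1000.0
            n_total = rng.poisson(base * length)
            positions = list(rng.integers(0, length, size=n_total))
            extra_rate = base * max(0.0, fam.enrichment - 1.0)
            for lo, hi in flanks:
                n_extra = rng.poisson(extra_rate * (hi - lo))
                positions.extend(rng.integers(lo, hi, size=n_extra))
            for pos in sorted(int(p) for p in positions):
                te_len = int(rng.integers(fam.min_len, fam.max_len + 1))
                end = min(pos + te_len, length)
                if end <= pos:
                    continue
                te = TEAnnotation(
                    interval=GenomicInterval(scaf, pos, end),
                    te_class=fam.te_class,
                    order=fam.order,
                    family_id=fam.name,
                )
                tes.append(te)
                te_rows.append(
                    {
                        "te_id": f"te{next(te_counter)}",
                        "family": fam.name,
                        "te_class": fam.te_class,
                        "order": fam.order,
                        "scaffold": scaf,
                        "start": pos,
                        "end": end,
                        "in_cluster_flank": any(lo <= pos < hi for lo, hi in flanks),
                    }
                )

    genome = {name: "".join(chars) for name, chars in scaffolds.items()}
    return SimulatedGenome(
        genome=genome,
        genes=genes,
        background_genes=background,
        tes=tes,
        gene_truth=pd.DataFrame(truth_rows),
        te_truth=pd.DataFrame(te_rows),
        cluster_spans=cluster_spans,
        config=config,
    )


def _plant_gene(
    rng: np.random.Generator,
    scaffold_chars: list[str],
    scaffold_name: str,
    start: int,
    protein: str,
    gene_id: str,
    clade: str,
    config: GenomeSimConfig,
    genes: list[GeneRecord],
    truth_rows: list[dict],
    force_category: Optional[str] = None,
    allele_of: Optional[str] = None,
) -> None:
    """Write one two-exon gene into the scaffold and record its truth."""
    cds = "ATG" + _backtranslate(rng, protein) + "TAA"
    category = force_category or "complete"
    if force_category is None and rng.random() < config.pseudogene_rate:
        # internal stop: disable a mid-gene codon
        k = int(rng.integers(10, len(protein) - 10))
        cds = cds[: 3 + 3 * k] + "TAA" + cds[3 + 3 * k + 3 :]
        category = "pseudogene"
    truncated = force_category is None and rng.random() < config.boundary_truncation_rate
    exon1_aa = len(cds) // 6 * 3  # split point in nt, codon-aligned
    exon1 = cds[:exon1_aa]
    exon2 = cds[exon1_aa:]
    e1 = GenomicInterval(scaffold_name, start, start + len(exon1), "+")
    intron_start = e1.end
    e2_start = intron_start + config.intron_length
    e2 = GenomicInterval(scaffold_name, e2_start, e2_start + len(exon2), "+")
    scaffold_chars[e1.start : e1.end] = list(exon1)
    scaffold_chars[e2.start : e2.end] = list(exon2)
    exons = [e1, e2]
    at_boundary = False
    if truncated:
        # keep only the first exon's worth of gene: emulate a scaffold break
        exons = [e1]
        cds = exon1
        scaffold_chars[e2.start : e2.end] = list(_random_dna(rng, len(exon2)))
        category = "partial"
        at_boundary = True
    full = translate(cds) if len(cds) >= 3 else ""
    genes.append(
        GeneRecord(
            gene_id=gene_id,
            family="GR",
            exons=exons,
            cds=cds,
            protein=full.split("*", 1)[0],
            category=category,
            allele_of=allele_of,
            clade=clade,
            at_scaffold_boundary=at_boundary,
        )
    )
    truth_rows.append(
        {
            "gene_id": gene_id,
            "scaffold": scaffold_name,
            "start": exons[0].start,
            "end": exons[-1].end,
            "category": category,
            "allele_of": allele_of,
            "clade": clade,
            "at_scaffold_boundary": at_boundary,
        }
    )


# ---------------------------------------------------------------------------
# Birth–death gene families

@dataclass
class FamilySimConfig:
    species_tree: str  # newick with branch lengths
    duplication_rate: float
    loss_rate: float
    root_copies: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.root_copies < 1:
            raise ValueError("root_copies must be >= 1")


@dataclass
class FamilySimResult:
    gene_tree: dendropy.Tree
    truth: pd.DataFrame  # per species branch: duplications, losses
    leaf_counts: dict[str, int]
    resamples: int = 0


def _bd_branch(rng, lineages, t, lam, mu):
    """Evolve lineages over a branch; returns survivors, (#dup, #loss).

    Each lineage is a dendropy node whose subtree is still being built.
    """
    dups = losses = 0
    alive = list(lineages)
    clock = 0.0
    while alive:
        total = len(alive) * (lam + mu)
        if total == 0:
            break
        wait = rng.exponential(1.0 / total)
        clock += wait
        if clock >= t:
            break
        i = int(rng.integers(len(alive)))
        if rng.random() < lam / (lam + mu):
            node = alive.pop(i)
            left, right = dendropy.Node(), dendropy.Node()
            node.add_child(left)
            node.add_child(right)
            alive.extend([left, right])
            dups += 1
        else:
            alive.pop(i)
            losses += 1
    return alive, dups, losses


def simulate_gene_family(config: FamilySimConfig, max_resamples: int = 50) -> FamilySimResult:
    """Gene birth–death along a species tree, with per-branch truth.

    Leaves are named ``<Species>_g<N>``.  A replicate in which every lineage
    goes extinct is resampled (counted in ``resamples``); exceeding
    ``max_resamples`` raises.
    """
    rng = np.random.default_rng(config.seed)
    species_tree = dendropy.Tree.get(
        data=config.species_tree, schema="newick", rooting="force-rooted",
        preserve_underscores=True
    )

    def branch_label(node) -> str:
        return node.taxon.label if node.taxon else (node.label or f"n{id(node)}")

    branch_labels = [
        branch_label(n)
        for n in species_tree.preorder_node_iter()
        if n.parent_node is not None
    ]
    for attempt in range(max_resamples + 1):
        events = {lab: {"duplications": 0, "losses": 0} for lab in branch_labels}
        stem_dups = config.root_copies - 1
        events["__stem__"] = {"duplications": stem_dups, "losses": 0}
        counter: dict[str, int] = {}
        taxon_namespace = dendropy.TaxonNamespace()

        # extra root copies arise from duplications on the stem branch
        if stem_dups:
            top = dendropy.Node()
            frontier = [top]
            for _ in range(stem_dups):
                node = frontier.pop(0)
                a, b = dendropy.Node(), dendropy.Node()
                node.add_child(a)
                node.add_child(b)
                frontier.extend([a, b])
            roots_structure, roots = top, frontier
        else:
            roots_structure = dendropy.Node()
            roots = [roots_structure]

        def speciate(species_node, lineage):
            # the lineage splits into one stub per species child
            for child in species_node.child_nodes():
                stub = dendropy.Node()
                lineage.add_child(stub)
                label = branch_label(child)
                survivors, dups, losses = _bd_branch(
                    rng, [stub], child.edge.length or 0.0,
                    config.duplication_rate, config.loss_rate,
                )
                events[label]["duplications"] += dups
                events[label]["losses"] += losses
                if child.is_leaf():
                    for node in survivors:
                        counter[label] = counter.get(label, 0) + 1
                        node.taxon = taxon_namespace.new_taxon(
                            f"{label}_g{counter[label]}"
                        )
                else:
                    for node in survivors:
                        speciate(child, node)

        for root_lineage in roots:
            speciate(species_tree.seed_node, root_lineage)

        tree = dendropy.Tree(taxon_namespace=taxon_namespace)
        tree.seed_node = roots_structure
        _prune_dead(tree)
        leaves = [l for l in tree.leaf_node_iter() if l.taxon is not None]
        if leaves:
            truth = pd.DataFrame(
                [
                    {"branch": lab, **counts}
                    for lab, counts in sorted(events.items())
                ]
            )
            return FamilySimResult(
                gene_tree=tree,
                truth=truth,
                leaf_counts=dict(sorted(counter.items())),
                resamples=attempt,
            )
    raise RuntimeError(
        f"all lineages extinct in {max_resamples} consecutive replicates"
    )


def _prune_dead(tree: dendropy.Tree) -> None:
    """Remove extinct (taxonless leaf) branches and suppress unary nodes."""
    changed = True
    while changed:
        changed = False
        for node in list(tree.postorder_node_iter()):
            if node.is_leaf() and node.taxon is None and node.parent_node is not None:
                node.parent_node.remove_child(node)
                changed = True
    # suppress unary internal nodes
    for node in list(tree.postorder_node_iter()):
        children = node.child_nodes()
        if len(children) == 1:
            child = children[0]
            parent = node.parent_node
            node.remove_child(child)
            if parent is None:
                tree.seed_node = child
                child.parent_node = None
            else:
                parent.remove_child(node)
                parent.add_child(child)


# ---------------------------------------------------------------------------
# Codon-alignment simulation

@dataclass
class CodonSimResult:
    alignment: CodonAlignment
    site_classes: np.ndarray       # class index per site
    positive_sites: np.ndarray     # boolean: site drawn from an omega>1 class
    root_codons: np.ndarray


def simulate_codon_alignment(
    tree: dendropy.Tree,
    kappa: float,
    classes: SiteClasses,
    n_codons: int,
    seed: int,
    pi: Optional[np.ndarray] = None,
    foreground_branch: Optional[str] = None,
) -> CodonSimResult:
    """Evolve codon sites down a tree by exact GY94 transition probabilities.

    Site classes are drawn from ``classes.weights``; on the designated
    foreground branch the class's foreground omega applies (branch-site
    regimes).  The returned truth records each site's class and whether it
    was drawn from a positive-selection (omega > 1) class.
    """
    rng = np.random.default_rng(seed)
    pi = uniform_frequencies() if pi is None else np.asarray(pi, float)
    leaf_names = [
        (l.taxon.label if l.taxon else l.label) for l in tree.leaf_node_iter()
    ]
    ti = _TreeIndex(tree, leaf_names)
    fg_edge = ti.edge_index_for(foreground_branch) if foreground_branch else None

    k_classes = len(classes.weights)
    site_class = rng.choice(k_classes, size=n_codons, p=classes.weights)
    omegas_bg = classes.omegas
    omegas_fg = classes.omegas_fg if classes.omegas_fg is not None else omegas_bg
    # shared scale: background-mixture expected rate = 1
    rates = np.array(
        [-np.dot(pi, np.diag(gy94_rate_matrix(kappa, om, pi, scale=False)))
         for om in omegas_bg]
    )
    scale = float(np.dot(classes.weights, rates)) or 1.0
    distinct = np.unique(np.concatenate([omegas_bg, omegas_fg]))
    eigs = {
        float(om): EigenQ(gy94_rate_matrix(kappa, om, pi, scale=False) / scale, pi)
        for om in distinct
    }

    states = np.empty((ti.n_nodes, n_codons), dtype=int)
    states[ti.root] = rng.choice(len(pi), size=n_codons, p=pi / pi.sum())
    # walk preorder (reverse postorder)
    for i in range(ti.n_nodes - 1, -1, -1):
        for c in ti.children[i]:
            e = ti.edge_of_node[c]
            t = ti.init_lengths[e]
            use_fg = fg_edge is not None and e == fg_edge
            for k in range(k_classes):
                sites = np.flatnonzero(site_class == k)
                if sites.size == 0:
                    continue
                om = omegas_fg[k] if use_fg else omegas_bg[k]
                p = eigs[float(om)].p(t)
                cum = np.cumsum(p, axis=1)
                u = rng.random(sites.size)
                parent_states = states[i, sites]
                states[c, sites] = np.array(
                    [np.searchsorted(cum[ps], uu) for ps, uu in zip(parent_states, u)]
                ).clip(0, len(pi) - 1)
    mat = np.empty((len(leaf_names), n_codons), dtype=int)
    for node_i, row in ti.leaf_row.items():
        mat[row] = states[node_i]
    positive = np.array(
        [max(omegas_bg[k], omegas_fg[k]) > 1.0 for k in range(k_classes)]
    )[site_class]
    return CodonSimResult(
        alignment=CodonAlignment(taxa=leaf_names, codons=mat),
        site_classes=site_class,
        positive_sites=positive,
        root_codons=states[ti.root].copy(),
    )


def simulate_m0_alignment(
    tree: dendropy.Tree, kappa: float, omega: float, n_codons: int, seed: int,
    pi: Optional[np.ndarray] = None,
) -> CodonSimResult:
    classes = SiteClasses(weights=np.array([1.0]), omegas=np.array([omega]))
    return simulate_codon_alignment(tree, kappa, classes, n_codons, seed, pi=pi)


# ---------------------------------------------------------------------------
# Identity-controlled protein sets

def make_identity_controlled_proteins(
    n: int, target_identity: float, length: int, seed: int
) -> dict[str, str]:
    """Protein set whose pairwise identities approximate ``target_identity``.

    A star design around a random ancestor: each copy substitutes sites at
    rate ``(1 - target) / 2`` independently, so two copies disagree at a
    site with probability ~``1 - target``.  Low targets are infeasible for a
    20-letter alphabet and raise.
    """
    if not 0.0 <= target_identity <= 1.0:
        raise ValueError("target_identity must lie in [0, 1]")
    if target_identity < 0.2 and n > 1:
        raise ValueError(
            "pairwise identity below ~0.2 is not reachable by site substitution"
        )
    rng = np.random.default_rng(seed)
    ancestor = _random_protein(rng, length)
    if n == 1:
        return {"prot1": ancestor}
    rate = (1.0 - target_identity) / 2.0
    return {
        f"prot{i + 1}": _mutate_protein(rng, ancestor, rate) for i in range(n)
    }
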