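"""Rule-based curation of annotated repertoires and summary tables.

The rules are the ones applied to large lepidopteran gustatory-receptor
repertoires after iterative annotation:

* sequences sharing at least 90% protein identity are alternative alleles of
  one gene and only the longest is retained for downstream analyses;
* a sequence containing one or more internal stop codons is a pseudogene;
* a gene is complete when a start and a stop codon are present and the
  protein is longer than 350 amino acids; otherwise it is partial;
* the conserved C-terminal receptor motif ``TYhhhhhQF`` (transmembrane
  domain 7) is checked as a verification flag, not a rejection filter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .codon import START_CODON, STOP_CODONS, translate
from .records import GeneRecord

#: hydrophobic residues accepted at an 'h' position of the receptor motif:
#: the Kyte–Doolittle-positive set plus the aromatics W and Y
HYDROPHOBIC = frozenset("AVLIMFWCY")


# ---------------------------------------------------------------------------
# Pairwise identity and allele collapse

def _global_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    # free end gaps: length differences between alleles are not penalised
    a.end_insertion_score = 0.0
    a.end_deletion_score = 0.0
    return a


def pairwise_identity(prot_a: str, prot_b: str) -> float:
    """Fraction of identical positions among aligned (non-gap-pair) columns
    of the global alignment of the two proteins.  Symmetric."""
    if not prot_a or not prot_b:
        raise ValueError("cannot compute identity of an empty sequence")
    aln = _global_aligner().align(prot_a, prot_b)[0]
    matches = columns = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        for x, y in zip(prot_a[qs:qe], prot_b[ts:te]):
            columns += 1
            if x == y:
                matches += 1
    return matches / columns if columns else 0.0


def collapse_alleles(
    records: Sequence[GeneRecord], threshold: float = 0.90
) -> list[GeneRecord]:
    """Mark allelic sequences: single-linkage clusters at >= ``threshold``
    identity; in each cluster the longest protein keeps its category and the
    others become ``allele`` of it (ties on length broken by smaller id)."""
    recs = [r for r in records]
    with_prot = [r for r in recs if r.protein]
    # union-find over single-linkage edges
    parent = {r.gene_id: r.gene_id for r in with_prot}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(with_prot, 2):
        if pairwise_identity(a.protein, b.protein) >= threshold:
            ra, rb = find(a.gene_id), find(b.gene_id)
            if ra != rb:
                parent[ra] = rb
    clusters: dict[str, list[GeneRecord]] = {}
    for r in with_prot:
        clusters.setdefault(find(r.gene_id), []).append(r)
    out = []
    for r in recs:
        out.append(r)
    by_id = {r.gene_id: r for r in out}
    for members in clusters.values():
        if len(members) < 2:
            continue
        keeper = min(members, key=lambda r: (-len(r.protein), r.gene_id))
        for m in members:
            if m.gene_id != keeper.gene_id:
                rec = by_id[m.gene_id]
                rec.category = "allele"
                rec.allele_of = keeper.gene_id
    return out


# ---------------------------------------------------------------------------
# Gene classification

def classify_gene(record: GeneRecord) -> str:
    """``pseudogene`` | ``complete`` | ``partial`` from the CDS.

    An internal stop codon anywhere makes a pseudogene.  Completeness needs
    a start codon, a terminal stop codon, and a protein strictly longer than
    350 amino acids.
    """
    cds = record.cds.upper()
    if not cds and record.protein:
        # protein-only record: internal stops encoded as '*'
        prot = record.protein
        if "*" in prot.rstrip("*"):
            return "pseudogene"
        return "partial"
    if not cds:
        raise ValueError(f"{record.gene_id}: no sequence to classify")
    full = translate(cds)
    body = full[:-1] if full.endswith("*") else full
    if "*" in body:
        return "pseudogene"
    has_start = cds.startswith(START_CODON)
    has_stop = full.endswith("*") or cds[-3:] in STOP_CODONS
    if has_start and has_stop and len(body) > 350:
        return "complete"
    return "partial"


def apply_classification(records: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Classify every non-allele record in place (alleles keep their mark)."""
    for r in records:
        if r.category != "allele":
            r.category = classify_gene(r)
    return list(records)


def motif_check(
    protein: str,
    motif: str = "TYhhhhhQF",
    window: int = 100,
    hydrophobic: frozenset[str] = HYDROPHOBIC,
) -> tuple[bool, Optional[int]]:
    """Look for the degenerate receptor motif within the C-terminal window.

    Lowercase ``h`` in ``motif`` matches any hydrophobic residue; any other
    letter matches itself.  Returns ``(found, absolute_position)``.
    """
    if not protein:
        return False, None
    start_at = max(0, len(protein) - window)
    m = len(motif)
    for pos in range(start_at, len(protein) - m + 1):
        ok = True
        for off, want in enumerate(motif):
            have = protein[pos + off]
            if want == "h":
                if have not in hydrophobic:
                    ok = False
                    break
            elif have != want:
                ok = False
                break
        if ok:
            return True, pos
    return False, None


# ---------------------------------------------------------------------------
# Summary tables

@dataclass
class RepertoireSummary:
    """Category counts and derived quantities of one species' repertoire.

    ``final_count`` is the repertoire used for evolutionary analyses: total
    minus pseudogenes and alleles.  ``percent`` holds each category as a
    whole-number percentage of the total.
    """

    complete: int
    partial: int
    pseudogene: int
    allele: int
    total: int = field(init=False)
    final_count: int = field(init=False)
    percent: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.complete + self.partial + self.pseudogene + self.allele
        self.final_count = self.total - self.pseudogene - self.allele
        if self.total:
            self.percent = {
                cat: round(getattr(self, cat) / self.total * 100)
                for cat in ("complete", "partial", "pseudogene", "allele")
            }
        else:
            self.percent = {c: 0 for c in ("complete", "partial", "pseudogene", "allele")}


def summarize_repertoire(records: Sequence[GeneRecord]) -> RepertoireSummary:
    counts = {c: 0 for c in ("complete", "partial", "pseudogene", "allele")}
    for r in records:
        counts[r.category] += 1
    return RepertoireSummary(**counts)


@dataclass
class CladeTable:
    """Per-clade counts of complete+partial genes and their share of the
    repertoire (clade_total / (complete+partial) * 100, one decimal)."""

    clade_counts: dict[str, int]
    denominator: int
    clade_total: int = field(init=False)
    percentage: float = field(init=False)

    def __post_init__(self) -> None:
        self.clade_total = sum(self.clade_counts.values())
        self.percentage = (
            round(self.clade_total / self.denominator * 100, 1) if self.denominator else 0.0
        )


def clade_proportion(
    records: Sequence[GeneRecord],
    clade_assignments: Mapping[str, str] | None = None,
) -> CladeTable:
    """Tabulate clade membership among complete+partial genes.

    ``clade_assignments`` maps gene_id -> clade and overrides any clade
    already set on the record.  Assigning a clade to a pseudogene or allele
    is an error: those are excluded from phylogenetic placement.
    """
    assignments = dict(clade_assignments or {})
    counts: dict[str, int] = {}
    denominator = 0
    for r in records:
        clade = assignments.get(r.gene_id, r.clade)
        if r.category in ("pseudogene", "allele"):
            if r.gene_id in assignments:
                raise ValueError(
                    f"{r.gene_id} is a {r.category}; clades apply to complete/partial genes"
                )
            continue
        denominator += 1
        if clade:
            counts[clade] = counts.get(clade, 0) + 1
    return CladeTable(clade_counts=dict(sorted(counts.items())), denominator=denominator)


def genome_size_from_cytometry(
    sample_2c_fluorescence: float,
    standard_2c_fluorescence: float,
    standard_1c_mbp: float = 328.0,
) -> float:
    """1C genome size in Mbp from flow-cytometry peak fluorescences.

    The sample's 2C peak fluorescence relative to a co-stained standard of
    known 1C content (the classic *Drosophila virilis* 328-Mbp standard)
    scales the standard's size.
    """
    if sample_2c_fluorescence <= 0 or standard_2c_fluorescence <= 0:
        raise ValueError("fluorescence values must be positive")
    return sample_2c_fluorescence / standard_2c_fluorescence * standard_1c_mbp
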