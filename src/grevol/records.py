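"""Curated gene-family members and transposable-element annotations."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .intervals import GenomicInterval

GENE_CATEGORIES = ("complete", "partial", "pseudogene", "allele")

#: TE orders grouped by class, following the standard Wicker-style hierarchy:
#: class I retrotransposons move via an RNA intermediate, class II DNA
#: transposons excise or copy as DNA.
TE_CLASS_ORDERS = {
    "I": ("DIRS", "LARD", "LINE", "LTR", "PLE", "SINE", "TRIM"),
    "II": ("Helitron", "MITE", "Maverick", "TIR", "noCat"),
    "noCat": ("noCat",),
    "host_gene": ("noCat",),
}


@dataclass
class GeneRecord:
    """One annotated member of a gene family.

    ``category`` follows the curation rules applied after iterative
    annotation: ``complete`` (start + stop codon, >350 aa), ``partial``,
    ``pseudogene`` (internal stop codon), or ``allele`` (>=90% identity with
    a longer annotated sequence, which ``allele_of`` names).
    """

    gene_id: str
    species: str = ""
    family: str = "GR"
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: str = ""
    protein: str = ""
    category: str = "partial"
    allele_of: Optional[str] = None
    clade: Optional[str] = None
    at_scaffold_boundary: bool = False
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in GENE_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "allele" and self.allele_of is None:
            raise ValueError(f"{self.gene_id}: category=allele requires allele_of")
        if self.exons:
            scaf = {e.scaffold for e in self.exons}
            strands = {e.strand for e in self.exons}
            if len(scaf) > 1 or len(strands) > 1:
                raise ValueError(f"{self.gene_id}: exons span scaffolds or strands")
            ordered = sorted(self.exons, key=lambda e: e.start)
            for a, b in zip(ordered, ordered[1:]):
                if b.start < a.end:
                    raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def scaffold(self) -> Optional[str]:
        return self.exons[0].scaffold if self.exons else None

    @property
    def strand(self) -> str:
        return self.exons[0].strand if self.exons else "."

    def span(self) -> Optional[GenomicInterval]:
        """Genomic footprint from first to last exon."""
        if not self.exons:
            return None
        return GenomicInterval(
            self.scaffold,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )


@dataclass
class TEAnnotation:
    """A transposable-element copy: location, class, order, consensus family."""

    interval: GenomicInterval
    te_class: str
    order: str
    family_id: str

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASS_ORDERS:
            raise ValueError(f"unknown TE class {self.te_class!r}")
        if self.order not in TE_CLASS_ORDERS[self.te_class]:
            raise ValueError(
                f"order {self.order!r} inconsistent with class {self.te_class!r}"
            )
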