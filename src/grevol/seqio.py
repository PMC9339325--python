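"""Readers and writers for FASTA, GFF3, BED, newick, and TSV helpers.

GFF3 is 1-based closed; BED is 0-based half-open.  Both are converted to the
package's internal 0-based half-open convention on read, and converted back
on write, so coordinate round-trips are identities.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval
from .records import GeneRecord, TEAnnotation


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` map.

    Raises on duplicate identifiers and on an empty file.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
    del width  # SeqIO wraps at 60; kept for signature stability


# ---------------------------------------------------------------------------
# GFF3 / BED

def _parse_strand(token: str, where: str) -> str:
    if token not in ("+", "-", "."):
        raise ValueError(f"unknown strand {token!r} in {where}")
    return token


def read_gff3(
    path: str | Path, feature_filter: Sequence[str] | None = None
) -> list[tuple[GenomicInterval, dict[str, str]]]:
    """Read GFF3 features as ``(interval, attributes)`` pairs.

    ``feature_filter`` restricts to the given feature types (column 3).
    Coordinates are converted from 1-based closed to 0-based half-open.
    """
    wanted = set(feature_filter) if feature_filter else None
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise ValueError(f"{path}:{ln}: malformed GFF3 line")
        scaffold, source, ftype, start, end, score, strand, frame = cols[:8]
        if wanted is not None and ftype not in wanted:
            continue
        start_i, end_i = int(start), int(end)
        if end_i < start_i:
            raise ValueError(f"{path}:{ln}: end < start")
        attrs: dict[str, str] = {"feature_type": ftype, "source": source}
        if len(cols) > 8 and cols[8] != ".":
            for item in cols[8].rstrip(";").split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = v.strip()
        iv = GenomicInterval(scaffold, start_i - 1, end_i, _parse_strand(strand, f"{path}:{ln}"))
        out.append((iv, attrs))
    return out


def write_gff3(
    features: Iterable[tuple[GenomicInterval, Mapping[str, str]]],
    path: str | Path,
    source: str = "grevol",
) -> None:
    lines = ["##gff-version 3"]
    for iv, attrs in features:
        ftype = attrs.get("feature_type", "region")
        astr = ";".join(
            f"{k}={v}" for k, v in attrs.items() if k not in ("feature_type", "source")
        ) or "."
        lines.append(
            "\t".join(
                [iv.scaffold, source, ftype, str(iv.start + 1), str(iv.end), ".", iv.strand, ".", astr]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, dict[str, str]]]:
    """Read a BED file (already 0-based half-open; no conversion needed)."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ValueError(f"{path}:{ln}: malformed BED line")
        start_i, end_i = int(cols[1]), int(cols[2])
        if end_i < start_i:
            raise ValueError(f"{path}:{ln}: end < start")
        strand = _parse_strand(cols[5], f"{path}:{ln}") if len(cols) >= 6 else "."
        attrs = {"name": cols[3]} if len(cols) >= 4 else {}
        out.append((GenomicInterval(cols[0], start_i, end_i, strand), attrs))
    return out


def read_scaffold_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV ``scaffold<TAB>length`` -> dict."""
    out: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        name, length = line.split("\t")[:2]
        out[name] = int(length)
    return out


# ---------------------------------------------------------------------------
# Gene records as GFF3 + FASTA

def write_gene_records(records: Sequence[GeneRecord], gff_path: str | Path, fasta_path: str | Path) -> None:
    feats = []
    for rec in records:
        attrs = {
            "feature_type": "gene",
            "ID": rec.gene_id,
            "category": rec.category,
            "family": rec.family,
        }
        if rec.clade:
            attrs["clade"] = rec.clade
        if rec.allele_of:
            attrs["allele_of"] = rec.allele_of
        span = rec.span()
        if span is not None:
            feats.append((span, attrs))
            for i, ex in enumerate(sorted(rec.exons, key=lambda e: e.start), start=1):
                feats.append((ex, {"feature_type": "exon", "ID": f"{rec.gene_id}.exon{i}", "Parent": rec.gene_id}))
    write_gff3(feats, gff_path)
    write_fasta({r.gene_id: r.protein for r in records if r.protein}, fasta_path)


def read_te_gff3(path: str | Path) -> list[TEAnnotation]:
    """Read TE copies from GFF3; class/order/family from attributes."""
    out = []
    for iv, attrs in read_gff3(path):
        out.append(
            TEAnnotation(
                interval=iv,
                te_class=attrs.get("te_class", "noCat"),
                order=attrs.get("te_order", "noCat"),
                family_id=attrs.get("family", attrs.get("ID", "unknown")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Trees

def read_tree(path_or_string: str | Path, rooted: bool = True) -> dendropy.Tree:
    """Read a newick tree from a path or a literal newick string."""
    text = str(path_or_string)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        rooting="force-rooted" if rooted else "default-unrooted",
        preserve_underscores=True,
    )
    return tree


def species_from_leaf(leaf_label: str, prefix_map: Mapping[str, str]) -> str:
    """Map a gene-tree leaf label to its species via a prefix map.

    ``prefix_map`` maps label prefixes (e.g. ``"Slit_"``) to species names.
    Longest matching prefix wins; an unmapped leaf is an error.
    """
    best = None
    for prefix, species in prefix_map.items():
        if leaf_label.startswith(prefix) and (best is None or len(prefix) > len(best[0])):
            best = (prefix, species)
    if best is None:
        raise KeyError(f"gene-tree leaf {leaf_label!r} matches no prefix in the map")
    return best[1]


def read_prefix_map(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        prefix, species = line.split("\t")[:2]
        out[prefix] = species
    return out
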