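"""Scaffold-anchored genomic intervals and merged region sets.

All coordinates are 0-based, half-open ``[start, end)``.  Format readers
(:mod:`grevol.seqio`) convert GFF3's 1-based closed convention at the
boundary, so every downstream computation — flanking, merging, overlap
counting — uses one unambiguous arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named scaffold."""

    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.scaffold:
            raise ValueError("scaffold name must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def flank(self, pad: int, scaffold_length: int | None = None) -> "GenomicInterval":
        """Expand by ``pad`` bp on both sides, clipped to ``[0, scaffold_length)``."""
        start = max(0, self.start - pad)
        end = self.end + pad
        if scaffold_length is not None:
            if self.end > scaffold_length:
                raise ValueError(
                    f"interval end {self.end} beyond scaffold length {scaffold_length}"
                )
            end = min(end, scaffold_length)
        return replace(self, start=start, end=end)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share >= 1 bp on the same scaffold.

    Strand is ignored: proximity of features like transposable elements to
    gene loci is strand-agnostic.
    """
    return a.scaffold == b.scaffold and a.start < b.end and b.start < a.end


def merge_intervals(intervals: Iterable[GenomicInterval], label: str = "reference") -> "RegionSet":
    """Merge into the minimal set of maximal non-overlapping intervals.

    Touching intervals (``end == start``) are treated as adjacent and merged,
    so abutting flanked gene regions collapse into a single cluster region.
    Strand information is dropped (merged regions are unstranded).
    """
    ordered = sorted(intervals, key=lambda iv: (iv.scaffold, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].scaffold == iv.scaffold and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.scaffold, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.scaffold, iv.start, iv.end))
    return RegionSet(regions=merged, label=label)


@dataclass
class RegionSet:
    """An ordered, merged, non-overlapping collection of intervals.

    ``label`` distinguishes the three roles region sets play in locus-overlap
    enrichment: the ``query`` (family-of-interest regions), the ``universe``
    (all genic regions), and a plain ``reference`` set.
    """

    regions: list[GenomicInterval] = field(default_factory=list)
    label: str = "reference"

    def __post_init__(self) -> None:
        for prev, cur in zip(self.regions, self.regions[1:]):
            if (prev.scaffold, prev.start) > (cur.scaffold, cur.start):
                raise ValueError("regions must be sorted by (scaffold, start)")
            if prev.scaffold == cur.scaffold and cur.start < prev.end:
                raise ValueError("regions must be non-overlapping; merge first")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.regions)

    def any_overlap(self, iv: GenomicInterval) -> bool:
        """True iff ``iv`` overlaps at least one region (binary search)."""
        import bisect

        index = getattr(self, "_index", None)
        if index is None:
            index = {}
            for r in self.regions:
                index.setdefault(r.scaffold, ([], []))
                index[r.scaffold][0].append(r.start)
                index[r.scaffold][1].append(r.end)
            object.__setattr__(self, "_index", index)
        if iv.scaffold not in index:
            return False
        starts, ends = index[iv.scaffold]
        # rightmost region starting before iv.end overlaps iff it ends after
        # iv.start (regions are merged, hence sorted and disjoint)
        j = bisect.bisect_left(starts, iv.end) - 1
        return j >= 0 and ends[j] > iv.start


def flank_and_merge(
    genes: Sequence[GenomicInterval],
    flank: int,
    scaffold_lengths: Mapping[str, int] | None = None,
    label: str = "reference",
) -> RegionSet:
    """Expand every gene by ``flank`` bp both sides, clip to scaffold, merge."""
    padded = []
    for g in genes:
        length = scaffold_lengths.get(g.scaffold) if scaffold_lengths else None
        if scaffold_lengths is not None and length is None:
            raise KeyError(f"no length recorded for scaffold {g.scaffold}")
        padded.append(g.flank(flank, length))
    return merge_intervals(padded, label=label)
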