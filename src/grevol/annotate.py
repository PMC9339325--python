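"""Iterative homology-based annotation of gene-family loci.

The discovery loop mirrors manual curation practice for large chemosensory
families: known family proteins are searched against the genome in all six
reading frames, hits are chained into exon/intron gene models, and every
newly found protein joins the query set for another round, until a round
adds no new locus.

The translated search is an exhaustive local alignment (Smith–Waterman via
Biopython's :class:`PairwiseAligner`) of each query against each frame
translation, not a heuristic seeded search: desk-scale genomes are small
enough that exactness is affordable, and it makes every score checkable
against a plain dynamic-programming oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .codon import reverse_complement, six_frame_translate, translate
from .intervals import GenomicInterval, overlaps
from .records import GeneRecord

_MASK_CHAR = "X"
#: genome-side gap (in aa) below which an alignment gap is an ordinary indel
#: and above which the alignment is split into separate exon-candidate HSPs
_INTRON_SPLIT_AA = 15


@dataclass(frozen=True)
class HSP:
    """A high-scoring local alignment of a query protein to one frame."""

    query_id: str
    scaffold: str
    frame: int  # +1..+3 forward, -1..-3 reverse strand
    query_range: tuple[int, int]  # aa, half-open, on the query
    genome_range: GenomicInterval  # bp, forward-strand coordinates
    score: float
    identity: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("only non-negative scores are reported")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


@dataclass
class SearchParams:
    """Knobs of the translated search and model-building stage.

    ``min_score`` (raw substitution-matrix units) plays the role a BLAST
    e-value cutoff plays in a heuristic search.  ``max_intron_bp`` bounds
    the genomic gap bridged when chaining exon hits.  ``allele_identity``
    and ``min_complete_aa`` are consumed downstream by curation.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_score: float = 60.0
    min_identity: float = 0.0
    max_intron_bp: int = 50_000
    #: chaining cost per kb of genomic gap; breaks score ties in favour of
    #: compact models so adjacent tandem paralogs are not chained together
    intron_penalty_per_kb: float = 10.0
    #: tolerated aa overlap between consecutive HSPs' query ranges
    #: (alignment-trimming slack); overlapping columns are score-discounted
    query_overlap_aa: int = 60
    allele_identity: float = 0.90
    min_complete_aa: int = 350
    max_hits_per_frame: int = 50

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity <= 1.0 and 0.0 <= self.allele_identity <= 1.0):
            raise ValueError("identity thresholds must lie in [0, 1]")
        if self.max_intron_bp <= 0 or self.min_complete_aa <= 0:
            raise ValueError("max_intron_bp and min_complete_aa must be positive")

    def substitution_matrix(self):
        m = substitution_matrices.load(self.matrix_name)
        # make the masking character strongly penalised so that already
        # claimed genome stretches cannot seed or bridge new hits
        if _MASK_CHAR in m.alphabet:
            for a in m.alphabet:
                m[a, _MASK_CHAR] = -8.0
                m[_MASK_CHAR, a] = -8.0
        return m


def _aligner(params: SearchParams) -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = params.substitution_matrix()
    a.open_gap_score = -params.gap_open
    a.extend_gap_score = -params.gap_extend
    return a


def _segment_stats(
    blocks: list[tuple[tuple[int, int], tuple[int, int]]],
    query: str,
    target: str,
    matrix,
    params: SearchParams,
) -> tuple[float, float]:
    """Score and identity of a run of aligned blocks with small internal gaps."""
    score = 0.0
    matches = 0
    columns = 0
    prev = None
    for (qs, qe), (ts, te) in blocks:
        if prev is not None:
            gap = max(qs - prev[0], ts - prev[1])
            if gap > 0:
                score -= params.gap_open + params.gap_extend * (gap - 1)
        for qa, ta in zip(query[qs:qe], target[ts:te]):
            score += matrix[qa, ta]
            columns += 1
            if qa == ta:
                matches += 1
        prev = (qe, te)
    identity = matches / columns if columns else 0.0
    return score, identity


def _frame_to_genome(frame: int, aa_start: int, aa_end: int, scaffold_len: int) -> tuple[int, int]:
    """Map an aa interval on a frame translation to forward-strand bp."""
    k = abs(frame)
    nt_start = (k - 1) + 3 * aa_start
    nt_end = (k - 1) + 3 * aa_end
    if frame > 0:
        return nt_start, nt_end
    return scaffold_len - nt_end, scaffold_len - nt_start


def _split_alignment(aln) -> list[list[tuple[tuple[int, int], tuple[int, int]]]]:
    """Split one local alignment into segments at intron-scale target gaps."""
    qblocks, tblocks = aln.aligned
    blocks = [((int(q[0]), int(q[1])), (int(t[0]), int(t[1]))) for q, t in zip(qblocks, tblocks)]
    segments: list[list] = [[]]
    prev_t_end = None
    for blk in blocks:
        t_start = blk[1][0]
        if prev_t_end is not None and t_start - prev_t_end > _INTRON_SPLIT_AA:
            segments.append([])
        segments[-1].append(blk)
        prev_t_end = blk[1][1]
    return segments


def translated_search(
    query_proteins: Mapping[str, str],
    genome: Mapping[str, str],
    params: SearchParams | None = None,
) -> list[HSP]:
    """All local alignments of every query against all six genome frames.

    Hits are reported down to ``params.min_score``; within one
    (query, frame) pair, hits are found best-first, the claimed stretch of
    the frame translation masked, and the search repeated, so multiple
    paralogous loci on one scaffold are each reported.
    """
    if not query_proteins or not genome:
        raise ValueError("queries and genome must be nonempty")
    params = params or SearchParams()
    aligner = _aligner(params)
    matrix = aligner.substitution_matrix
    hsps: list[HSP] = []
    for scaffold, seq in genome.items():
        frames = six_frame_translate(seq)
        for frame, frame_prot in frames.items():
            if not frame_prot:
                continue
            for query_id, qprot in query_proteins.items():
                target = frame_prot
                for _ in range(params.max_hits_per_frame):
                    if not target.strip(_MASK_CHAR):
                        break
                    alignments = aligner.align(qprot, target)
                    if alignments.score < params.min_score:
                        break
                    aln = alignments[0]
                    claimed: list[tuple[int, int]] = []
                    for seg in _split_alignment(aln):
                        score, identity = _segment_stats(seg, qprot, target, matrix, params)
                        q_lo, q_hi = seg[0][0][0], seg[-1][0][1]
                        s_lo, s_hi = seg[0][1][0], seg[-1][1][1]
                        claimed.append((s_lo, s_hi))
                        if score < params.min_score or identity < params.min_identity:
                            continue
                        g_lo, g_hi = _frame_to_genome(frame, s_lo, s_hi, len(seq))
                        hsps.append(
                            HSP(
                                query_id=query_id,
                                scaffold=scaffold,
                                frame=frame,
                                query_range=(q_lo, q_hi),
                                genome_range=GenomicInterval(
                                    scaffold, g_lo, g_hi, "+" if frame > 0 else "-"
                                ),
                                score=score,
                                identity=identity,
                            )
                        )
                    # mask only the aligned stretches: the gaps between
                    # segments may hold other loci's exons in this frame
                    chars = list(target)
                    for s_lo, s_hi in claimed:
                        chars[s_lo:s_hi] = _MASK_CHAR * (s_hi - s_lo)
                    target = "".join(chars)
    hsps.sort(key=lambda h: (h.scaffold, h.genome_range.start, h.query_id, -h.score))
    return hsps


# ---------------------------------------------------------------------------
# Chaining

@dataclass
class GeneModel:
    """A chained gene model: ordered exons from one query on one strand."""

    query_id: str
    scaffold: str
    strand: str
    exons: list[GenomicInterval]
    score: float
    hsps: list[HSP] = field(default_factory=list)

    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.scaffold,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )


def _chain_gap(a: HSP, b: HSP) -> int:
    """Genomic gap (bp) between consecutive HSPs in coding order."""
    if a.strand == "+":
        return b.genome_range.start - a.genome_range.end
    return a.genome_range.start - b.genome_range.end


def _chainable(a: HSP, b: HSP, params: SearchParams) -> bool:
    """May chain a -> b?  Collinear in query and genome, intron-bounded."""
    if a.query_range[1] - params.query_overlap_aa > b.query_range[0]:
        return False
    return 0 <= _chain_gap(a, b) <= params.max_intron_bp


def _gap_holds_other_hit(a: HSP, b: HSP, hsps: Sequence[HSP]) -> bool:
    """True if another HSP lies wholly inside the implied intron a -> b.

    A genuine intron of one gene does not contain a separate high-scoring
    hit of the same query; in tandem arrays such a hit marks an intervening
    paralog, so chaining across it would fuse two loci.
    """
    if a.strand == "+":
        lo, hi = a.genome_range.end, b.genome_range.start
    else:
        lo, hi = b.genome_range.end, a.genome_range.start
    for h in hsps:
        if h is a or h is b:
            continue
        if lo <= h.genome_range.start and h.genome_range.end <= hi:
            return True
    return False


def chain_hsps(hsps: Sequence[HSP], params: SearchParams | None = None) -> list[GeneModel]:
    """Chain collinear HSPs of one query on one scaffold and strand.

    Best-scoring chains are extracted greedily: a maximal-score chain is
    found by dynamic programming, its members removed, and the process
    repeated, so well-separated paralogous loci yield separate models.
    """
    params = params or SearchParams()
    if not hsps:
        return []
    key = {(h.query_id, h.scaffold, h.strand) for h in hsps}
    if len(key) != 1:
        raise ValueError("chain_hsps expects HSPs of one query on one scaffold/strand")
    query_id, scaffold, strand = next(iter(key))
    remaining = sorted(hsps, key=lambda h: h.query_range)
    models: list[GeneModel] = []
    while remaining:
        n = len(remaining)
        best_score = [h.score for h in remaining]
        back = [-1] * n
        for i in range(n):
            for j in range(i):
                if _chainable(remaining[j], remaining[i], params) and not _gap_holds_other_hit(
                    remaining[j], remaining[i], remaining
                ):
                    gap_cost = (
                        _chain_gap(remaining[j], remaining[i]) / 1000.0
                        * params.intron_penalty_per_kb
                    )
                    overlap = max(
                        0, remaining[j].query_range[1] - remaining[i].query_range[0]
                    )
                    cand = best_score[j] + remaining[i].score - gap_cost - 4.0 * overlap
                    if cand > best_score[i]:
                        best_score[i] = cand
                        back[i] = j
        top = int(np.argmax(best_score))
        chain = []
        at = top
        while at != -1:
            chain.append(remaining[at])
            at = back[at]
        chain.reverse()
        used = set(map(id, chain))
        remaining = [h for h in remaining if id(h) not in used]
        exons = sorted((h.genome_range for h in chain), key=lambda iv: iv.start)
        models.append(
            GeneModel(
                query_id=query_id,
                scaffold=scaffold,
                strand=strand,
                exons=list(exons),
                score=float(best_score[top]),
                hsps=chain,
            )
        )
    models.sort(key=lambda m: -m.score)
    return models


def complete_model(
    model: GeneModel, genome: Mapping[str, str], max_scan_codons: int = 15
) -> GeneModel:
    """Extend model termini to a nearby in-frame start/stop codon.

    A translated local alignment can neither align the stop codon (the query
    protein carries no ``*``) nor reliably keep a mismatched N-terminus, so
    raw chained models systematically miss their start/stop.  This mirrors a
    curator completing the model: scan at most ``max_scan_codons`` codons
    downstream for a stop (extending through any intervening codons) and
    upstream for the farthest ATG not separated by a stop.
    """
    from .codon import START_CODON, STOP_CODONS

    seq = genome[model.scaffold]
    exons = sorted(model.exons, key=lambda e: e.start)
    length = len(seq)

    def codon_at(pos: int, minus: bool) -> str:
        if pos < 0 or pos + 3 > length:
            return ""
        c = seq[pos : pos + 3].upper()
        return reverse_complement(c) if minus else c

    minus = model.strand == "-"
    # coding-3' extension to a stop codon
    if not minus:
        tail = exons[-1].end
        step = +3
        pos0 = tail
    else:
        tail = exons[0].start
        step = -3
        pos0 = tail - 3
    for k in range(max_scan_codons):
        codon = codon_at(pos0 + step * k, minus)
        if not codon:
            break
        if codon in STOP_CODONS:
            if not minus:
                last = exons[-1]
                exons[-1] = GenomicInterval(
                    last.scaffold, last.start, tail + 3 * (k + 1), last.strand
                )
            else:
                first = exons[0]
                exons[0] = GenomicInterval(
                    first.scaffold, tail - 3 * (k + 1), first.end, first.strand
                )
            break
    # coding-5' extension to the farthest ATG with no intervening stop
    if not minus:
        head = exons[0].start
        first_codon = codon_at(head, False)
        if first_codon != START_CODON:
            best = None
            for k in range(1, max_scan_codons + 1):
                codon = codon_at(head - 3 * k, False)
                if not codon or codon in STOP_CODONS:
                    break
                if codon == START_CODON:
                    best = k
            if best:
                f = exons[0]
                exons[0] = GenomicInterval(f.scaffold, head - 3 * best, f.end, f.strand)
    else:
        head = exons[-1].end
        first_codon = codon_at(head - 3, True)
        if first_codon != START_CODON:
            best = None
            for k in range(1, max_scan_codons + 1):
                codon = codon_at(head + 3 * k - 3, True)
                if not codon or codon in STOP_CODONS:
                    break
                if codon == START_CODON:
                    best = k
            if best:
                f = exons[-1]
                exons[-1] = GenomicInterval(f.scaffold, f.start, head + 3 * best, f.strand)
    return GeneModel(
        query_id=model.query_id,
        scaffold=model.scaffold,
        strand=model.strand,
        exons=exons,
        score=model.score,
        hsps=model.hsps,
    )


def extract_cds(model: GeneModel, genome: Mapping[str, str]) -> str:
    """Concatenated exon nucleotides, read 5'->3' on the coding strand."""
    seq = genome[model.scaffold]
    parts = [seq[e.start : e.end] for e in sorted(model.exons, key=lambda e: e.start)]
    cds = "".join(parts)
    return cds if model.strand == "+" else reverse_complement(cds)


# ---------------------------------------------------------------------------
# Iterative discovery

def _reciprocal_overlap_frac(a: GenomicInterval, b: GenomicInterval) -> float:
    if not overlaps(a, b):
        return 0.0
    shared = min(a.end, b.end) - max(a.start, b.start)
    return shared / min(len(a), len(b))


@dataclass
class AnnotationRound:
    round_number: int
    queries: int
    new_loci: int


@dataclass
class AnnotationResult:
    records: list[GeneRecord]
    rounds: list[AnnotationRound]


def _models_to_candidates(
    all_hsps: Sequence[HSP], params: SearchParams
) -> list[GeneModel]:
    groups: dict[tuple, list[HSP]] = {}
    for h in all_hsps:
        groups.setdefault((h.query_id, h.scaffold, h.strand), []).append(h)
    models: list[GeneModel] = []
    for group in groups.values():
        models.extend(chain_hsps(group, params))
    return [m for m in models if m.score >= params.min_score]


def _dedupe_locus(models: list[GeneModel], min_reciprocal: float = 0.5) -> list[GeneModel]:
    """One gene per locus: of two models with reciprocal overlap above
    ``min_reciprocal`` of the shorter span, keep the higher-scoring one."""
    kept: list[GeneModel] = []
    for m in sorted(models, key=lambda x: (-x.score, x.scaffold, x.span().start)):
        if all(
            _reciprocal_overlap_frac(m.span(), k.span()) <= min_reciprocal
            for k in kept
            if k.scaffold == m.scaffold
        ):
            kept.append(m)
    return kept


def iterate_annotation(
    seed_queries: Mapping[str, str],
    genome: Mapping[str, str],
    params: SearchParams | None = None,
    family: str = "GR",
    max_rounds: int = 50,
) -> AnnotationResult:
    """Search, model, accept, and repeat with the newly found proteins.

    Terminates at the fixed point where one more round with the current
    repertoire as queries adds no locus.  Accepted loci never overlap
    previously accepted loci, so the repertoire grows monotonically and the
    loop is bounded by the number of loci in the genome.
    """
    if not seed_queries:
        raise ValueError("seed query set must be nonempty")
    params = params or SearchParams()
    accepted: list[GeneRecord] = []
    accepted_spans: list[GenomicInterval] = []
    queries = dict(sorted(seed_queries.items()))
    rounds: list[AnnotationRound] = []
    for round_number in range(1, max_rounds + 1):
        hsps = translated_search(queries, genome, params)
        candidates = _models_to_candidates(hsps, params)
        candidates = [
            m
            for m in candidates
            if not any(overlaps(m.span(), s) for s in accepted_spans)
        ]
        new_models = _dedupe_locus(candidates)
        new_records = []
        for m in sorted(new_models, key=lambda x: (x.scaffold, x.span().start)):
            m = complete_model(m, genome)
            span = m.span()
            cds = extract_cds(m, genome)
            prot_full = translate(cds) if len(cds) >= 3 else ""
            protein = prot_full.split("*", 1)[0]
            gene_id = f"{family}_{m.scaffold}_{span.start}"
            boundary = span.start == 0 or span.end == len(genome[m.scaffold])
            new_records.append(
                GeneRecord(
                    gene_id=gene_id,
                    family=family,
                    exons=m.exons,
                    cds=cds,
                    protein=protein,
                    category="partial",
                    at_scaffold_boundary=boundary,
                    score=m.score,
                )
            )
        rounds.append(AnnotationRound(round_number, len(queries), len(new_records)))
        if not new_records:
            break
        accepted.extend(new_records)
        accepted_spans.extend(r.span() for r in new_records)
        queries = {r.gene_id: r.protein for r in new_records if r.protein}
        if not queries:
            break
    accepted.sort(key=lambda r: (r.scaffold or "", r.span().start if r.exons else 0))
    return AnnotationResult(records=accepted, rounds=rounds)
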