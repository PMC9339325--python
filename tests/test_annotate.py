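"""Translated search, HSP chaining, and the iterate-until-fixed-point loop."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from grevol.annotate import (
    HSP,
    SearchParams,
    chain_hsps,
    iterate_annotation,
    translated_search,
)
from grevol.codon import (
    CODON_TO_AA,
    reverse_complement,
    six_frame_translate,
    translate,
)
from grevol.intervals import GenomicInterval, overlaps
from grevol.simulate import _backtranslate, _mutate_protein, _random_dna, _random_protein

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def smith_waterman_score(a: str, b: str, gap_open=11.0, gap_extend=1.0) -> float:
    """Quadratic affine-gap local-alignment DP oracle."""
    n, m = len(a), len(b)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in a
    F = np.full((n + 1, m + 1), neg)  # gap in b
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            s = BLOSUM62[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def plant_single_exon_gene(genome: list, pos: int, protein: str) -> str:
    """Write ATG + CDS + stop at pos; return the full planted protein."""
    cds = "ATG" + _backtranslate(np.random.default_rng(pos), protein) + "TAA"
    genome[pos : pos + len(cds)] = list(cds)
    return "M" + protein


class TestSixFrameTranslate:
    def test_forward_frame(self):
        assert six_frame_translate("ATGAAATAG")[1] == "MK*"

    def test_reverse_frame_of_cat(self):
        assert six_frame_translate("CAT")[-1] == "M"

    def test_random_sequence_matches_codon_lookup(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        frames = six_frame_translate(seq)
        expected = "".join(CODON_TO_AA[seq[i : i + 3]] for i in range(0, 300, 3))
        assert frames[1] == expected
        rc = reverse_complement(seq)
        assert frames[-2] == "".join(CODON_TO_AA[rc[i : i + 3]] for i in range(1, 298, 3))

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            six_frame_translate("")

    def test_n_codon_translates_to_x(self):
        assert translate("ATNAAA") == "XK"


class TestTranslatedSearch:
    def test_planted_identity_query(self, rng):
        genome_chars = list(_random_dna(rng, 6_000))
        protein = _random_protein(rng, 120)
        plant_single_exon_gene(genome_chars, 1_500, protein)
        genome = {"sc": "".join(genome_chars)}
        hsps = translated_search({"q": "M" + protein}, genome, SearchParams(min_score=80))
        assert hsps, "planted gene not found"
        top = max(hsps, key=lambda h: h.score)
        assert top.identity == 1.0
        assert top.genome_range.start == 1_500
        assert top.genome_range.end == 1_500 + 3 * 121
        assert top.frame == (1_500 % 3) + 1

    def test_score_matches_smith_waterman_oracle(self, rng):
        # gapless planted fragment: the single reported HSP's score must
        # equal the quadratic DP optimum for the (query, frame) pair
        for trial in range(5):
            genome_chars = list(_random_dna(rng, 900))
            protein = _random_protein(rng, 40)
            plant_single_exon_gene(genome_chars, 300, protein)
            genome = {"sc": "".join(genome_chars)}
            query = _mutate_protein(np.random.default_rng(trial), "M" + protein, 0.15)
            hsps = translated_search({"q": query}, genome, SearchParams(min_score=40))
            frames = six_frame_translate(genome["sc"])
            best_frame = max(
                smith_waterman_score(query, frames[f]) for f in (1, 2, 3, -1, -2, -3)
            )
            assert max(h.score for h in hsps) == pytest.approx(best_frame)

    def test_no_hits_returns_empty(self, rng):
        genome = {"sc": _random_dna(rng, 2_000)}
        assert translated_search({"q": "W" * 50}, genome, SearchParams(min_score=100)) == []

    def test_reported_identity_matches_recomputation(self, rng):
        genome_chars = list(_random_dna(rng, 4_000))
        protein = _random_protein(rng, 100)
        plant_single_exon_gene(genome_chars, 1_000, protein)
        genome = {"sc": "".join(genome_chars)}
        query = _mutate_protein(rng, "M" + protein, 0.1)
        for h in translated_search({"q": query}, genome, SearchParams(min_score=60)):
            frame_prot = six_frame_translate(genome["sc"])[h.frame]
            # recompute identity over the reported coordinate ranges
            qseg = query[h.query_range[0] : h.query_range[1]]
            gstart = (
                (h.genome_range.start - (h.frame - 1)) // 3
                if h.frame > 0
                else (len(genome["sc"]) - h.genome_range.end - (-h.frame - 1)) // 3
            )
            tseg = frame_prot[gstart : gstart + len(qseg)]
            if len(qseg) == len(tseg):  # gapless HSP: direct recount
                ident = sum(x == y for x, y in zip(qseg, tseg)) / len(qseg)
                assert h.identity == pytest.approx(ident)


class TestChainHsps:
    def _hsp(self, qr, gr, score=100.0, strand="+"):
        frame = 1 if strand == "+" else -1
        return HSP("q", "sc", frame, qr, GenomicInterval("sc", *gr, strand), score, 0.9)

    def test_two_exons_with_short_intron_chain(self):
        h1 = self._hsp((0, 100), (1_000, 1_300))
        h2 = self._hsp((100, 200), (3_300, 3_600))
        models = chain_hsps([h1, h2], SearchParams())
        assert len(models) == 1
        assert len(models[0].exons) == 2

    def test_oversize_intron_splits_models(self):
        h1 = self._hsp((0, 100), (1_000, 1_300))
        h2 = self._hsp((100, 200), (62_000, 62_300))
        models = chain_hsps([h1, h2], SearchParams(max_intron_bp=50_000))
        assert len(models) == 2
        assert all(len(m.exons) == 1 for m in models)

    def test_chain_score_matches_enumeration_oracle(self, rng):
        params = SearchParams(max_intron_bp=10_000)
        for _ in range(20):
            hsps = []
            for _ in range(8):
                q0 = int(rng.integers(0, 150))
                g0 = int(rng.integers(0, 20_000))
                hsps.append(
                    self._hsp(
                        (q0, q0 + int(rng.integers(10, 60))),
                        (g0, g0 + int(rng.integers(30, 200))),
                        score=float(rng.integers(20, 200)),
                    )
                )
            from grevol.annotate import _chain_gap, _chainable, _gap_holds_other_hit
            import itertools

            def chain_value(chain):
                v = chain[0].score
                for a, b in zip(chain, chain[1:]):
                    v += b.score - _chain_gap(a, b) / 1000.0 * params.intron_penalty_per_kb
                    v -= 4.0 * max(0, a.query_range[1] - b.query_range[0])
                return v

            best = 0.0
            order = sorted(hsps, key=lambda h: h.query_range)
            for r in range(1, 9):
                for combo in itertools.combinations(order, r):
                    if all(
                        _chainable(a, b, params)
                        and not _gap_holds_other_hit(a, b, hsps)
                        for a, b in zip(combo, combo[1:])
                    ):
                        best = max(best, chain_value(list(combo)))
            models = chain_hsps(hsps, params)
            assert models[0].score == pytest.approx(best)

    def test_mixed_queries_rejected(self):
        h1 = self._hsp((0, 10), (0, 30))
        h2 = HSP("other", "sc", 1, (0, 10), GenomicInterval("sc", 50, 80, "+"), 10.0, 0.5)
        with pytest.raises(ValueError):
            chain_hsps([h1, h2])


@pytest.fixture(scope="module")
def divergence_chain():
    """Three paralogs where the seed only reaches the first: p1 finds
    p2, p2 finds p3 — convergence needs three productive rounds."""
    rng = np.random.default_rng(3)
    p1 = _random_protein(rng, 150)
    p2 = _mutate_protein(rng, p1, 0.35)
    p3 = _mutate_protein(rng, p2, 0.35)
    genome_chars = list(_random_dna(rng, 20_000))
    proteins = {}
    for pos, prot in ((2_000, p1), (8_000, p2), (14_000, p3)):
        proteins[pos] = plant_single_exon_gene(genome_chars, pos, prot)
    seed = "M" + _mutate_protein(rng, p1, 0.12)
    return {"sc": "".join(genome_chars)}, seed, proteins


class TestIterateAnnotation:
    def test_divergence_chain_needs_three_rounds(self, divergence_chain):
        genome, seed, proteins = divergence_chain
        params = SearchParams(min_score=60, min_identity=0.62)
        res = iterate_annotation({"seed": seed}, genome, params)
        assert len(res.records) == 3
        for pos in proteins:  # each planted gene covered by one model
            hits = [
                r for r in res.records
                if r.span().start <= pos < r.span().end
            ]
            assert len(hits) == 1
        productive = [r for r in res.rounds if r.new_loci > 0]
        assert len(productive) == 3

    def test_no_hits_gives_empty_repertoire_after_one_round(self, rng):
        genome = {"sc": _random_dna(rng, 3_000)}
        res = iterate_annotation({"seed": "W" * 60}, genome, SearchParams(min_score=100))
        assert res.records == []
        assert len(res.rounds) == 1

    def test_output_independent_of_seed_ordering(self, divergence_chain):
        genome, seed, _ = divergence_chain
        params = SearchParams(min_score=60, min_identity=0.62)
        other = "M" + "L" * 149  # inert second seed
        a = iterate_annotation({"s1": seed, "s2": other}, genome, params)
        b = iterate_annotation({"s2": other, "s1": seed}, genome, params)
        assert [r.gene_id for r in a.records] == [r.gene_id for r in b.records]

    def test_accepted_loci_pairwise_non_overlapping(self, divergence_chain):
        genome, seed, _ = divergence_chain
        res = iterate_annotation(
            {"seed": seed}, genome, SearchParams(min_score=60, min_identity=0.62)
        )
        spans = [r.span() for r in res.records]
        for i, a in enumerate(spans):
            for b in spans[i + 1 :]:
                assert not overlaps(a, b)

    def test_empty_seed_set_is_error(self, rng):
        with pytest.raises(ValueError):
            iterate_annotation({}, {"sc": _random_dna(rng, 100)})
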