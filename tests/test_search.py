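"""Seeded local search: alignment statistics, seeding, extension, screening."""

import math
import random

import pytest
from Bio.Align import PairwiseAligner

from copatrace.refdb import ReferenceDB, ReferenceGene
from copatrace.search import (
    SearchParams,
    build_word_index,
    candidate_contigs,
    filter_hits,
    reverse_complement,
    search_contig,
    solve_karlin_altschul,
)

from conftest import mutate_dna, random_dna, small_db


def local_aligner(params: SearchParams) -> PairwiseAligner:
    """Independent Smith-Waterman oracle under the same scoring."""
    al = PairwiseAligner()
    al.mode = "local"
    al.match_score = params.match
    al.mismatch_score = params.mismatch
    al.open_gap_score = -(params.gap_open + params.gap_extend)
    al.extend_gap_score = -params.gap_extend
    return al


class TestKarlinAltschul:
    def test_lambda_satisfies_identity(self):
        # bisection oracle on (1/4)e^lam - ... = 1, independent of brentq
        lam, _ = solve_karlin_altschul(1, -2)

        def f(x):
            return 0.25 * math.exp(x) + 0.75 * math.exp(-2 * x) - 1.0

        lo, hi = 1e-9, 2.0
        for _ in range(100):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        assert abs(lam - (lo + hi) / 2) < 1e-9
        assert abs(f(lam)) < 1e-9

    def test_zero_expected_score_rejected(self):
        # (+1, -1): expected pair score is 0.25 - 0.75 = -0.5 < 0, so the
        # scheme is valid; (+3, -1) has positive expectation and must fail
        with pytest.raises(ValueError, match="invalid scoring scheme"):
            solve_karlin_altschul(3, -1)

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError):
            solve_karlin_altschul(-1, 2)

    def test_doubling_scores_halves_lambda(self):
        lam1, k1 = solve_karlin_altschul(1, -2)
        lam2, k2 = solve_karlin_altschul(2, -4)
        assert lam2 == pytest.approx(lam1 / 2, rel=1e-9)
        assert k1 == k2


class TestSeedIndex:
    def test_position_count(self, rng):
        db = ReferenceDB([ReferenceGene("gi_1_A_b", "1", "A_b", random_dna(rng, 15))])
        idx = build_word_index(db, 11)
        assert idx.n_positions == 5

    def test_homopolymer_single_word(self):
        db = ReferenceDB([ReferenceGene("gi_1_A_b", "1", "A_b", "A" * 11)])
        idx = build_word_index(db, 11)
        assert idx.n_positions == 1
        assert len(idx.words) == 1

    def test_n_words_skipped(self, rng):
        seq = random_dna(rng, 20)
        seq = seq[:10] + "N" + seq[11:]
        db = ReferenceDB([ReferenceGene("gi_1_A_b", "1", "A_b", seq)])
        idx = build_word_index(db, 11)
        assert all("N" not in w for w in idx.words)
        assert idx.n_positions == sum(
            1 for i in range(10) if "N" not in seq[i : i + 11]
        )

    def test_word_longer_than_reference(self, rng):
        db = ReferenceDB([ReferenceGene("gi_1_A_b", "1", "A_b", random_dna(rng, 9))])
        with pytest.raises(ValueError, match="gi_1_A_b"):
            build_word_index(db, 11)


class TestSearchContig:
    def test_exact_copy_full_length_hit(self, rng):
        db = small_db(rng, n_genes=1, length=100)
        idx = build_word_index(db, 11)
        ref = db.genes[0].sequence
        hits = search_contig(ref, "c", idx, db)
        top = hits[0]
        assert top.identity_pct == 100.0
        assert top.align_len == 100
        assert top.strand == "+"
        assert (top.q_start, top.q_end, top.s_start, top.s_end) == (1, 100, 1, 100)

    def test_reverse_complement_strand_flag(self, rng):
        db = small_db(rng, n_genes=1, length=100)
        idx = build_word_index(db, 11)
        hits = search_contig(
            reverse_complement(db.genes[0].sequence), "c", idx, db
        )
        top = hits[0]
        assert top.strand == "-"
        assert top.identity_pct == 100.0
        assert top.align_len == 100

    def test_short_contig_warns_empty(self, rng, caplog):
        db = small_db(rng, n_genes=1, length=100)
        idx = build_word_index(db, 11)
        assert search_contig("ACGTACG", "tiny", idx, db) == []

    def test_smith_waterman_oracle(self, rng):
        """Best-hit raw score equals the full Smith-Waterman optimum."""
        params = SearchParams()
        al = local_aligner(params)
        for trial in range(40):
            ref = random_dna(rng, rng.randint(120, 300))
            db = ReferenceDB([ReferenceGene("gi_1_O_r", "1", "O_r", ref)])
            idx = build_word_index(db, params.word_size)
            contig = mutate_dna(rng, ref, sub_rate=0.1, max_indels=3)
            if rng.random() < 0.5:
                contig = reverse_complement(contig)
            hits = search_contig(contig, "c", idx, db, params)
            assert hits, f"no hit in trial {trial}"
            assert hits[0].raw_score == al.score(contig, ref) or hits[
                0
            ].raw_score == al.score(reverse_complement(contig), ref)

    def test_strand_involution(self, rng):
        """Searching the reverse complement mirrors coordinates and strands."""
        params = SearchParams()
        db = small_db(rng, n_genes=2, length=200)
        idx = build_word_index(db, params.word_size)
        contig = (
            random_dna(rng, 50) + db.genes[0].sequence + random_dna(rng, 50)
        )
        m = len(contig)
        fwd = search_contig(contig, "c", idx, db, params)
        rev = search_contig(reverse_complement(contig), "c", idx, db, params)
        key = lambda h: (h.subject_id, h.raw_score)
        assert sorted(map(key, fwd)) == sorted(map(key, rev))
        flip = {"+": "-", "-": "+"}
        mapped = {
            (h.subject_id, m - h.q_end + 1, m - h.q_start + 1, flip[h.strand])
            for h in rev
        }
        assert {(h.subject_id, h.q_start, h.q_end, h.strand) for h in fwd} == mapped

    def test_self_search_database(self, rng):
        """Every database gene finds itself as top hit, full coverage."""
        db = small_db(rng, n_genes=5, length=250)
        idx = build_word_index(db, 11)
        for g in db:
            hits = search_contig(g.sequence, g.record_id, idx, db)
            top = hits[0]
            assert top.subject_id == g.record_id
            assert top.identity_pct == 100.0
            assert top.align_len == len(g)


class TestFilterHits:
    def make_hit(self, rng, **kw):
        from copatrace.search import LocalAlignmentHit

        defaults = dict(
            query_id="q",
            subject_id="s",
            identity_pct=95.0,
            align_len=100,
            mismatches=5,
            gap_opens=0,
            q_start=1,
            q_end=100,
            s_start=1,
            s_end=100,
            strand="+",
            raw_score=85,
            bit_score=100.0,
            evalue=1e-30,
        )
        defaults.update(kw)
        return LocalAlignmentHit(**defaults)

    def test_length_boundary(self, rng):
        params = SearchParams()
        below = self.make_hit(rng, align_len=39)
        at = self.make_hit(rng, align_len=40, evalue=1e-5)
        kept = filter_hits([below, at], params)
        assert kept == [at]

    def test_evalue_cutoff(self, rng):
        params = SearchParams()
        bad = self.make_hit(rng, evalue=1e-3)
        good = self.make_hit(rng, evalue=1e-4)
        assert filter_hits([bad, good], params) == [good]

    def test_sort_order(self, rng):
        params = SearchParams()
        h1 = self.make_hit(rng, align_len=50, evalue=1e-10, subject_id="b")
        h2 = self.make_hit(rng, align_len=60, evalue=1e-5, subject_id="a")
        h3 = self.make_hit(rng, align_len=50, evalue=1e-10, subject_id="a")
        assert filter_hits([h1, h2, h3], params) == [h2, h3, h1]

    def test_empty(self):
        assert filter_hits([], SearchParams()) == []

    def test_evalue_monotone_in_score(self):
        params = SearchParams()
        evs = [params.evalue(s, 1000, 10000) for s in range(10, 200, 10)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_candidate_contigs(self, rng):
        hits = [
            self.make_hit(rng, query_id=q) for q in ["c1", "c2", "c1", "c1", "c2"]
        ]
        assert candidate_contigs(hits) == {"c1", "c2"}
        assert candidate_contigs([]) == set()
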