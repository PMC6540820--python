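import math

import numpy as np
import pytest

from evescan.genome import Scaffold
from evescan.scoring import (
    BACKGROUND_FREQS,
    ScoringScheme,
    encode_aa,
    karlin_lambda_ungapped,
    load_matrix,
)
from evescan.search import (
    ProteinRecord,
    SearchHit,
    external_engine_adapter,
    local_align,
    rank_hits,
    revcomp,
    search_blastx_like,
    search_tblastn_like,
    six_frame_translate,
    write_hits_tabular,
)
from evescan.simulate import SimConfig, reverse_translate, simulate_protein_db

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# independent table-driven oracle for the standard genetic code
_B = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_ORACLE = {
    a + b + c: _AAS[16 * i + 4 * j + k]
    for i, a in enumerate(_B)
    for j, b in enumerate(_B)
    for k, c in enumerate(_B)
}


def sw_score_oracle(q, s, mat, gap_open, gap_extend):
    """Plain quadratic Smith-Waterman, score only; a gap of length k
    costs gap_open + k * gap_extend."""
    n, m = len(q), len(s)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            H[i][j] = max(0, H[i - 1][j - 1] + mat[q[i - 1], s[j - 1]], E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestScoring:
    def test_matrix_symmetric_with_negative_expectation(self):
        m = load_matrix()
        assert np.array_equal(m, m.T)
        p = np.outer(BACKGROUND_FREQS, BACKGROUND_FREQS)
        assert (p * m[:20, :20]).sum() < 0

    def test_ungapped_lambda_solves_characteristic_equation(self):
        m = load_matrix()
        lam = karlin_lambda_ungapped(m)
        p = np.outer(BACKGROUND_FREQS, BACKGROUND_FREQS)
        assert abs((p * np.exp(lam * m[:20, :20].astype(float))).sum() - 1.0) < 1e-6

    def test_bit_score_evalue_relation(self, scheme):
        for raw in (40, 100, 333):
            bits = scheme.bit_score(raw)
            assert bits == pytest.approx(
                (scheme.karlin_lambda * raw - math.log(scheme.karlin_K)) / math.log(2),
                abs=1e-9,
            )
            ev = scheme.evalue(raw, 200, 1_000_000)
            assert ev > 0


class TestSixFrame:
    def test_standard_code_frame1(self):
        assert six_frame_translate("ATGAAATAA")[0] == (1, "MK*")

    def test_reverse_frames_are_revcomp_forward_frames(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = "".join(rng.choice(list("ACGT"), size=rng.integers(9, 120)))
            frames = dict(six_frame_translate(s))
            frames_rc = dict(six_frame_translate(revcomp(s)))
            assert frames[-1] == frames_rc[1]
            assert frames[-2] == frames_rc[2]

    def test_matches_codon_table_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            s = "".join(rng.choice(list("ACGT"), size=rng.integers(3, 90)))
            for frame, aa in six_frame_translate(s):
                src = s if frame > 0 else revcomp(s)
                off = abs(frame) - 1
                expected = "".join(
                    CODON_ORACLE[src[i : i + 3]]
                    for i in range(off, off + 3 * ((len(src) - off) // 3), 3)
                )
                assert aa == expected

    def test_ambiguous_codons_become_x(self):
        assert six_frame_translate("ATGNNN")[0] == (1, "MX")

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            six_frame_translate("ACGQ")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            six_frame_translate("AC")


class TestLocalAlign:
    def test_matches_smith_waterman_oracle(self, scheme):
        rng = np.random.default_rng(5)
        for _ in range(60):
            q = encode_aa("".join(rng.choice(list(AA20), size=rng.integers(5, 61))))
            s = encode_aa("".join(rng.choice(list(AA20), size=rng.integers(5, 61))))
            aln = local_align(q, s, scheme)
            got = aln.raw_score if aln else 0
            assert got == sw_score_oracle(q, s, scheme.matrix, scheme.gap_open, scheme.gap_extend)

    def test_alignment_score_is_consistent(self, scheme):
        rng = np.random.default_rng(6)
        for _ in range(20):
            base = "".join(rng.choice(list(AA20), size=80))
            q = encode_aa(base)
            s = encode_aa(base[10:70])
            aln = local_align(q, s, scheme)
            score = 0
            gap_q = gap_s = 0
            for a, b in zip(aln.aligned_q, aln.aligned_s):
                if a == "-":
                    gap_q += 1
                elif b == "-":
                    gap_s += 1
                else:
                    score += int(scheme.matrix[encode_aa(a)[0], encode_aa(b)[0]])
            # reconstruct affine gap costs from the gapped strings
            def gap_cost(t):
                cost = runs = 0
                prev = False
                for c in t:
                    if c == "-":
                        cost += scheme.gap_extend
                        if not prev:
                            runs += 1
                        prev = True
                    else:
                        prev = False
                return cost + runs * scheme.gap_open
            assert aln.raw_score == score - gap_cost(aln.aligned_q) - gap_cost(aln.aligned_s)


@pytest.fixture(scope="module")
def tiny_db():
    cfg = SimConfig(n_viral_clades=2, proteins_per_clade=2, n_host_decoys=6, seed=21)
    viral, decoys = simulate_protein_db(cfg)
    return viral, decoys


class TestTblastnLike:
    def test_planted_exact_segment_found_in_right_frame(self, scheme):
        rng = np.random.default_rng(7)
        prot = ProteinRecord("q1", "", "".join(rng.choice(list(AA20), size=100)))
        nt = reverse_translate(rng, prot.seq)
        bg = "".join(rng.choice(list("ACGT"), size=9_000))
        seq = bg[:4_001] + nt + bg[4_001 + len(nt):]
        hits = search_tblastn_like([prot], [Scaffold("sc", seq)], scheme, 1e-20)
        assert len(hits) == 1
        h = hits[0]
        assert h.frame == (4_001 % 3) + 1
        assert h.subject_nt_start <= 4_001 and h.subject_nt_end >= 4_001 + len(nt)
        assert h.evalue <= 1e-20

    def test_no_hits_between_unrelated_sequences(self, scheme):
        rng = np.random.default_rng(8)
        for trial in range(25):
            sc = Scaffold("s", "".join(rng.choice(list("ACGT"), size=10_000)))
            q = ProteinRecord("q", "", "".join(rng.choice(list(AA20), size=200)))
            assert search_tblastn_like([q], [sc], scheme, 1e-20) == []

    def test_revcomp_scan_mirrors_scores_and_frames(self, scheme, tiny_db):
        viral, _ = tiny_db
        rng = np.random.default_rng(9)
        nt = reverse_translate(rng, viral[0].seq[:120])
        bg = "".join(rng.choice(list("ACGT"), size=12_000))
        seq = bg[:5_000] + nt + bg[5_000 + len(nt):]
        fwd = search_tblastn_like([viral[0]], [Scaffold("s", seq)], scheme, 1e-20)
        rev = search_tblastn_like([viral[0]], [Scaffold("s", revcomp(seq))], scheme, 1e-20)
        assert sorted(h.raw_score for h in fwd) == sorted(h.raw_score for h in rev)
        assert sorted(-h.frame for h in fwd) == sorted(h.frame for h in rev)
        # intervals mirror around the sequence length
        L = len(seq)
        assert sorted((L - h.subject_nt_end, L - h.subject_nt_start) for h in rev) == \
            sorted((h.subject_nt_start, h.subject_nt_end) for h in fwd)

    def test_evalue_threshold_monotonic(self, scheme, clean_scan):
        data, _ = clean_scan
        strict = search_tblastn_like(data.viral, data.genome, scheme, 1e-20)
        loose = search_tblastn_like(data.viral, data.genome, scheme, 1e-3)
        key = lambda h: (h.query_id, h.subject_id, h.frame, h.subject_nt_start)
        assert set(map(key, strict)) <= set(map(key, loose))

    def test_bit_evalue_relation_holds_for_every_hit(self, scheme, clean_scan):
        data, result = clean_scan
        n_space = sum(2 * len(s.seq) // 1 for s in data.genome)  # upper bound only
        for h in result.hits:
            assert h.bit_score == pytest.approx(
                (scheme.karlin_lambda * h.raw_score - math.log(scheme.karlin_K))
                / math.log(2),
                abs=1e-9,
            )
            assert h.evalue > 0
            ungapped = sum(c != "-" for c in h.aligned_subject)
            assert h.subject_nt_end - h.subject_nt_start == 3 * ungapped

    def test_empty_query_set_rejected(self, scheme):
        with pytest.raises(ValueError):
            search_tblastn_like([], [Scaffold("s", "ACGTACGT")], scheme, 1e-5)

    def test_empty_genome_gives_empty_result(self, scheme, tiny_db):
        viral, _ = tiny_db
        assert search_tblastn_like(viral, [], scheme, 1e-5) == []


class TestBlastxLike:
    def test_reverse_translated_copy_recovers_source(self, scheme, tiny_db):
        viral, decoys = tiny_db
        rng = np.random.default_rng(10)
        nt = reverse_translate(rng, viral[1].seq)
        ranked = search_blastx_like(nt, viral + decoys, scheme, 1e-3)
        assert ranked and ranked[0].subject_id == viral[1].id

    def test_empty_db(self, scheme):
        assert search_blastx_like("ATGATGATG", [], scheme) == []

    def test_short_query_rejected(self, scheme, tiny_db):
        viral, _ = tiny_db
        with pytest.raises(ValueError):
            search_blastx_like("AT", viral, scheme)

    def test_ranking_matches_sort_oracle(self):
        rng = np.random.default_rng(11)
        hits = []
        for i in range(100):
            ev = float(10.0 ** rng.integers(-30, -1))
            hits.append(
                SearchHit(
                    query_id="q", subject_id=f"p{rng.integers(40)}", frame=1,
                    subject_nt_start=0, subject_nt_end=3, query_aa_start=0,
                    query_aa_end=1, raw_score=int(rng.integers(50, 500)),
                    bit_score=float(rng.integers(20, 200)), evalue=ev,
                    aligned_query="A", aligned_subject="A",
                )
            )
        expected = sorted(hits, key=lambda h: (h.evalue, -h.bit_score, h.subject_id))
        assert rank_hits(hits) == expected


class TestAdapter:
    def test_minus_strand_coordinates_normalized(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q\ts\t90.0\t20\t2\t0\t1\t20\t101\t40\t1e-30\t55.0\n")
        (h,) = external_engine_adapter(p)
        assert h.frame < 0
        assert (h.subject_nt_start, h.subject_nt_end) == (39, 101)
        assert (h.query_aa_start, h.query_aa_end) == (0, 20)

    def test_roundtrip_internal_to_tabular_to_internal(self, scheme, clean_scan, tmp_path):
        _, result = clean_scan
        hits = result.hits[:20]
        p = tmp_path / "out.tsv"
        write_hits_tabular(hits, p)
        back = external_engine_adapter(p, scheme)
        assert len(back) == len(hits)
        for a, b in zip(hits, back):
            assert (a.query_id, a.subject_id, a.frame) == (b.query_id, b.subject_id, b.frame)
            assert (a.subject_nt_start, a.subject_nt_end) == (b.subject_nt_start, b.subject_nt_end)
            assert (a.query_aa_start, a.query_aa_end) == (b.query_aa_start, b.query_aa_end)
            assert b.evalue == pytest.approx(a.evalue, rel=5e-3)
            assert b.raw_score == pytest.approx(a.raw_score, abs=1)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("q\ts\t90.0\t20\n")
        with pytest.raises(ValueError, match="line 1"):
            external_engine_adapter(p)
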