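"""Local-alignment screen tests, checked against a brute-force DP oracle."""

import math
import random

import pytest
from Bio.Align import substitution_matrices

from lassomine.formats import NUCLEOTIDE, PROTEIN, SequenceRecord
from lassomine.homology import (
    DEFAULT_PARAMS,
    evalue,
    global_identity,
    local_align,
    screen_cores,
    screen_proteins,
    six_frame_translations,
)
from lassomine.orfs import reverse_complement

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

AA = "ACDEFGHIKLMNPQRSTVWY"


def sw_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Independent affine-gap Smith-Waterman (Gotoh three-state DP).

    A gap of length k costs gap_open + (k - 1) * gap_extend, matching the
    package's scoring convention.
    """
    n, m = len(a), len(b)
    NEG = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


class TestLocalAlign:
    @pytest.mark.parametrize("seq", ["MKK", "GKSIKPSF", "MTYNKPSFEKISSFKESTM"])
    def test_self_alignment_is_fully_identical(self, seq):
        score, ident, (q_iv, s_iv) = local_align(seq, seq)
        assert ident == 100.0
        assert q_iv == (0, len(seq)) and s_iv == (0, len(seq))
        assert score == sw_oracle(seq, seq)

    def test_no_positive_alignment_returns_zero_sentinel(self):
        score, ident, _ = local_align("MKK", "WWW")
        assert score == 0 and ident == 0.0
        assert sw_oracle("MKK", "WWW") == 0

    def test_score_matches_oracle_on_example_pair(self):
        score, ident, _ = local_align("GKSIKPSF", "GKVIKASF")
        assert score == sw_oracle("GKSIKPSF", "GKVIKASF") == 27
        assert ident == pytest.approx(100.0 * 6 / 8)

    def test_symmetry(self):
        a, b = "GPGLKTPDAVQPDVDEVVHYS", "GKSIKPSFDAFRIDENGNLWASFES"
        assert local_align(a, b)[0] == local_align(b, a)[0]

    def test_oracle_equivalence_on_random_pairs(self):
        """Aligner score equals the brute-force DP on 200 random short pairs."""
        rng = random.Random(1234)
        for _ in range(200):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 30)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 30)))
            expected = sw_oracle(a, b)
            got = local_align(a, b)[0]
            assert got == expected, (a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "MKK")


class TestEvalue:
    def test_linear_in_subject_length(self):
        e1 = evalue(30, 100, 5000)
        e2 = evalue(30, 100, 10000)
        assert e2 == pytest.approx(2 * e1)

    def test_decreasing_in_score_and_vanishing_limit(self):
        scores = [10, 20, 50, 200]
        values = [evalue(s, 100, 10000) for s in scores]
        assert all(x > y for x, y in zip(values, values[1:]))
        assert evalue(5000, 100, 10000) < 1e-300

    def test_closed_form_value(self):
        expected = 0.041 * 100 * 10000 * math.exp(-0.267 * 50)
        assert evalue(50, 100, 10000) == pytest.approx(expected, rel=1e-12)


class TestScreenProteins:
    def test_exact_copy_scores_full_identity(self):
        query = SequenceRecord(id="q", residues="MKNWNAPEIKELCLSGTQQHGTPNPYVD",
                               alphabet=PROTEIN)
        target = SequenceRecord(
            id="t",
            residues="AAAA" + query.residues + "WWWW",
            alphabet=PROTEIN,
        )
        hits = screen_proteins([query], [target])
        assert len(hits) == 1
        assert hits[0].identity_pct == 100.0

    def test_thresholds_hold_for_every_hit(self, anchor_panel):
        targets = [
            SequenceRecord(id="t", residues=anchor_panel[0].residues,
                           alphabet=PROTEIN)
        ]
        hits = screen_proteins(anchor_panel, targets)
        assert hits, "identical target must be found"
        for h in hits:
            assert h.identity_pct >= 30.0
            assert h.evalue < 1e-5

    def test_shuffled_decoys_produce_no_hits(self, anchor_panel):
        rng = random.Random(99)
        decoys = []
        for i, rec in enumerate(anchor_panel):
            residues = list(rec.residues)
            rng.shuffle(residues)
            decoys.append(
                SequenceRecord(id=f"decoy{i}", residues="".join(residues),
                               alphabet=PROTEIN)
            )
        assert screen_proteins(anchor_panel, decoys) == []

    def test_planted_gene_found_at_its_locus(self, anchor_panel):
        from lassomine.synthetic import reverse_translate
        import numpy as np

        rng = np.random.default_rng(7)
        lasC = anchor_panel[1]
        gene = reverse_translate(lasC.residues, rng)
        background = "".join(rng.choice(list("ACGT"), size=3000))
        contig = SequenceRecord(
            id="ctg", residues=background[:1500] + gene + background[1500:],
            alphabet=NUCLEOTIDE,
        )
        hits = [h for h in screen_proteins([lasC], [contig])
                if h.query_id == lasC.id]
        assert len(hits) == 1
        assert hits[0].subject_begin == 1500
        assert hits[0].subject_end == 1500 + len(gene)
        assert hits[0].strand == "+"

    def test_empty_target_set_is_empty_result(self, anchor_panel):
        assert screen_proteins(anchor_panel, []) == []


class TestScreenCores:
    def test_identical_core_hits_at_100(self):
        core = SequenceRecord(id="k", residues="GKSIKPSFDAFRIDENGNLWASFES",
                              alphabet=PROTEIN)
        cand = SequenceRecord(id="c", residues=core.residues, alphabet=PROTEIN)
        hits = screen_cores([core], [cand])
        assert len(hits) == 1 and hits[0].identity_pct == 100.0

    def test_below_threshold_is_no_hit(self):
        # 13 identities over 21 columns = 61.9% < 70%
        a = "GKSIKPSFDAFRIDENGNLWA"
        b = "GKSIKPSFDAFRIYYYYYYYY"
        matches = sum(x == y for x, y in zip(a, b))
        assert matches == 13
        panel = [SequenceRecord(id="k", residues=a, alphabet=PROTEIN)]
        cand = [SequenceRecord(id="c", residues=b, alphabet=PROTEIN)]
        assert screen_cores(panel, cand) == []

    def test_identity_agrees_with_hand_count(self):
        a, b = "GKSIKPSFDA", "GKVIKASFDA"
        _, ident, _ = local_align(a, b)
        hand = sum(x == y for x, y in zip(a, b))  # gap-free pair
        assert ident == pytest.approx(100.0 * hand / 10)


class TestSixFrames:
    def test_six_frames_cover_both_strands(self):
        dna = "ATGAAAAAATAA"
        frames = six_frame_translations(dna)
        assert len(frames) == 6
        assert ("MKK*", "+", 0) in frames

    def test_reverse_frames_match_reverse_complement(self):
        dna = "ATGGATTACACGTTT"
        fwd = {p for p, s, f in six_frame_translations(dna) if s == "-"}
        rc_fwd = {p for p, s, f in six_frame_translations(reverse_complement(dna))
                  if s == "+"}
        assert fwd == rc_fwd


class TestGlobalIdentity:
    def test_identical_is_100(self):
        assert global_identity("MKKW", "MKKW") == 100.0

    def test_prefix_counts_terminal_gaps(self):
        # 4 identities over 8 columns
        assert global_identity("MKKWAAAA", "MKKW") == pytest.approx(50.0)
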