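"""Precursor-grammar tests, including a brute-force enumeration oracle."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lassomine.grammar import (
    DEFAULT_GRAMMAR,
    GrammarConfig,
    PrecursorSplit,
    batch_split,
    best_split,
    enumerate_splits,
    ring_annotation,
    score_split,
    strip_label_suffix,
)

KPR7A = "MKKDWTIPTLEVLDINMTMA" + "GPGLKTPDAVQPDVDEVVHYS"
B316 = "MKNWNAPEIKELCLSGTQQH" + "GTPNPYVDGKIYDAQRNENWFTFSGNNVDDTATPGEVIIGNP"
D15D = "MKTWITPRVEELEIVETAQ" + "GKSIKPSFDAFRIDENGNLWASFES"


def brute_force_splits(peptide, config=DEFAULT_GRAMMAR):
    """Independent candidate enumeration over all (g, acceptor, thr) triples."""
    found = set()
    n = len(peptide)
    for g in range(n):
        if peptide[g] not in config.ring_donors:
            continue
        if not (config.min_leader_aa <= g <= config.max_leader_aa):
            continue
        if not (config.min_core_aa <= n - g <= config.max_core_aa):
            continue
        acceptors = [
            p for p in config.acceptor_positions
            if g + p - 1 < n and peptide[g + p - 1] in config.ring_acceptors
        ]
        thrs = [
            off for off in config.leader_thr_window
            if 0 <= g + off < g and peptide[g + off] == "T"
        ]
        if acceptors and thrs:
            found.add(g)
    return found


class TestEnumerateSplits:
    def test_no_donor_residue_means_no_candidates(self):
        assert enumerate_splits("M" + "A" * 40) == []

    def test_single_donor_construction(self):
        peptide = "M" * 12 + "TAA" + "G" + "A" * 7 + "D" + "A" * 13
        candidates = enumerate_splits(peptide)
        assert len(candidates) == 1
        (c,) = candidates
        assert len(c.leader) == 15
        assert c.acceptor_pos == 9
        assert c.thr_offset == -3

    @pytest.mark.parametrize("peptide", [KPR7A, B316, D15D])
    def test_candidate_set_matches_brute_force(self, peptide):
        got = {len(c.leader) for c in enumerate_splits(peptide)}
        assert got == brute_force_splits(peptide)

    def test_acceptor_at_both_positions_takes_smaller(self):
        peptide = "M" * 12 + "TAA" + "G" + "A" * 6 + "DD" + "A" * 12
        (c,) = enumerate_splits(peptide)
        assert c.acceptor_pos == 8

    def test_reconstruction_invariant(self):
        for c in enumerate_splits(B316):
            assert c.leader + c.core == B316

    def test_relaxing_bounds_never_removes_candidates(self):
        tight = GrammarConfig(min_core_aa=20, max_core_aa=45)
        loose = GrammarConfig(min_core_aa=15, max_core_aa=50)
        for peptide in (KPR7A, B316, D15D):
            tight_set = {len(c.leader) for c in enumerate_splits(peptide, tight)}
            loose_set = {len(c.leader) for c in enumerate_splits(peptide, loose)}
            assert tight_set <= loose_set

    def test_non_protein_input_rejected(self):
        with pytest.raises(ValueError):
            enumerate_splits("MKK123" + "A" * 30)


class TestScoreSplit:
    def _candidate(self, thr_offset, cterm_ser):
        leader = list("M" * 15)
        leader[15 + thr_offset] = "T"
        core = "G" + "A" * 6 + "D" + "A" * 8 + ("SAA" if cterm_ser else "AAA")
        return PrecursorSplit(
            full="".join(leader) + core, leader="".join(leader), core=core,
            acceptor_pos=8, thr_offset=thr_offset, has_cterm_ser=cterm_ser,
        )

    def test_canonical_thr_and_ser_scores_four(self):
        assert score_split(self._candidate(-3, True)) == 4.0

    def test_offset_thr_no_ser_scores_two(self):
        assert score_split(self._candidate(-4, False)) == 2.0

    def test_scores_rank_hand_enumerated_candidates(self):
        # adjacent donors GG share one D; the first sees T at -3, the second at -4
        peptide = "M" * 12 + "TAA" + "GG" + "A" * 6 + "D" + "A" * 12
        candidates = enumerate_splits(peptide)
        assert len(candidates) == 2
        ranked = sorted(candidates, key=lambda c: c.score, reverse=True)
        assert ranked[0].thr_offset == -3
        assert ranked[1].thr_offset == -4
        assert ranked[0].score > ranked[1].score


class TestBestSplit:
    def test_reproduces_kpr7a_boundary(self):
        s = best_split(KPR7A)
        assert len(s.leader) == 20
        assert len(s.core) == 21
        assert s.acceptor_pos == 8

    def test_reproduces_b316_boundary(self):
        s = best_split(B316)
        assert len(s.core) == 42
        assert s.thr_offset == -4

    def test_homopolymer_has_no_split(self):
        assert best_split("A" * 40) is None

    def test_determinism(self):
        a, b = best_split(B316), best_split(B316)
        assert a == b


class TestBatchSplit:
    def test_fixture_recovers_published_counts(self, precursor_table):
        records = [
            (row["entry_label"], row["leader"] + row["core"])
            for _, row in precursor_table.iterrows()
        ]
        table, summary = batch_split(records)
        assert summary["n_passing"] == 35
        assert summary["n_distinct_genomes"] == 29

    def test_boundary_recovery_on_fixture(self, precursor_table):
        """The grammar recovers at least 33 of the 35 curated splits exactly."""
        matches = 0
        for _, row in precursor_table.iterrows():
            s = best_split(row["leader"] + row["core"])
            if s and s.leader == row["leader"] and s.core == row["core"]:
                matches += 1
                assert len(s.core) == row["recomputed_core_length"]
        assert matches >= 33

    def test_empty_input(self):
        table, summary = batch_split([])
        assert summary == {"n_passing": 0, "n_distinct_genomes": 0}
        assert len(table) == 0

    def test_shared_genome_label_counted_once(self):
        peptide = D15D
        records = [(f"Genome X (#{i})", peptide) for i in (1, 2, 3)]
        _, summary = batch_split(records)
        assert summary["n_passing"] == 3
        assert summary["n_distinct_genomes"] == 1

    def test_label_suffix_stripping(self):
        assert strip_label_suffix("Butyrivibrio sp. NC3005 (#1, #2)") == \
            "Butyrivibrio sp. NC3005"
        assert strip_label_suffix("Ruminococcus albus 8") == "Ruminococcus albus 8"


class TestRingAnnotation:
    def test_kpr7a_ring(self):
        donor, acceptor, length = ring_annotation(best_split(KPR7A))
        assert (donor, acceptor, length) == ("G1", "D8", 8)

    def test_d15d_ring(self):
        donor, acceptor, length = ring_annotation(best_split(D15D))
        assert (donor, acceptor) == ("G1", "D9")
        assert length == 9


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=30, deadline=None)
def test_sampled_precursors_always_split(seed):
    """Grammar closure: sampled precursors always pass their own grammar."""
    from lassomine.synthetic import sample_precursor

    peptide = sample_precursor(seed=seed)
    split = best_split(peptide)
    assert split is not None
    assert split.leader + split.core == peptide
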