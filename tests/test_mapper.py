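import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbgmap.graph import FORWARD_ONLY, build_cdbg, count_kmers, reverse_complement
from dbgmap.mapper import (
    MappingParams,
    Status,
    StepStats,
    anchor_extremity,
    check_mapping,
    find_anchors,
    hamming_cost,
    map_on_unitigs,
    map_read_exhaustive,
    map_read_greedy,
    map_reads,
)
from dbgmap.overlap import build_overlap_index
from dbgmap.simulate import random_genome, simulate_reads
from oracles import enumerate_anchored_mappings, hamming

from conftest import random_kmer_graph


class TestHammingCost:
    def test_one_mismatch(self):
        assert hamming_cost("AAGC", "AAGA") == 1

    def test_identity(self):
        assert hamming_cost("ACGTACGT", "ACGTACGT") == 0

    def test_n_always_mismatches(self):
        assert hamming_cost("NN", "NA") == 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming_cost("AA", "AAA")

    @given(st.integers(0, 40), st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_positional_oracle(self, length, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGTN"), size=length))
        b = "".join(rng.choice(list("ACGTN"), size=length))
        assert hamming_cost(a, b) == hamming(a, b)


class TestFindAnchors:
    def test_fixture_read(self, toy_index):
        anchors = find_anchors("TAAGC", toy_index)
        assert [(a.pos, a.word) for a in anchors] == [(0, "TA"), (1, "AA"), (3, "GC")]

    def test_error_destroys_anchor(self, toy_index):
        anchors = find_anchors("TATGC", toy_index)
        assert [(a.pos, a.word) for a in anchors] == [(0, "TA"), (3, "GC")]

    def test_no_anchor(self, toy_index):
        assert find_anchors("GGGGG", toy_index) == []


class TestAnchorExtremity:
    def test_left_trace(self, toy_graph, toy_index, no_rc_params):
        anchors = find_anchors("TAAGC", toy_index)
        anchor, uid, mm = anchor_extremity("TAAGC", anchors, toy_graph, no_rc_params, "left")
        assert (anchor.pos, uid, mm) == (1, "u3", 0)  # u3 = TAA beats u2 = CAA

    def test_left_failure_budget(self, toy_graph, toy_index, no_rc_params):
        anchors = find_anchors("TATGC", toy_index)
        # "TA"@0 has no enders (failure 1); "GC"@3 needs a length-5 suffix of
        # AAGC (failure 2) -> n=2 exhausted
        assert anchor_extremity("TATGC", anchors, toy_graph, no_rc_params, "left") is None

    def test_anchor_at_pos_zero_trivial(self, toy_graph, toy_index, no_rc_params):
        anchors = find_anchors("AAGC", toy_index)
        anchor, uid, mm = anchor_extremity("AAGC", anchors, toy_graph, no_rc_params, "left")
        assert anchor.pos == 0 and mm == 0

    def test_right_side(self, toy_graph, toy_index, no_rc_params):
        anchors = find_anchors("TAAGC", toy_index)
        # "GC"@3 has no starters (failure 1); "AA"@1 aligns AAGC exactly
        anchor, uid, mm = anchor_extremity("TAAGC", anchors, toy_graph, no_rc_params, "right")
        assert (anchor.pos, uid, mm) == (1, "u1", 0)


class TestMapReadGreedy:
    def test_exact_branching_read(self, toy_graph, toy_index, no_rc_params):
        m = map_read_greedy("r1", "TAAGC", toy_graph, toy_index, no_rc_params)
        assert m.status is Status.MAPPED_PATH
        assert m.walk == ("u3", "u1")
        assert m.start_offset == 0
        assert m.mismatches == 0
        check_mapping(m, "TAAGC", toy_graph)

    def test_one_substitution(self, toy_graph, toy_index, no_rc_params):
        m = map_read_greedy("r2", "TAAGA", toy_graph, toy_index, no_rc_params)
        assert m.status is Status.MAPPED_PATH
        assert m.walk == ("u3", "u1")
        assert m.mismatches == 1
        check_mapping(m, "TAAGA", toy_graph)

    def test_unanchored(self, toy_graph, toy_index, no_rc_params):
        m = map_read_greedy("r3", "TATGC", toy_graph, toy_index, no_rc_params)
        assert m.status is Status.UNMAPPED_UNANCHORED

    def test_too_short(self, toy_graph, toy_index, no_rc_params):
        m = map_read_greedy("r4", "TA", toy_graph, toy_index, no_rc_params)
        assert m.status is Status.UNMAPPED_TOO_SHORT

    def test_second_branching_read(self, toy_graph, toy_index, no_rc_params):
        m = map_read_greedy("r5", "CAAGC", toy_graph, toy_index, no_rc_params)
        assert m.status is Status.MAPPED_PATH
        assert m.walk == ("u2", "u1")
        assert m.mismatches == 0

    def test_reverse_complement_mapping(self, toy_graph, toy_index):
        params = MappingParams()
        m = map_read_greedy("r6", reverse_complement("TAAGC"), toy_graph, toy_index, params)
        assert m.status is Status.MAPPED_PATH
        assert m.orientation == "reverse"
        assert m.walk == ("u3", "u1")
        check_mapping(m, reverse_complement("TAAGC"), toy_graph)

    def test_zero_budget_blocks_extremity(self, toy_graph, toy_index):
        # with t=0 the right extremity of TAAGA cannot align -> unanchored
        params = MappingParams(max_mismatches=0, try_reverse_complement=False)
        m = map_read_greedy("r7", "TAAGA", toy_graph, toy_index, params)
        assert m.status is Status.UNMAPPED_UNANCHORED

    def test_degenerate_walk_is_containment(self, toy_graph, toy_index, no_rc_params):
        # AAGC anchors at pos 0, so the left extremity contributes only the
        # overlap; the normalized mapping is containment in u1
        m = map_read_greedy("r8", "AAGC", toy_graph, toy_index, no_rc_params)
        assert m.status is Status.MAPPED_UNITIG
        assert m.walk == ("u1",) and m.start_offset == 0 and m.mismatches == 0


@pytest.fixture(scope="module")
def trap_graph():
    """Graph where greedy's locally best extension dead-ends.

    k=3 kmers spell unitigs AACG(u1), AAGGT(u2), TAA(u3).  Mapping TAACGT
    with t=1: after the left extremity TAA, candidate u1 aligns with 0
    mismatches but has no successor, while u2 completes the read with 1.
    """
    kmers = {"TAA", "AAC", "ACG", "AAG", "AGG", "GGT"}
    g = build_cdbg(kmers, 3)
    assert [(u.id, u.seq) for u in g] == [("u1", "AACG"), ("u2", "AAGGT"), ("u3", "TAA")]
    return g


class TestGreedyVsExhaustive:
    READ = "TAACGT"
    PARAMS = MappingParams(max_mismatches=1, anchor_failures=3, try_reverse_complement=False)

    def test_greedy_falls_into_dead_end(self, trap_graph):
        index = build_overlap_index(trap_graph)
        m = map_read_greedy("r", self.READ, trap_graph, index, self.PARAMS)
        assert m.status is Status.UNMAPPED_OVER_BUDGET

    def test_exhaustive_recovers(self, trap_graph):
        index = build_overlap_index(trap_graph)
        m = map_read_exhaustive("r", self.READ, trap_graph, index, self.PARAMS)
        assert m.status is Status.MAPPED_PATH
        assert m.walk == ("u3", "u2")
        assert m.mismatches == 1
        check_mapping(m, self.READ, trap_graph)

    def test_exhaustive_agrees_with_enumeration(self, trap_graph):
        index = build_overlap_index(trap_graph)
        m = map_read_exhaustive("r", self.READ, trap_graph, index, self.PARAMS)
        best = enumerate_anchored_mappings(trap_graph, self.READ, 1, 1, ["u3"])
        assert best is not None
        assert best[0] == m.mismatches and best[2] == m.walk

    def test_state_cap_raises(self, trap_graph, monkeypatch):
        import dbgmap.mapper as mapper_mod
        from dbgmap.errors import SearchLimitExceeded

        monkeypatch.setattr(mapper_mod, "EXHAUSTIVE_STATE_CAP", 1)
        index = build_overlap_index(trap_graph)
        with pytest.raises(SearchLimitExceeded):
            map_read_exhaustive("r", self.READ, trap_graph, index, self.PARAMS)

    def test_exhaustive_matches_greedy_on_toy(self, toy_graph, toy_index, no_rc_params):
        for read in ("TAAGC", "TAAGA", "CAAGC"):
            a = map_read_greedy("r", read, toy_graph, toy_index, no_rc_params)
            b = map_read_exhaustive("r", read, toy_graph, toy_index, no_rc_params)
            assert (a.status, a.walk, a.mismatches) == (b.status, b.walk, b.mismatches)


class TestMapOnUnitigs:
    def test_exact_containment(self, toy_graph, no_rc_params):
        m = map_on_unitigs("r1", "AAGC", toy_graph, no_rc_params)
        assert m.status is Status.MAPPED_UNITIG
        assert m.walk == ("u1",) and m.start_offset == 0 and m.mismatches == 0

    def test_offset_containment(self, toy_graph, no_rc_params):
        m = map_on_unitigs("r2", "AGC", toy_graph, no_rc_params)
        assert m.status is Status.MAPPED_UNITIG
        assert m.walk == ("u1",) and m.start_offset == 1

    def test_read_longer_than_unitigs(self, toy_graph, no_rc_params):
        m = map_on_unitigs("r3", "TAAGCTTTT", toy_graph, no_rc_params)
        assert m.status is Status.UNMAPPED_UNANCHORED

    def test_seed_retry_on_errorful_first_kmer(self):
        # k=11 on 500 bp: (k-1)-mers unique, the genome is one unitig
        genome = random_genome(500, 3)
        g = build_cdbg({genome[i : i + 11] for i in range(len(genome) - 10)}, 11)
        read = genome[50:90]
        corrupted = ("T" if read[0] != "T" else "A") + read[1:]
        m = map_on_unitigs("r", corrupted, g, MappingParams(try_reverse_complement=False))
        assert m.status is Status.MAPPED_UNITIG
        assert m.start_offset == 50 and m.mismatches == 1
        check_mapping(m, corrupted, g)


class TestPipeline:
    def test_fixture_summary(self, toy_graph, toy_index, no_rc_params):
        reads = ["TAAGC", "CAAGC", "AAGC"]
        mappings, summary = map_reads(reads, toy_graph, toy_index, no_rc_params)
        assert summary.n_reads == 3
        assert summary.n_mapped_path == 2
        assert summary.n_mapped_unitig == 1
        assert summary.n_mapped == 3

    def test_empty_read_set(self, toy_graph, toy_index, no_rc_params):
        mappings, summary = map_reads([], toy_graph, toy_index, no_rc_params)
        assert mappings == [] and summary.n_reads == 0

    def test_error_free_reads_all_map(self):
        genome = random_genome(5000, 11)
        g = build_cdbg({genome[i : i + 9] for i in range(len(genome) - 8)}, 9)
        index = build_overlap_index(g)
        sims = simulate_reads(genome, 300, 60, 0.0, 12)
        params = MappingParams(try_reverse_complement=False)
        mappings, summary = map_reads([s.record for s in sims], g, index, params)
        assert summary.n_mapped == 300
        for m, s in zip(mappings, sims):
            check_mapping(m, s.record.seq, g)


class TestProperties:
    @pytest.mark.parametrize("seed", range(15))
    def test_soundness_and_step_bound(self, seed):
        rng = np.random.default_rng(seed)
        genome, g = random_kmer_graph(rng, 5, 800)
        index = build_overlap_index(g)
        sims = simulate_reads(genome, 60, 40, 0.01, seed)
        stats = StepStats()
        params = MappingParams(try_reverse_complement=False)
        mappings, _ = map_reads([s.record for s in sims], g, index, params, stats=stats)
        for m, s in zip(mappings, sims):
            check_mapping(m, s.record.seq, g)
            if m.status is Status.MAPPED_PATH:
                for a, b in zip(m.walk, m.walk[1:]):
                    assert g.adjacent(a, b)
        assert stats.max_candidates <= 4

    @pytest.mark.parametrize("seed", range(10))
    def test_exhaustive_dominates_greedy(self, seed):
        rng = np.random.default_rng(100 + seed)
        genome, g = random_kmer_graph(rng, 5, 500)
        index = build_overlap_index(g)
        sims = simulate_reads(genome, 40, 35, 0.03, seed)
        params = MappingParams(try_reverse_complement=False)
        for s in sims:
            greedy = map_read_greedy(s.record.id, s.record.seq, g, index, params)
            exh = map_read_exhaustive(s.record.id, s.record.seq, g, index, params)
            if greedy.mapped:
                assert exh.mapped
                assert exh.mismatches <= greedy.mismatches

    @pytest.mark.parametrize("seed", range(6))
    def test_budget_monotonicity(self, seed):
        rng = np.random.default_rng(300 + seed)
        genome, g = random_kmer_graph(rng, 5, 600)
        index = build_overlap_index(g)
        sims = simulate_reads(genome, 50, 40, 0.05, seed)
        counts = []
        for t in (0, 1, 2, 3):
            params = MappingParams(max_mismatches=t, try_reverse_complement=False)
            _, summary = map_reads([s.record for s in sims], g, index, params)
            counts.append(summary.n_mapped)
        assert counts == sorted(counts)
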