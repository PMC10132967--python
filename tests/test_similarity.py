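"""Similarity score, breakpoint matching, empirical p-values, clonal pairs."""

import numpy as np
import pytest

from focalamp.classify import AmpliconClass, ClassifiedAmplicon, classify_amplicon
from focalamp.cohort import CohortSample
from focalamp.graphio import (
    AmpliconGraph,
    Breakend,
    BreakpointEdge,
    Cycle,
    Decomposition,
    GraphSegment,
)
from focalamp.intervals import GenomicInterval
from focalamp.similarity import (
    SimilarityResult,
    find_clonal_pairs,
    match_breakpoints,
    similarity_p_value,
    similarity_score,
)
from focalamp.simulate import simulate_structure


def edge(c1, p1, s1, c2, p2, s2):
    return BreakpointEdge(Breakend(c1, p1, s1), Breakend(c2, p2, s2),
                          kind="discordant")


def _amplicon(amp_id, intervals, edges, weight=20.0, sample_id="s"):
    segs = [GraphSegment(iv, weight) for iv in intervals]
    graph = AmpliconGraph(amp_id, segs, list(edges), sample_id)
    decomp = Decomposition(
        amp_id,
        {i + 1: iv for i, iv in enumerate(intervals)},
        [Cycle([(i + 1, "+") for i in range(len(intervals))], weight, True, 1)],
    )
    return ClassifiedAmplicon(
        graph=graph,
        decomposition=decomp,
        amplicon_class=AmpliconClass.ECDNA,
        amplified_intervals=list(intervals),
        max_copy_number=weight,
        n_ecdna_species=1,
    )


def _max_matching_brute(edges_a, edges_b, tol):
    """Exhaustive maximum bipartite matching size (instances <= 8 edges)."""
    from focalamp.similarity import edges_match

    adj = [
        [j for j, eb in enumerate(edges_b) if edges_match(ea, eb, tol)]
        for ea in edges_a
    ]

    def best(i, used):
        if i == len(adj):
            return 0
        top = best(i + 1, used)
        for j in adj[i]:
            if not used & (1 << j):
                top = max(top, 1 + best(i + 1, used | (1 << j)))
        return top

    return best(0, 0)


class TestMatchBreakpoints:
    def test_identical_lists_fully_match(self):
        edges = [edge("chr1", 1000 * k, "+", "chr2", 500 * k, "-") for k in (1, 2, 3)]
        assert len(match_breakpoints(edges, list(edges), tol=100)) == 3

    def test_tolerance_boundary(self):
        a = [edge("chr1", 1000, "+", "chr1", 9000, "-")]
        b = [edge("chr1", 1150, "+", "chr1", 9150, "-")]
        assert match_breakpoints(a, b, tol=100) == []
        assert len(match_breakpoints(a, b, tol=200)) == 1

    def test_sides_must_agree(self):
        a = [edge("chr1", 1000, "+", "chr1", 9000, "-")]
        b = [edge("chr1", 1000, "-", "chr1", 9000, "+")]
        assert match_breakpoints(a, b, tol=100) == []

    def test_each_edge_matched_at_most_once(self):
        a = [edge("chr1", 1000, "+", "chr1", 9000, "-")] * 3
        b = [edge("chr1", 1010, "+", "chr1", 9010, "-")]
        assert len(match_breakpoints(a, b, tol=100)) == 1

    def test_greedy_achieves_exhaustive_optimum(self, rng):
        # clustered coordinates: candidate matches are unambiguous, where the
        # greedy strategy is provably optimal
        for trial in range(30):
            n_a, n_b = int(rng.integers(1, 8)), int(rng.integers(1, 8))

            def mk(n):
                out = []
                for _ in range(n):
                    cl = int(rng.integers(1, 6)) * 100_000
                    off = int(rng.integers(-150, 151))
                    out.append(
                        edge("chr1", cl + off, "+", "chr2", cl + off + 7, "-")
                    )
                return out

            ea, eb = mk(n_a), mk(n_b)
            greedy = len(match_breakpoints(ea, eb, tol=100))
            assert greedy == _max_matching_brute(ea, eb, 100)


class TestScore:
    def test_self_similarity_is_one(self):
        a = _amplicon("a", [GenomicInterval("chr1", 1, 100_000)],
                      [edge("chr1", 1, "-", "chr1", 100_000, "+")])
        r = similarity_score(a, a)
        assert r.score == 1.0
        assert r.genomic_jaccard == 1.0
        assert r.breakpoint_jaccard == 1.0

    def test_disjoint_is_zero(self):
        a = _amplicon("a", [GenomicInterval("chr1", 1, 100_000)], [])
        b = _amplicon("b", [GenomicInterval("chr2", 1, 100_000)], [])
        assert similarity_score(a, b).score == 0.0

    def test_hand_computed_mixed_pair(self):
        # a: 100-kb interval, 2 junctions; b: extended to 150 kb sharing one
        # junction of its two -> genomic 2/3, breakpoint 1/3, score 1/2
        shared = edge("chr1", 1, "-", "chr1", 100_000, "+")
        a = _amplicon(
            "a", [GenomicInterval("chr1", 1, 100_000)],
            [shared, edge("chr1", 40_000, "+", "chr1", 60_000, "-")],
        )
        b = _amplicon(
            "b", [GenomicInterval("chr1", 1, 150_000)],
            [shared, edge("chr1", 120_000, "+", "chr1", 130_000, "-")],
        )
        r = similarity_score(a, b)
        assert r.genomic_jaccard == pytest.approx(100_000 / 150_000)
        assert r.breakpoint_jaccard == pytest.approx(1 / 3)
        assert r.score == pytest.approx(0.5)

    def test_symmetry(self):
        a = _amplicon("a", [GenomicInterval("chr1", 1, 100_000)],
                      [edge("chr1", 1, "-", "chr1", 100_000, "+")])
        b = _amplicon("b", [GenomicInterval("chr1", 50_000, 130_000)], [])
        assert similarity_score(a, b).score == similarity_score(b, a).score

    def test_empty_intervals_error(self):
        a = _amplicon("a", [GenomicInterval("chr1", 1, 100_000)], [])
        a.amplified_intervals = []
        b = _amplicon("b", [GenomicInterval("chr1", 1, 100_000)], [])
        with pytest.raises(ValueError):
            similarity_score(a, b)

    def test_shared_edge_raises_unshared_lowers(self):
        iv = [GenomicInterval("chr1", 1, 100_000)]
        shared = edge("chr1", 1, "-", "chr1", 100_000, "+")
        extra_a = edge("chr1", 30_000, "+", "chr1", 70_000, "-")
        base = similarity_score(_amplicon("a", iv, [shared]),
                                _amplicon("b", iv, [shared])).score
        with_shared = similarity_score(
            _amplicon("a", iv, [shared, extra_a]),
            _amplicon("b", iv, [shared, extra_a]),
        ).score
        with_unshared = similarity_score(
            _amplicon("a", iv, [shared, extra_a]),
            _amplicon("b", iv, [shared]),
        ).score
        assert with_shared >= base
        assert with_unshared <= base


class TestPValue:
    def _pair(self):
        iv = [GenomicInterval("chr1", 1_000_000, 1_100_000)]
        e = [edge("chr1", 1_000_000, "-", "chr1", 1_100_000, "+")]
        return _amplicon("a", iv, e), _amplicon("b", iv, e)

    def test_formula_at_maximal_score(self, genome):
        a, b = self._pair()
        r = similarity_score(a, b)
        assert r.score == 1.0
        r = similarity_p_value(r, a, b, background=[], n_null=999, seed=5,
                               genome=genome)
        assert r.p_value == pytest.approx(1 / 1000)

    def test_zero_score_gives_p_one(self, genome):
        a, _ = self._pair()
        c = _amplicon("c", [GenomicInterval("chr2", 1, 100_000)], [])
        r = similarity_score(a, c)
        assert r.score == 0.0
        r = similarity_p_value(r, a, c, background=[], n_null=200, seed=5,
                               genome=genome)
        assert r.p_value == 1.0

    def test_reproducible_given_seed(self, genome):
        a, b = self._pair()
        ps = []
        for _ in range(2):
            r = similarity_score(a, b)
            r = similarity_p_value(r, a, b, background=[], n_null=300, seed=17,
                                   genome=genome)
            ps.append(r.p_value)
        assert ps[0] == ps[1]

    def test_no_background_and_no_genome_errors(self):
        a, b = self._pair()
        r = similarity_score(a, b)
        with pytest.raises(ValueError):
            similarity_p_value(r, a, b, background=[], n_null=200, seed=0)

    def test_cross_patient_pairs_are_not_significant(self, genome):
        # structurally unrelated amplicons from different patients: the
        # empirical null should not call them similar
        rng = np.random.default_rng(11)
        amps = []
        for i in range(8):
            g, d, _ = simulate_structure(
                genome, "ecDNA", rng, f"p{i}_amp", f"p{i}_s",
                anchor=(f"chr{i % 4 + 1}", 1_500_000 + (i // 4) * 6_000_000),
            )
            amps.append((f"p{i}", classify_amplicon(g, d)))
        n_sig = 0
        for i in range(4):
            a, b = amps[2 * i][1], amps[2 * i + 1][1]
            r = similarity_score(a, b)
            bg = [x for j, x in enumerate(amps) if j not in (2 * i, 2 * i + 1)]
            r = similarity_p_value(r, a, b, bg, n_null=100, seed=i, genome=genome)
            n_sig += r.p_value < 0.05
        assert n_sig == 0


class TestClonalPairs:
    def _sample(self, sid, pid, amp, tp="TP-1"):
        return CohortSample(sample_id=sid, patient_id=pid, group="CO",
                            time_point=tp, level_cm=30.0, amplicons=[amp])

    def test_same_ecdna_in_two_biopsies_is_one_pair(self, genome):
        iv = [GenomicInterval("chr1", 1_000_000, 1_100_000)]
        e = [edge("chr1", 1_000_000, "-", "chr1", 1_100_000, "+")]
        s1 = self._sample("s1", "p1", _amplicon("a1", iv, e, sample_id="s1"))
        s2 = self._sample("s2", "p1", _amplicon("a2", iv, e, sample_id="s2"), tp="TP-2")
        pairs = find_clonal_pairs([s1, s2], n_null=100, seed=3, genome=genome)
        assert len(pairs) == 1
        assert pairs[0].patient_id == "p1"

    def test_unrelated_ecdnas_make_no_pair(self, genome):
        a = _amplicon("a1", [GenomicInterval("chr1", 1, 100_000)], [], sample_id="s1")
        b = _amplicon("a2", [GenomicInterval("chr3", 1, 100_000)], [], sample_id="s2")
        s1 = self._sample("s1", "p1", a)
        s2 = self._sample("s2", "p1", b, tp="TP-2")
        assert find_clonal_pairs([s1, s2], n_null=100, seed=3, genome=genome) == []
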