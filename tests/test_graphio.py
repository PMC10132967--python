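"""Graph/cycles file dialects: parsing, round-trips, amplified intervals."""

import numpy as np
import pytest

from focalamp.graphio import (
    AmpliconGraph,
    Breakend,
    BreakpointEdge,
    GraphParseError,
    GraphSegment,
    amplified_intervals,
    read_cycles_file,
    read_graph_file,
    write_cycles_file,
    write_graph_file,
)
from focalamp.intervals import GenomicInterval
from focalamp.simulate import simulate_structure


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestGraphParsing:
    def test_single_sequence_record(self, tmp_path):
        p = _write(tmp_path, "a_graph.txt",
                   "sequence\tchr1:10001-\tchr1:20000+\t8.0\n")
        g = read_graph_file(p)
        assert len(g.segments) == 1
        assert g.segments[0].interval.length == 10000
        assert g.segments[0].copy_count == 8.0
        assert g.edges == []

    def test_end_before_start_is_parse_error(self, tmp_path):
        p = _write(tmp_path, "bad_graph.txt",
                   "sequence\tchr1:20000-\tchr1:10001+\t8.0\n")
        with pytest.raises(GraphParseError, match="line 1"):
            read_graph_file(p)

    def test_negative_copy_count_is_parse_error(self, tmp_path):
        p = _write(tmp_path, "neg_graph.txt",
                   "sequence\tchr1:1-\tchr1:100+\t-3\n")
        with pytest.raises(GraphParseError, match="line 1"):
            read_graph_file(p)

    def test_empty_file_is_error(self, tmp_path):
        p = _write(tmp_path, "empty_graph.txt", "")
        with pytest.raises(GraphParseError, match="empty"):
            read_graph_file(p)

    def test_unknown_record_type_warns_and_skips(self, tmp_path, caplog):
        p = _write(
            tmp_path, "odd_graph.txt",
            "sequence\tchr1:1-\tchr1:1000+\t6.0\n"
            "weird\tstuff\n",
        )
        with caplog.at_level("WARNING"):
            g = read_graph_file(p)
        assert len(g.segments) == 1
        assert "weird" in caplog.text

    def test_three_segments_one_edge_round_trip(self, tmp_path):
        text = (
            "sequence\tchr1:1000-\tchr1:2000+\t8\n"
            "sequence\tchr1:5000-\tchr1:6000+\t8\n"
            "sequence\tchr2:100-\tchr2:900+\t7\n"
            "discordant\tchr2:900+->chr1:1000-\t7.5\t21\n"
        )
        p = _write(tmp_path, "t_graph.txt", text)
        g = read_graph_file(p)
        assert len(g.segments) == 3
        assert len(g.discordant_edges) == 1
        out = tmp_path / "t2_graph.txt"
        write_graph_file(g, out)
        g2 = read_graph_file(out, amplicon_id=g.amplicon_id)
        assert g2.segments == sorted(
            g.segments, key=lambda s: (s.interval.chrom, s.interval.start)
        )
        assert g2.edges == g.edges


class TestCyclesParsing:
    def test_minimal_cyclic_walk(self, tmp_path):
        p = _write(
            tmp_path, "a_cycles.txt",
            "Segment\t1\tchr1\t100\t200\n"
            "Segment\t2\tchr1\t300\t400\n"
            "Cycle=1;Copy_count=12.0;Segments=1+,2+\n",
        )
        d = read_cycles_file(p)
        assert len(d.cycles) == 1
        assert d.cycles[0].weight == 12.0
        assert d.cycles[0].is_cyclic

    def test_sentinel_marks_linear_walk(self, tmp_path):
        p = _write(
            tmp_path, "b_cycles.txt",
            "Segment\t1\tchr1\t100\t200\n"
            "Segment\t2\tchr1\t300\t400\n"
            "Cycle=1;Copy_count=3.0;Segments=0+,1+,2-,0-\n",
        )
        d = read_cycles_file(p)
        assert not d.cycles[0].is_cyclic
        assert d.cycles[0].signed_segments == [(1, "+"), (2, "-")]

    def test_undefined_segment_is_error(self, tmp_path):
        p = _write(
            tmp_path, "c_cycles.txt",
            "Segment\t1\tchr1\t100\t200\n"
            "Cycle=1;Copy_count=3.0;Segments=1+,3+\n",
        )
        with pytest.raises(GraphParseError, match="undefined segment 3"):
            read_cycles_file(p)

    def test_duplicate_segment_id_is_error(self, tmp_path):
        p = _write(
            tmp_path, "d_cycles.txt",
            "Segment\t1\tchr1\t100\t200\nSegment\t1\tchr1\t300\t400\n",
        )
        with pytest.raises(GraphParseError, match="duplicate"):
            read_cycles_file(p)


class TestWriterReaderClosure:
    @pytest.mark.parametrize("kind", ["ecDNA", "BFB", "complex_non_cyclic", "linear"])
    def test_generated_structures_round_trip(self, tmp_path, genome, kind):
        rng = np.random.default_rng(7)
        for i in range(5):
            g, d, _ = simulate_structure(genome, kind, rng, f"a{i}", "s")
            gp, cp = tmp_path / f"{kind}{i}_graph.txt", tmp_path / f"{kind}{i}_cycles.txt"
            write_graph_file(g, gp)
            write_cycles_file(d, cp)
            g2 = read_graph_file(gp, amplicon_id=g.amplicon_id)
            d2 = read_cycles_file(cp, amplicon_id=d.amplicon_id)
            assert sorted(g2.segments, key=lambda s: (s.interval.chrom, s.interval.start)) \
                == sorted(g.segments, key=lambda s: (s.interval.chrom, s.interval.start))
            assert sorted(g2.edges, key=repr) == sorted(g.edges, key=repr)
            assert d2.segments == d.segments
            assert sorted((c.weight, c.is_cyclic, c.signed_segments) for c in d2.cycles) \
                == sorted((c.weight, c.is_cyclic, c.signed_segments) for c in d.cycles)


class TestEdgeSymmetry:
    def test_endpoint_swap_is_same_edge(self):
        a = BreakpointEdge(Breakend("chr1", 100, "+"), Breakend("chr2", 50, "-"),
                           kind="discordant")
        b = BreakpointEdge(Breakend("chr2", 50, "-"), Breakend("chr1", 100, "+"),
                           kind="discordant")
        assert a == b
        assert hash(a) == hash(b)

    def test_concordant_requires_adjacency(self):
        with pytest.raises(ValueError):
            BreakpointEdge(Breakend("chr1", 100, "+"), Breakend("chr1", 300, "-"),
                           kind="concordant")


class TestAmplifiedIntervals:
    def _graph(self, cns):
        segs = [
            GraphSegment(GenomicInterval("chr1", 1 + i * 20000, (i + 1) * 20000), cn)
            for i, cn in enumerate(cns)
        ]
        return AmpliconGraph("a", segs, [])

    def test_threshold_filters_segments(self):
        g = self._graph([8.0, 3.0, 6.0])
        ivs = amplified_intervals(g, 4.5)
        assert ivs == [
            GenomicInterval("chr1", 1, 20000),
            GenomicInterval("chr1", 40001, 60000),
        ]

    def test_abutting_segments_merge(self):
        g = self._graph([8.0, 6.0])
        assert amplified_intervals(g, 0.1) == [GenomicInterval("chr1", 1, 40000)]

    def test_random_graph_matches_per_base_oracle(self, rng):
        segs = []
        pos = 1
        for _ in range(50):
            length = int(rng.integers(100, 2000))
            gap = int(rng.integers(0, 3))
            segs.append(
                GraphSegment(
                    GenomicInterval("chr1", pos + gap, pos + gap + length - 1),
                    float(rng.uniform(0, 12)),
                )
            )
            pos += gap + length
        g = AmpliconGraph("a", segs, [])
        for thr in (2.0, 4.5, 8.0):
            got = amplified_intervals(g, thr)
            expected_bases = set()
            for s in segs:
                if s.copy_count >= thr:
                    expected_bases.update(
                        range(s.interval.start, s.interval.end + 1)
                    )
            got_bases = set()
            for iv in got:
                got_bases.update(range(iv.start, iv.end + 1))
            # merging abutting intervals never covers new bases
            assert got_bases == expected_bases

    def test_total_length_monotone_in_threshold(self, rng):
        g = self._graph(list(rng.uniform(0, 12, size=20)))
        lengths = [
            sum(iv.length for iv in amplified_intervals(g, thr))
            for thr in (0.5, 2.0, 4.5, 7.0, 10.0)
        ]
        assert lengths == sorted(lengths, reverse=True)
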