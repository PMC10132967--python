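"""Breakpoint graphs, cycle decompositions, and their file dialects.

A focal amplification ("amplicon") is described by two text files emitted by a
breakpoint-graph builder:

* a **graph file** listing amplified reference segments with copy counts, plus
  concordant (reference-adjacent) and discordant (rearrangement) junction edges;
* a **cycles file** listing a weighted decomposition of the graph into cyclic
  and linear walks — the candidate amplicon structures.

Both dialects use 1-based inclusive coordinates.  Junction endpoint direction
``+`` means the junction attaches to the *head* (right end, increasing
coordinate) of the incoming sequence, ``-`` to the *tail* (left end).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from .intervals import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

HEAD = "+"
TAIL = "-"

LINEAR_SENTINEL = 0  # segment id 0 marks the open ends of a linear walk


class GraphParseError(ValueError):
    """Malformed graph or cycles file; message carries the line number."""


@dataclass(frozen=True)
class GraphSegment:
    """An amplified reference segment with its estimated copy count."""

    interval: GenomicInterval
    copy_count: float
    coverage: float | None = None

    def __post_init__(self) -> None:
        if self.copy_count < 0:
            raise ValueError(f"negative copy count {self.copy_count}")
        if self.coverage is not None and self.coverage < 0:
            raise ValueError(f"negative coverage {self.coverage}")


@dataclass(frozen=True)
class Breakend:
    """One oriented endpoint of a junction edge."""

    chrom: str
    pos: int
    side: str  # HEAD ('+') or TAIL ('-')

    def __post_init__(self) -> None:
        if self.side not in (HEAD, TAIL):
            raise ValueError(f"side must be '+' or '-', got {self.side!r}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}{self.side}"


def _breakend_key(b: Breakend) -> tuple:
    return (b.chrom, b.pos, b.side)


@dataclass(frozen=True)
class BreakpointEdge:
    """An unordered junction between two oriented genomic positions.

    Equality and hashing are symmetric under endpoint swap: the edge is stored
    with endpoints in canonical (coordinate-sorted) order.
    """

    left: Breakend
    right: Breakend
    kind: str  # 'concordant' | 'discordant'
    copy_count: float = 0.0
    support: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("concordant", "discordant"):
            raise ValueError(f"unknown edge kind {self.kind!r}")
        if self.copy_count < 0:
            raise ValueError(f"negative copy count {self.copy_count}")
        if self.support < 0:
            raise ValueError(f"negative read support {self.support}")
        if _breakend_key(self.left) > _breakend_key(self.right):
            lo, hi = self.right, self.left
            object.__setattr__(self, "left", lo)
            object.__setattr__(self, "right", hi)
        if self.kind == "concordant":
            if self.left.chrom != self.right.chrom:
                raise ValueError("concordant edge spans two chromosomes")
            if abs(self.left.pos - self.right.pos) > 1:
                raise ValueError(
                    "concordant edge endpoints not reference-adjacent: "
                    f"{self.left} -> {self.right}"
                )

    @property
    def is_foldback_shaped(self) -> bool:
        """Same chromosome, same side (head-head or tail-tail): inverted."""
        return (
            self.left.chrom == self.right.chrom and self.left.side == self.right.side
        )

    def span(self) -> int:
        """Genomic distance between endpoints (same-chromosome edges only)."""
        if self.left.chrom != self.right.chrom:
            raise ValueError("span undefined for interchromosomal edge")
        return abs(self.right.pos - self.left.pos)


@dataclass
class AmpliconGraph:
    """Segments plus junction edges for one focal amplification."""

    amplicon_id: str
    segments: list[GraphSegment] = field(default_factory=list)
    edges: list[BreakpointEdge] = field(default_factory=list)
    sample_id: str = ""

    def validate(self, boundary_tol: int = 1) -> None:
        """Check segment disjointness and discordant-endpoint anchoring."""
        ivs = sorted(
            (s.interval for s in self.segments), key=lambda i: (i.chrom, i.start)
        )
        for a, b in zip(ivs, ivs[1:]):
            if a.overlaps(b):
                raise ValueError(f"overlapping segments {a} and {b}")
        boundaries: set[tuple[str, int]] = set()
        for s in self.segments:
            boundaries.add((s.interval.chrom, s.interval.start))
            boundaries.add((s.interval.chrom, s.interval.end))
        for e in self.edges:
            if e.kind != "discordant":
                continue
            for end in (e.left, e.right):
                if not any(
                    end.chrom == c and abs(end.pos - p) <= boundary_tol
                    for c, p in boundaries
                ):
                    raise ValueError(
                        f"discordant endpoint {end} not on a segment boundary"
                    )

    @property
    def discordant_edges(self) -> list[BreakpointEdge]:
        return [e for e in self.edges if e.kind == "discordant"]

    def max_copy_number(self) -> float:
        return max((s.copy_count for s in self.segments), default=0.0)


@dataclass
class Cycle:
    """One weighted walk of a decomposition.

    signed_segments lists (segment id, orientation) steps with the linear-walk
    sentinels already stripped; is_cyclic records whether the walk closes.
    """

    signed_segments: list[tuple[int, str]]
    weight: float
    is_cyclic: bool = True
    cycle_id: int = 0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"negative cycle weight {self.weight}")


@dataclass
class Decomposition:
    """A weighted set of candidate structures over a segment table."""

    amplicon_id: str
    segments: dict[int, GenomicInterval] = field(default_factory=dict)
    cycles: list[Cycle] = field(default_factory=list)

    def validate(self) -> None:
        for cyc in self.cycles:
            for seg_id, _ in cyc.signed_segments:
                if seg_id not in self.segments:
                    raise ValueError(
                        f"cycle {cyc.cycle_id} references undefined segment {seg_id}"
                    )

    def cycle_intervals(self, cyc: Cycle) -> list[GenomicInterval]:
        """Merged genomic footprint of one walk."""
        return merge_intervals(
            [self.segments[sid] for sid, _ in cyc.signed_segments], gap=0
        )

    def cyclic_walks(self) -> list[Cycle]:
        return [c for c in self.cycles if c.is_cyclic]


# ---------------------------------------------------------------------------
# graph file dialect


_POSITION_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<pos>\d+)(?P<dir>[+-])$")
_EDGE_RE = re.compile(
    r"^(?P<c1>[\w.]+):(?P<p1>\d+)(?P<d1>[+-])->(?P<c2>[\w.]+):(?P<p2>\d+)(?P<d2>[+-])$"
)


def _parse_position(token: str, lineno: int) -> tuple[str, int, str]:
    m = _POSITION_RE.match(token)
    if not m:
        raise GraphParseError(f"line {lineno}: malformed coordinate {token!r}")
    return m.group("chrom"), int(m.group("pos")), m.group("dir")


def _parse_float(token: str, lineno: int, what: str) -> float:
    try:
        value = float(token)
    except ValueError:
        raise GraphParseError(f"line {lineno}: malformed {what} {token!r}") from None
    if value < 0:
        raise GraphParseError(f"line {lineno}: negative {what} {token!r}")
    return value


def read_graph_file(path: str | Path, amplicon_id: str | None = None,
                    sample_id: str = "") -> AmpliconGraph:
    """Parse a graph file into a validated :class:`AmpliconGraph`.

    Unknown record types are skipped with a logged warning; an empty file (no
    sequence records) raises :class:`GraphParseError`.
    """
    path = Path(path)
    if amplicon_id is None:
        amplicon_id = path.stem.replace("_graph", "")
    segments: list[GraphSegment] = []
    edges: list[BreakpointEdge] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "sequence":
                if len(fields) < 4:
                    raise GraphParseError(
                        f"line {lineno}: sequence record needs 4 fields"
                    )
                c1, p1, _ = _parse_position(fields[1], lineno)
                c2, p2, _ = _parse_position(fields[2], lineno)
                if c1 != c2:
                    raise GraphParseError(
                        f"line {lineno}: sequence spans chromosomes {c1}/{c2}"
                    )
                if p2 < p1:
                    raise GraphParseError(
                        f"line {lineno}: sequence end {p2} < start {p1}"
                    )
                cn = _parse_float(fields[3], lineno, "copy count")
                cov = (
                    _parse_float(fields[4], lineno, "coverage")
                    if len(fields) > 4 and fields[4] not in ("", "NA")
                    else None
                )
                segments.append(
                    GraphSegment(GenomicInterval(c1, p1, p2), cn, cov)
                )
            elif kind in ("concordant", "discordant"):
                if len(fields) < 2:
                    raise GraphParseError(f"line {lineno}: truncated edge record")
                m = _EDGE_RE.match(fields[1])
                if not m:
                    raise GraphParseError(
                        f"line {lineno}: malformed edge {fields[1]!r}"
                    )
                cn = _parse_float(fields[2], lineno, "copy count") if len(fields) > 2 else 0.0
                support = int(fields[3]) if len(fields) > 3 else 0
                try:
                    edges.append(
                        BreakpointEdge(
                            Breakend(m.group("c1"), int(m.group("p1")), m.group("d1")),
                            Breakend(m.group("c2"), int(m.group("p2")), m.group("d2")),
                            kind=kind,
                            copy_count=cn,
                            support=support,
                        )
                    )
                except ValueError as exc:
                    raise GraphParseError(f"line {lineno}: {exc}") from None
            elif kind.endswith(":") or kind in ("SequenceEdge", "BreakpointEdge"):
                continue  # header line
            else:
                logger.warning("%s line %d: skipping unknown record type %r",
                               path.name, lineno, kind)
    if not segments:
        raise GraphParseError(f"{path}: no sequence records (empty graph)")
    graph = AmpliconGraph(amplicon_id, segments, edges, sample_id)
    graph.validate()
    return graph


def write_graph_file(graph: AmpliconGraph, path: str | Path) -> None:
    """Emit the graph dialect with deterministic record ordering."""
    def seg_key(s: GraphSegment):
        return (s.interval.chrom, s.interval.start, s.interval.end)

    def edge_key(e: BreakpointEdge):
        return (e.kind, _breakend_key(e.left), _breakend_key(e.right))

    with open(path, "w") as fh:
        fh.write("SequenceEdge:\tStartPosition\tEndPosition\tPredictedCopyCount"
                 "\tAverageCoverage\tSize\n")
        for s in sorted(graph.segments, key=seg_key):
            iv = s.interval
            cov = f"{s.coverage:g}" if s.coverage is not None else "NA"
            fh.write(
                f"sequence\t{iv.chrom}:{iv.start}-\t{iv.chrom}:{iv.end}+"
                f"\t{s.copy_count:g}\t{cov}\t{iv.length}\n"
            )
        fh.write("BreakpointEdge:\tStartPosition->EndPosition\tPredictedCopyCount"
                 "\tNumberOfReadPairs\n")
        for e in sorted(graph.edges, key=edge_key):
            fh.write(
                f"{e.kind}\t{e.left}->{e.right}\t{e.copy_count:g}\t{e.support}\n"
            )


# ---------------------------------------------------------------------------
# cycles file dialect


def read_cycles_file(path: str | Path, amplicon_id: str | None = None) -> Decomposition:
    """Parse a cycles file into a validated :class:`Decomposition`.

    Walks whose segment list carries the ``0`` sentinel are linear
    (is_cyclic=False); all others are cyclic.
    """
    path = Path(path)
    if amplicon_id is None:
        amplicon_id = path.stem.replace("_cycles", "")
    segments: dict[int, GenomicInterval] = {}
    cycles: list[Cycle] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("Interval"):
                continue  # seed-interval bookkeeping, not contracted
            if line.startswith("Segment"):
                fields = line.split()
                if len(fields) != 5:
                    raise GraphParseError(f"line {lineno}: malformed Segment record")
                seg_id = int(fields[1])
                if seg_id in segments:
                    raise GraphParseError(
                        f"line {lineno}: duplicate segment id {seg_id}"
                    )
                try:
                    segments[seg_id] = GenomicInterval(
                        fields[2], int(fields[3]), int(fields[4])
                    )
                except ValueError as exc:
                    raise GraphParseError(f"line {lineno}: {exc}") from None
            elif line.startswith("Cycle="):
                attrs = dict(part.split("=", 1) for part in line.split(";"))
                try:
                    cycle_id = int(attrs["Cycle"])
                    weight = float(attrs["Copy_count"])
                    steps_raw = attrs["Segments"].split(",")
                except (KeyError, ValueError):
                    raise GraphParseError(
                        f"line {lineno}: malformed Cycle record"
                    ) from None
                steps: list[tuple[int, str]] = []
                n_sentinels = 0
                for tok in steps_raw:
                    m = re.match(r"^(\d+)([+-])$", tok.strip())
                    if not m:
                        raise GraphParseError(
                            f"line {lineno}: malformed cycle step {tok!r}"
                        )
                    seg_id = int(m.group(1))
                    if seg_id == LINEAR_SENTINEL:
                        n_sentinels += 1
                        continue
                    if seg_id not in segments:
                        raise GraphParseError(
                            f"line {lineno}: cycle references undefined segment {seg_id}"
                        )
                    steps.append((seg_id, m.group(2)))
                if weight < 0:
                    raise GraphParseError(f"line {lineno}: negative cycle weight")
                cycles.append(
                    Cycle(steps, weight, is_cyclic=n_sentinels == 0, cycle_id=cycle_id)
                )
            else:
                logger.warning("%s line %d: skipping unknown record %r",
                               path.name, lineno, line.split()[0])
    decomp = Decomposition(amplicon_id, segments, cycles)
    decomp.validate()
    return decomp


def write_cycles_file(decomp: Decomposition, path: str | Path) -> None:
    """Emit the cycles dialect: segments by coordinate, cycles by falling weight."""
    seg_items = sorted(
        decomp.segments.items(), key=lambda kv: (kv[1].chrom, kv[1].start, kv[0])
    )
    with open(path, "w") as fh:
        for seg_id, iv in seg_items:
            fh.write(f"Segment\t{seg_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")
        ordered = sorted(
            decomp.cycles, key=lambda c: (-c.weight, c.cycle_id)
        )
        for out_id, cyc in enumerate(ordered, start=1):
            steps = [f"{sid}{sign}" for sid, sign in cyc.signed_segments]
            if not cyc.is_cyclic:
                steps = ["0+"] + steps + ["0-"]
            fh.write(
                f"Cycle={out_id};Copy_count={cyc.weight:g};Segments={','.join(steps)}\n"
            )


# ---------------------------------------------------------------------------


def amplified_intervals(
    graph: AmpliconGraph, cn_threshold: float = 4.5
) -> list[GenomicInterval]:
    """Merged, sorted footprint of segments at or above cn_threshold copies.

    Abutting intervals (gap <= 1 bp) are merged.  Total length is monotone
    non-increasing in cn_threshold.
    """
    if cn_threshold <= 0:
        raise ValueError("cn_threshold must be positive")
    kept = [s.interval for s in graph.segments if s.copy_count >= cn_threshold]
    return merge_intervals(kept, gap=1)
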