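"""Focal-amplification classification.

Each amplicon (breakpoint graph + cycle decomposition) is assigned one of four
classes by a decision cascade:

1. **ecDNA** — a cyclic walk at amplified copy number explains the amplified
   content (a circular structure at amplified copy number being the operative
   signature of extrachromosomal DNA);
2. **BFB** — no qualifying cycle, but foldback (inverted, near-coincident)
   junctions carry a substantial share of the discordant edge weight, the
   signature of breakage-fusion-bridge cycles;
3. **complex non-cyclic** — neither, but several discordant edges touch the
   amplified region;
4. **linear** — everything else that passed seeding.

Thresholds are config-exposed on :class:`ClassifierParams`; the defaults are
this package's convention, validated against synthetic ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from .graphio import AmpliconGraph, BreakpointEdge, Decomposition
from .intervals import (
    GenomicInterval,
    intersect_length,
    interval_sets_overlap,
    total_length,
)


class AmpliconClass(Enum):
    """Amplification class, ordered by reporting priority (ecDNA highest)."""

    ECDNA = ("ecDNA", 1)
    BFB = ("BFB", 2)
    COMPLEX = ("complex_non_cyclic", 3)
    LINEAR = ("linear", 4)

    def __init__(self, label: str, rank: int) -> None:
        self.label = label
        self.rank = rank

    @classmethod
    def from_label(cls, label: str) -> "AmpliconClass":
        for member in cls:
            if member.label == label:
                return member
        raise ValueError(f"unknown amplicon class {label!r}")


@dataclass(frozen=True)
class ClassifierParams:
    cn_min: float = 4.5                  # amplified copy-number threshold
    ecdna_cycle_weight_min: float = 0.5  # fraction of amplified bases a cycle must cover
    foldback_frac_min: float = 0.25      # fraction of discordant weight on foldbacks
    foldback_dist_max: int = 25_000      # bp between foldback endpoints
    complex_edge_min: int = 3            # discordant edges for complex non-cyclic

    def __post_init__(self) -> None:
        for name in ("ecdna_cycle_weight_min", "foldback_frac_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class ClassifiedAmplicon:
    graph: AmpliconGraph
    decomposition: Decomposition
    amplicon_class: AmpliconClass
    amplified_intervals: list[GenomicInterval]
    max_copy_number: float
    n_ecdna_species: int = 0
    complexity_bits: float | None = None

    @property
    def amplicon_id(self) -> str:
        return self.graph.amplicon_id

    @property
    def sample_id(self) -> str:
        return self.graph.sample_id

    def amplified_length(self) -> int:
        return total_length(self.amplified_intervals)


def detect_foldbacks(graph: AmpliconGraph, dist_max: int = 25_000) -> list[BreakpointEdge]:
    """Discordant edges that are inverted (head-head or tail-tail), intra-
    chromosomal, and whose endpoints lie within dist_max bp of each other."""
    return [
        e
        for e in graph.discordant_edges
        if e.is_foldback_shaped and e.span() <= dist_max
    ]


def _qualifying_cycles(
    decomp: Decomposition,
    amplified: list[GenomicInterval],
    params: ClassifierParams,
) -> list:
    """Cyclic walks at amplified weight covering enough of the amplified bases."""
    amp_len = total_length(amplified)
    out = []
    for cyc in decomp.cyclic_walks():
        if cyc.weight < params.cn_min or not cyc.signed_segments:
            continue
        footprint = decomp.cycle_intervals(cyc)
        covered = intersect_length(footprint, amplified)
        if amp_len and covered / amp_len >= params.ecdna_cycle_weight_min:
            out.append(cyc)
    return out


def _count_species(decomp: Decomposition, cycles: list) -> int:
    """Connected clusters of qualifying cyclic walks; clusters are joined when
    their genomic footprints share any base."""
    if not cycles:
        return 0
    footprints = [decomp.cycle_intervals(c) for c in cycles]
    parent = list(range(len(cycles)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(cycles)):
        for j in range(i + 1, len(cycles)):
            if interval_sets_overlap(footprints[i], footprints[j]):
                parent[find(i)] = find(j)
    return len({find(i) for i in range(len(cycles))})


def classify_amplicon(
    graph: AmpliconGraph,
    decomp: Decomposition,
    params: ClassifierParams = ClassifierParams(),
) -> ClassifiedAmplicon:
    """Run the decision cascade on one amplicon.

    graph and decomp must describe the same amplicon (matching ids).
    """
    if graph.amplicon_id != decomp.amplicon_id:
        raise ValueError(
            f"amplicon id mismatch: graph {graph.amplicon_id!r} "
            f"vs decomposition {decomp.amplicon_id!r}"
        )
    from .graphio import amplified_intervals as _amplified

    amplified = _amplified(graph, params.cn_min)
    max_cn = max(
        (
            s.copy_count
            for s in graph.segments
            if any(s.interval.overlaps(iv) for iv in amplified)
        ),
        default=graph.max_copy_number(),
    )

    label = AmpliconClass.LINEAR
    n_species = 0

    qualifying = _qualifying_cycles(decomp, amplified, params)
    cyclic_on_amp = [
        c
        for c in decomp.cyclic_walks()
        if c.signed_segments
        and interval_sets_overlap(decomp.cycle_intervals(c), amplified)
    ]
    aggregate_cyclic_weight = sum(c.weight for c in cyclic_on_amp)

    if qualifying or (cyclic_on_amp and aggregate_cyclic_weight >= params.cn_min):
        label = AmpliconClass.ECDNA
        n_species = _count_species(decomp, qualifying or cyclic_on_amp)
    else:
        foldbacks = detect_foldbacks(graph, params.foldback_dist_max)
        disc = graph.discordant_edges
        total_w = sum(e.copy_count for e in disc)
        if total_w > 0:
            fb_frac = sum(e.copy_count for e in foldbacks) / total_w
        else:
            fb_frac = len(foldbacks) / len(disc) if disc else 0.0
        if len(foldbacks) >= 2 and fb_frac >= params.foldback_frac_min:
            label = AmpliconClass.BFB
        else:
            touching = [
                e
                for e in disc
                if any(
                    iv.contains(end.chrom, end.pos) or
                    (end.chrom == iv.chrom and abs(end.pos - iv.start) <= 1) or
                    (end.chrom == iv.chrom and abs(end.pos - iv.end) <= 1)
                    for end in (e.left, e.right)
                    for iv in amplified
                )
            ]
            if len(touching) >= params.complex_edge_min:
                label = AmpliconClass.COMPLEX

    return ClassifiedAmplicon(
        graph=graph,
        decomposition=decomp,
        amplicon_class=label,
        amplified_intervals=amplified,
        max_copy_number=max_cn,
        n_ecdna_species=n_species,
    )


def deduplicate_amplicons(
    amplicons: Iterable[ClassifiedAmplicon],
) -> list[ClassifiedAmplicon]:
    """Keep one amplicon per overlap-connected component of amplified regions.

    Within a component: best (lowest) class rank wins; ties broken by largest
    total amplified length, then lexicographic amplicon id.  Idempotent and
    invariant to input order.
    """
    amps = sorted(amplicons, key=lambda a: a.amplicon_id)
    n = len(amps)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if interval_sets_overlap(
                amps[i].amplified_intervals, amps[j].amplified_intervals
            ):
                parent[find(i)] = find(j)

    groups: dict[int, list[ClassifiedAmplicon]] = {}
    for i, amp in enumerate(amps):
        groups.setdefault(find(i), []).append(amp)

    winners = [
        min(
            group,
            key=lambda a: (
                a.amplicon_class.rank,
                -a.amplified_length(),
                a.amplicon_id,
            ),
        )
        for group in groups.values()
    ]
    return sorted(winners, key=lambda a: a.amplicon_id)


def sample_ecdna_status(
    amplicons: Iterable[ClassifiedAmplicon],
) -> tuple[bool, int]:
    """(any ecDNA present, total distinct ecDNA species) for one deduplicated
    sample."""
    amps = list(amplicons)
    positive = any(a.amplicon_class is AmpliconClass.ECDNA for a in amps)
    n_species = sum(a.n_ecdna_species for a in amps)
    return positive, n_species
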