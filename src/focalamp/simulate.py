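"""Synthetic cohort generator.

Builds complete, self-contained toy cohorts — a small genome, focal
amplifications of each class, longitudinal clonal ecDNA, copy-number segment
tables, breakpoint-graph/cycles files, cohort metadata and histology — plus a
ground-truth table, so the whole pipeline is testable without access-controlled
patient data.

Two presets mirror the study designs this package analyses:

* :func:`fhcc_config` — a prospective case-control cohort: 40 cancer-outcome
  (CO) and 40 non-cancer-outcome (NCO) patients, two sequencing biopsies at
  each of two time points, independently collected histology at matched
  oesophageal levels, clonal ecDNA lineages evolving between time points;
* :func:`cambridge_config` — a cross-sectional surveillance cohort: NDBE/LGD,
  HGD, early-stage-EAC and late-stage-EAC patient groups with one biopsy each.

Positive patients per group are allocated deterministically (round(n * p));
stochastic choices (structure geometry, copy numbers, histology shuffling) are
driven by a single master seed with per-entity sub-seeds derived by stable
label hashing, so a fixed seed yields byte-identical output trees.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .classify import ClassifierParams, ClassifiedAmplicon, classify_amplicon, \
    deduplicate_amplicons
from .cohort import CohortSample, HistologyGrade
from .genes import GeneModel
from .graphio import (
    AmpliconGraph,
    Breakend,
    BreakpointEdge,
    Cycle,
    Decomposition,
    GraphSegment,
    read_cycles_file,
    read_graph_file,
    write_cycles_file,
    write_graph_file,
)
from .intervals import GenomicInterval
from .stats import pair_histology

# ---------------------------------------------------------------------------
# toy genome and gene models


def make_toy_genome(
    n_chromosomes: int = 4, chrom_length: int = 10_000_000
) -> dict[str, int]:
    return {f"chr{i + 1}": chrom_length for i in range(n_chromosomes)}


def make_toy_genes(genome: dict[str, int]) -> list[GeneModel]:
    """60 evenly spaced 20-kb genes; every fifth is an oncogene, six are
    immunomodulatory."""
    chroms = sorted(genome)
    genes: list[GeneModel] = []
    for i in range(60):
        chrom = chroms[i % len(chroms)]
        start = 200_000 + (i // len(chroms)) * 650_000
        genes.append(
            GeneModel(
                name=f"G{i:03d}",
                interval=GenomicInterval(chrom, start, start + 19_999),
                strand="+" if i % 2 == 0 else "-",
                is_oncogene=i % 5 == 0,
                is_immunomodulatory=i % 10 == 3,
            )
        )
    return genes


def _rng(seed: int, *labels: str) -> np.random.Generator:
    """Sub-seeded generator: stable across processes (no str hash salt)."""
    subs = [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng([seed & 0x7FFFFFFF, *subs])


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GroupSpec:
    """One cohort arm of a generic (cross-sectional) design."""

    n_patients: int
    n_ecdna_patients: int
    grade: HistologyGrade
    extra_amp_prob: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.n_ecdna_patients <= self.n_patients:
            raise ValueError("n_ecdna_patients out of range")
        if not 0.0 <= self.extra_amp_prob <= 1.0:
            raise ValueError("extra_amp_prob must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    design: str = "generic"  # 'generic' | 'fhcc'
    n_chromosomes: int = 4
    chrom_length: int = 10_000_000
    group_specs: dict[str, GroupSpec] = field(default_factory=dict)
    ecdna_cn_median: float = 15.0     # log-normal median of ecDNA copy number
    other_cn_median: float = 8.0      # ... of non-ecDNA amplifications
    cn_sigma: float = 0.4             # log-scale spread of copy numbers
    cn_escalation_factor: float = 1.5  # clonal CN multiplier per grade step
    cn_noise_sigma: float = 0.05      # multiplicative noise on clonal CN
    clonal_pairs: int = 8             # planted within-patient clonal pairs (fhcc)
    extra_amp_prob: float = 0.25      # chance of a non-ecDNA amplicon per sample
    rearrangement_steps_by_grade: dict[str, int] = field(
        default_factory=lambda: {"NDBE": 0, "LGD": 0, "HGD": 1, "EAC": 2}
    )

    def genome(self) -> dict[str, int]:
        return make_toy_genome(self.n_chromosomes, self.chrom_length)


def fhcc_config(seed: int = 0) -> SimConfig:
    return SimConfig(seed=seed, design="fhcc")


def cambridge_config(seed: int = 0) -> SimConfig:
    """Cross-sectional surveillance cohort with the study's group sizes and
    per-group ecDNA-positive patient counts."""
    return SimConfig(
        seed=seed,
        design="generic",
        group_specs={
            "NDBE/LGD": GroupSpec(42, 0, HistologyGrade.LGD),
            "HGD": GroupSpec(25, 1, HistologyGrade.HGD),
            "early EAC": GroupSpec(51, 13, HistologyGrade.EAC),
            "late EAC": GroupSpec(88, 38, HistologyGrade.EAC),
        },
    )


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    amplicon_id: str
    true_class: str
    true_cn: float
    lineage_id: str
    genes_planted: tuple[str, ...]


# ---------------------------------------------------------------------------
# structure simulation


def _sample_segments(
    rng: np.random.Generator,
    genome: dict[str, int],
    anchor: tuple[str, int],
    n: int,
    len_range: tuple[int, int] = (50_000, 400_000),
    window: int = 2_000_000,
) -> list[GenomicInterval]:
    """n non-overlapping segments near an anchor position (same chromosome)."""
    chrom, center = anchor
    limit = genome[chrom]
    placed: list[GenomicInterval] = []
    for _ in range(n):
        for _attempt in range(200):
            length = int(rng.integers(len_range[0], len_range[1] + 1))
            lo = max(1, center - window)
            hi = min(limit - length, center + window)
            if hi <= lo:
                raise ValueError("window too small for segment placement")
            start = int(rng.integers(lo, hi + 1))
            iv = GenomicInterval(chrom, start, start + length - 1)
            if all(
                not iv.overlaps(p) and (
                    p.chrom != iv.chrom or min(abs(iv.start - p.end),
                                               abs(p.start - iv.end)) > 2
                )
                for p in placed
            ):
                placed.append(iv)
                break
        else:
            raise ValueError("segment sampling collision after max retries")
    return sorted(placed, key=lambda i: (i.chrom, i.start))


def _genes_inside(
    segments: Sequence[GraphSegment],
    genes: Sequence[GeneModel],
    cn_min: float = 4.5,
) -> tuple[str, ...]:
    """Genes fully contained in a segment at amplified copy number: these are
    guaranteed callable downstream (intact 5' end, mean CN above threshold)."""
    out = []
    for g in genes:
        gi = g.interval
        if any(
            s.copy_count >= cn_min
            and s.interval.chrom == gi.chrom
            and s.interval.start <= gi.start
            and gi.end <= s.interval.end
            for s in segments
        ):
            out.append(g.name)
    return tuple(sorted(out))


def _draw_cn(rng: np.random.Generator, median: float, sigma: float) -> float:
    return round(max(5.0, median * float(np.exp(rng.normal(0.0, sigma)))), 2)


def simulate_structure(
    genome: dict[str, int],
    kind: str,
    rng: np.random.Generator,
    amplicon_id: str,
    sample_id: str = "",
    cn: float | None = None,
    cn_median: float = 15.0,
    cn_sigma: float = 0.4,
    anchor: tuple[str, int] | None = None,
    genes: Sequence[GeneModel] = (),
    n_segments: int | None = None,
    rearrangement_steps: int = 0,
) -> tuple[AmpliconGraph, Decomposition, TruthRecord]:
    """Generate one focal amplification of the requested class.

    kind is one of 'ecDNA', 'BFB', 'complex_non_cyclic', 'linear'.  The
    structure is anchored near ``anchor`` (random position when omitted) and
    its copy number is drawn log-normally around cn_median unless ``cn`` is
    given.  rearrangement_steps adds low-weight decomposition variants,
    raising structural complexity (ecDNA only).
    """
    if anchor is None:
        chroms = sorted(genome)
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        anchor = (chrom, int(rng.integers(1_500_000, genome[chrom] - 1_500_000)))
    w = cn if cn is not None else _draw_cn(rng, cn_median, cn_sigma)

    if kind == "ecDNA":
        graph, decomp = _make_ecdna(genome, rng, amplicon_id, sample_id, anchor,
                                    w, n_segments, rearrangement_steps)
    elif kind == "BFB":
        graph, decomp = _make_bfb(genome, rng, amplicon_id, sample_id, anchor, w)
    elif kind == "complex_non_cyclic":
        graph, decomp = _make_complex(genome, rng, amplicon_id, sample_id, anchor, w)
    elif kind == "linear":
        graph, decomp = _make_linear(genome, rng, amplicon_id, sample_id, anchor, w)
    else:
        raise ValueError(f"unknown amplicon class {kind!r}")
    graph.validate()
    decomp.validate()
    truth = TruthRecord(
        sample_id=sample_id,
        amplicon_id=amplicon_id,
        true_class=kind,
        true_cn=w,
        lineage_id="",
        genes_planted=_genes_inside(graph.segments, genes),
    )
    return graph, decomp, truth


def _make_ecdna(genome, rng, amplicon_id, sample_id, anchor, w,
                n_segments, rearrangement_steps):
    n = n_segments or int(rng.integers(1, 4))
    # tight window: lineages anchored at different genes stay genomically
    # disjoint, so cross-patient amplicon pairs score zero similarity
    segs = _sample_segments(rng, genome, anchor, n,
                            len_range=(50_000, 250_000), window=600_000)
    segments = [GraphSegment(iv, w, coverage=round(w * 15.0, 1)) for iv in segs]
    edges = []
    for i in range(n):
        a = segs[i]
        b = segs[(i + 1) % n]
        edges.append(
            BreakpointEdge(
                Breakend(a.chrom, a.end, "+"),
                Breakend(b.chrom, b.start, "-"),
                kind="discordant",
                copy_count=w,
                support=int(max(2, round(w * 4))),
            )
        )
    graph = AmpliconGraph(amplicon_id, segments, edges, sample_id)
    seg_table = {i + 1: iv for i, iv in enumerate(segs)}
    cycles = [Cycle([(i + 1, "+") for i in range(n)], w, is_cyclic=True, cycle_id=1)]
    for step in range(rearrangement_steps):
        # lower-weight structural variant: same segments, one dropped if possible
        keep = list(range(1, n + 1))
        if n > 1:
            keep.remove(1 + int(rng.integers(0, n)))
        cycles.append(
            Cycle(
                [(i, "+") for i in keep],
                round(w * 0.3 / (step + 1), 2),
                is_cyclic=True,
                cycle_id=step + 2,
            )
        )
    return graph, Decomposition(amplicon_id, seg_table, cycles)


def _make_bfb(genome, rng, amplicon_id, sample_id, anchor, w):
    chrom, center = anchor
    arm = int(rng.integers(5_000, 15_000))        # terminal foldback arms
    body = int(rng.integers(200_000, 500_000))    # central amplified body
    p = max(1, min(center, genome[chrom] - (2 * arm + body) - 10))
    a = GenomicInterval(chrom, p, p + arm)
    b = GenomicInterval(chrom, p + arm + 1, p + arm + body)
    c = GenomicInterval(chrom, p + arm + body + 1, p + arm + body + 1 + arm)
    ladder = [round(w * 0.55, 2), w, round(w * 0.55, 2)]  # stepwise CN ladder
    segments = [
        GraphSegment(iv, cn, coverage=round(cn * 15.0, 1))
        for iv, cn in zip((a, b, c), ladder)
    ]
    edges = [
        BreakpointEdge(  # tail-tail foldback at the left edge
            Breakend(chrom, a.start, "-"),
            Breakend(chrom, b.start, "-"),
            kind="discordant",
            copy_count=round(w / 2, 2),
            support=int(max(2, round(w * 2))),
        ),
        BreakpointEdge(  # head-head foldback at the right edge
            Breakend(chrom, b.end, "+"),
            Breakend(chrom, c.end, "+"),
            kind="discordant",
            copy_count=round(w / 2, 2),
            support=int(max(2, round(w * 2))),
        ),
    ]
    graph = AmpliconGraph(amplicon_id, segments, edges, sample_id)
    seg_table = {1: a, 2: b, 3: c}
    cycles = [
        Cycle([(1, "+"), (2, "+"), (3, "+")], round(w * 0.6, 2),
              is_cyclic=False, cycle_id=1),
        Cycle([(2, "+")], round(w * 0.4, 2), is_cyclic=False, cycle_id=2),
    ]
    return graph, Decomposition(amplicon_id, seg_table, cycles)


def _make_complex(genome, rng, amplicon_id, sample_id, anchor, w):
    segs = _sample_segments(rng, genome, anchor, 3)
    segments = [GraphSegment(iv, w, coverage=round(w * 15.0, 1)) for iv in segs]
    s1, s2, s3 = segs
    # head-tail jumps between distant boundaries: rearranged but not cyclic,
    # and never foldback-shaped (sides always differ)
    edges = [
        BreakpointEdge(Breakend(s1.chrom, s1.end, "+"),
                       Breakend(s3.chrom, s3.start, "-"),
                       kind="discordant", copy_count=round(w / 2, 2), support=8),
        BreakpointEdge(Breakend(s2.chrom, s2.end, "+"),
                       Breakend(s1.chrom, s1.start, "-"),
                       kind="discordant", copy_count=round(w / 2, 2), support=8),
        BreakpointEdge(Breakend(s3.chrom, s3.end, "+"),
                       Breakend(s2.chrom, s2.start, "-"),
                       kind="discordant", copy_count=round(w / 3, 2), support=5),
    ]
    graph = AmpliconGraph(amplicon_id, segments, edges, sample_id)
    seg_table = {1: s1, 2: s2, 3: s3}
    cycles = [
        Cycle([(1, "+"), (3, "+")], round(w * 0.6, 2), is_cyclic=False, cycle_id=1),
        Cycle([(2, "+")], round(w * 0.4, 2), is_cyclic=False, cycle_id=2),
    ]
    return graph, Decomposition(amplicon_id, seg_table, cycles)


def _make_linear(genome, rng, amplicon_id, sample_id, anchor, w):
    (iv,) = _sample_segments(rng, genome, anchor, 1, len_range=(100_000, 600_000))
    graph = AmpliconGraph(
        amplicon_id,
        [GraphSegment(iv, w, coverage=round(w * 15.0, 1))],
        [],
        sample_id,
    )
    decomp = Decomposition(
        amplicon_id,
        {1: iv},
        [Cycle([(1, "+")], w, is_cyclic=False, cycle_id=1)],
    )
    return graph, decomp


def evolve_clone(
    parent: tuple[AmpliconGraph, Decomposition],
    grade_delta: int,
    config: SimConfig,
    rng: np.random.Generator,
    amplicon_id: str,
    sample_id: str,
    noise: bool = True,
) -> tuple[AmpliconGraph, Decomposition, float]:
    """Derive a clonal child ecDNA from a parent structure.

    The child keeps all parent segments and junctions (so the pair shares the
    bulk of its bases and breakpoints); its weight is the parent's multiplied
    by cn_escalation_factor**grade_delta with optional multiplicative noise.
    A positive grade_delta additionally splices one small extra segment into a
    secondary decomposition variant, raising structural diversity.  Raises
    ValueError when the parent has no cyclic walk (non-ecDNA parent).
    """
    pgraph, pdecomp = parent
    parent_cycles = pdecomp.cyclic_walks()
    if not parent_cycles:
        raise ValueError("evolve_clone requires an ecDNA (cyclic) parent")
    parent_w = max(c.weight for c in parent_cycles)
    factor = config.cn_escalation_factor ** grade_delta
    w = parent_w * factor
    if noise:
        w *= float(np.exp(rng.normal(0.0, config.cn_noise_sigma)))
    w = round(max(5.0, w), 2)

    genome = config.genome()
    segments = [replace(s, copy_count=w) for s in pgraph.segments]
    edges = list(pgraph.edges)
    seg_table = dict(pdecomp.segments)
    main = parent_cycles[0]
    cycles = [Cycle(list(main.signed_segments), w, is_cyclic=True, cycle_id=1)]

    if grade_delta > 0:
        # splice a small nearby segment into a secondary structural variant
        last_iv = segments[-1].interval
        first_seg_iv = segments[0].interval
        existing = [s.interval for s in segments]
        new_iv = None
        windows = [
            (last_iv.end + 50_000, last_iv.end + 300_000),
            (first_seg_iv.start - 300_000, first_seg_iv.start - 50_000),
        ]
        for w_lo, w_hi in windows:
            for _attempt in range(200):
                length = int(rng.integers(30_000, 60_000))
                lo = max(1, w_lo)
                hi = min(genome[last_iv.chrom] - length, w_hi)
                if hi <= lo:
                    break
                start = int(rng.integers(lo, hi + 1))
                cand = GenomicInterval(last_iv.chrom, start, start + length - 1)
                if all(not cand.overlaps(p) for p in existing):
                    new_iv = cand
                    break
            if new_iv is not None:
                break
        if new_iv is None:
            raise ValueError("segment sampling collision after max retries")
        new_w = round(w * 0.35, 2)
        segments.append(GraphSegment(new_iv, new_w, coverage=round(new_w * 15.0, 1)))
        first_iv = pgraph.segments[0].interval
        edges.append(
            BreakpointEdge(
                Breakend(last_iv.chrom, last_iv.end, "+"),
                Breakend(new_iv.chrom, new_iv.start, "-"),
                kind="discordant", copy_count=new_w, support=6,
            )
        )
        edges.append(
            BreakpointEdge(
                Breakend(new_iv.chrom, new_iv.end, "+"),
                Breakend(first_iv.chrom, first_iv.start, "-"),
                kind="discordant", copy_count=new_w, support=6,
            )
        )
        new_id = max(seg_table) + 1
        seg_table[new_id] = new_iv
        cycles.append(
            Cycle(
                list(main.signed_segments) + [(new_id, "+")],
                new_w,
                is_cyclic=True,
                cycle_id=2,
            )
        )

    graph = AmpliconGraph(amplicon_id, segments, edges, sample_id)
    graph.validate()
    decomp = Decomposition(amplicon_id, seg_table, cycles)
    decomp.validate()
    return graph, decomp, w


# ---------------------------------------------------------------------------
# cohort simulation


_GRADE_NAME = {g: g.name for g in HistologyGrade}


def _grade_steps(config: SimConfig, grade: HistologyGrade | None) -> int:
    if grade is None:
        return 0
    return config.rearrangement_steps_by_grade.get(grade.name, 0)


class _CohortBuilder:
    """Accumulates samples, histology records, files and truth rows."""

    def __init__(self, config: SimConfig, outdir: Path):
        self.config = config
        self.outdir = Path(outdir)
        self.genome = config.genome()
        self.genes = make_toy_genes(self.genome)
        self.meta_rows: list[dict] = []
        self.hist_rows: list[dict] = []
        self.truth_rows: list[TruthRecord] = []
        self.amp_store: dict[str, list[tuple[AmpliconGraph, Decomposition]]] = {}

    def gene_anchor(self, index: int) -> tuple[str, int]:
        g = self.genes[index % len(self.genes)]
        mid = (g.interval.start + g.interval.end) // 2
        return (g.interval.chrom, mid)

    def add_sample(
        self,
        sample_id: str,
        patient_id: str,
        group: str,
        time_point: str,
        level_cm: float,
        on_level: HistologyGrade | None,
        windowed_only: HistologyGrade | None,
    ) -> None:
        self.meta_rows.append(
            dict(sample_id=sample_id, patient_id=patient_id, group=group,
                 time_point=time_point, level_cm=level_cm)
        )
        if on_level is not None:
            self.hist_rows.append(
                dict(patient_id=patient_id, time_point=time_point,
                     level_cm=level_cm, grade=_GRADE_NAME[on_level])
            )
        if windowed_only is not None:
            self.hist_rows.append(
                dict(patient_id=patient_id, time_point=time_point,
                     level_cm=level_cm + 0.5, grade=_GRADE_NAME[windowed_only])
            )
        self.amp_store.setdefault(sample_id, [])

    def add_amplicon(
        self,
        sample_id: str,
        graph: AmpliconGraph,
        decomp: Decomposition,
        truth: TruthRecord,
    ) -> None:
        self.amp_store[sample_id].append((graph, decomp))
        self.truth_rows.append(truth)

    def add_extra_amplicons(self, sample_id: str, patient_label: str) -> None:
        """Sprinkle a non-ecDNA amplification with configured probability."""
        rng = _rng(self.config.seed, "extra", sample_id)
        if rng.random() >= self.config.extra_amp_prob:
            return
        kind = ["linear", "BFB", "complex_non_cyclic"][
            int(rng.choice(3, p=[0.5, 0.25, 0.25]))
        ]
        amp_id = f"{sample_id}_amp{len(self.amp_store[sample_id]) + 1}"
        # keep clear of this sample's existing amplicons
        used = [
            s.interval
            for g, _ in self.amp_store[sample_id]
            for s in g.segments
        ]
        for _attempt in range(50):
            chroms = sorted(self.genome)
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            center = int(rng.integers(1_500_000, self.genome[chrom] - 1_500_000))
            probe = GenomicInterval(chrom, max(1, center - 1_000_000),
                                    center + 1_000_000)
            if all(not probe.overlaps(u) for u in used):
                break
        else:
            return
        graph, decomp, truth = simulate_structure(
            self.genome, kind, rng, amp_id, sample_id,
            cn_median=self.config.other_cn_median,
            cn_sigma=self.config.cn_sigma,
            anchor=(chrom, center),
            genes=self.genes,
        )
        self.add_amplicon(sample_id, graph, decomp, truth)

    # -- output ------------------------------------------------------------

    def write(self) -> Path:
        samples_dir = self.outdir / "samples"
        samples_dir.mkdir(parents=True, exist_ok=True)
        for sample_id in sorted(self.amp_store):
            self._write_cns(samples_dir, sample_id)
            for k, (graph, decomp) in enumerate(self.amp_store[sample_id], start=1):
                write_graph_file(graph, samples_dir / f"{graph.amplicon_id}_graph.txt")
                write_cycles_file(
                    decomp, samples_dir / f"{decomp.amplicon_id}_cycles.txt"
                )
        self._write_tsv(
            self.outdir / "metadata.tsv",
            ["sample_id", "patient_id", "group", "time_point", "level_cm"],
            self.meta_rows,
        )
        self._write_tsv(
            self.outdir / "histology.tsv",
            ["patient_id", "time_point", "level_cm", "grade"],
            self.hist_rows,
        )
        truth_rows = [
            dict(
                sample_id=t.sample_id,
                amplicon_id=t.amplicon_id,
                true_class=t.true_class,
                true_cn=t.true_cn,
                lineage_id=t.lineage_id,
                genes_planted=",".join(t.genes_planted),
            )
            for t in self.truth_rows
        ]
        self._write_tsv(
            self.outdir / "truth.tsv",
            ["sample_id", "amplicon_id", "true_class", "true_cn",
             "lineage_id", "genes_planted"],
            truth_rows,
        )
        genome_rows = [
            dict(chrom=c, length=self.genome[c]) for c in sorted(self.genome)
        ]
        self._write_tsv(self.outdir / "genome.tsv", ["chrom", "length"], genome_rows)
        with open(self.outdir / "genes.bed", "w") as fh:
            for g in self.genes:
                flags = []
                if g.is_oncogene:
                    flags.append("oncogene")
                if g.is_immunomodulatory:
                    flags.append("immunomodulatory")
                fh.write(
                    f"{g.interval.chrom}\t{g.interval.start - 1}\t{g.interval.end}"
                    f"\t{g.name}\t{g.strand}\t{','.join(flags)}\n"
                )
        return self.outdir

    def _write_cns(self, samples_dir: Path, sample_id: str) -> None:
        rows = []
        for graph, _ in self.amp_store[sample_id]:
            for s in graph.segments:
                iv = s.interval
                rows.append((iv.chrom, iv.start - 1, iv.end, s.copy_count))
        for chrom in sorted(self.genome):
            rows.append((chrom, 0, self.genome[chrom], 2.0))
        rows.sort()
        with open(samples_dir / f"{sample_id}.cns", "w") as fh:
            fh.write("chromosome\tstart\tend\tcn\n")
            for chrom, start, end, cn in rows:
                fh.write(f"{chrom}\t{start}\t{end}\t{cn:g}\n")

    @staticmethod
    def _write_tsv(path: Path, columns: list[str], rows: list[dict]) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(columns) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def simulate_cohort(config: SimConfig, outdir: str | Path) -> Path:
    """Write a complete synthetic cohort to outdir; deterministic per seed.

    Layout: ``samples/<sample>.cns``, ``samples/<amplicon>_graph.txt`` /
    ``_cycles.txt``, ``metadata.tsv``, ``histology.tsv``, ``truth.tsv``,
    ``genome.tsv``, ``genes.bed``.
    """
    outdir = Path(outdir)
    if config.design == "fhcc":
        builder = _build_fhcc(config, outdir)
    elif config.design == "generic":
        builder = _build_generic(config, outdir)
    else:
        raise ValueError(f"unknown design {config.design!r}")
    return builder.write()


def _build_generic(config: SimConfig, outdir: Path) -> _CohortBuilder:
    """Cross-sectional cohort: one sample per patient, per-group grade and
    planted positive-patient counts."""
    if not config.group_specs:
        raise ValueError("generic design requires group_specs")
    b = _CohortBuilder(config, outdir)
    patient_no = 0
    for group in sorted(config.group_specs):
        spec = config.group_specs[group]
        for i in range(spec.n_patients):
            patient_no += 1
            patient_id = f"P{patient_no:03d}"
            sample_id = f"{patient_id}_S1"
            b.add_sample(
                sample_id, patient_id, group, time_point="TP-1",
                level_cm=30.0, on_level=spec.grade, windowed_only=None,
            )
            if i < spec.n_ecdna_patients:
                rng = _rng(config.seed, "ecdna", sample_id)
                amp_id = f"{sample_id}_amp1"
                graph, decomp, truth = simulate_structure(
                    b.genome, "ecDNA", rng, amp_id, sample_id,
                    cn_median=config.ecdna_cn_median, cn_sigma=config.cn_sigma,
                    anchor=b.gene_anchor(patient_no),
                    genes=b.genes,
                    rearrangement_steps=_grade_steps(config, spec.grade),
                )
                truth = replace(truth, lineage_id=f"{patient_id}_L1")
                b.add_amplicon(sample_id, graph, decomp, truth)
            b.add_extra_amplicons(sample_id, patient_id)
    return b


def _build_fhcc(config: SimConfig, outdir: Path) -> _CohortBuilder:
    """Longitudinal case-control cohort with planted sample-level histology.

    40 cancer-outcome (CO) patients, indices 0..39, and 40 non-cancer-outcome
    (NCO) patients; two sequencing biopsies ('S1' at 30 cm, 'S2' at 34 cm) at
    each of TP-1 and TP-2.  ecDNA-positive patients and their histology
    pairings are planted so that the cohort reproduces the case-control and
    per-time-point association tables exactly; eight clonal ecDNA lineages
    span two biopsies each (five across time points, three within TP-2).
    """
    b = _CohortBuilder(config, outdir)
    H = HistologyGrade
    n_co, n_nco = 40, 40

    tp1_pos = set(range(0, 7))      # 7 CO patients ecDNA+ at TP-1
    tp2_pos = set(range(2, 13))     # 11 at TP-2; union = 13 positive patients
    cross_tp_same = {2, 3}          # clonal pairs, histology HGD -> HGD
    cross_tp_adv = {4, 5, 6}        # clonal pairs, histology HGD -> EAC
    within_tp2 = {7, 8, 9}          # clonal pairs across the two TP-2 biopsies
    tp1_windowed_only = {0}         # the one TP-1 positive without on-level

    # negative-sample on-level histology pools (counts planted to match the
    # per-time-point association tables)
    rng_alloc = _rng(config.seed, "fhcc-alloc")
    tp1_neg_pool = (
        [("on", H.HGD)] * 21 + [("on", H.LGD)] * 25 + [("none", None)] * 27
    )
    tp2_neg_pool = (
        [("on", H.EAC)] * 20 + [("on", H.HGD)] * 15 + [("on", H.NDBE)] * 8
        + [("none", None)] * 23
    )
    tp1_neg_pool = [tp1_neg_pool[i] for i in rng_alloc.permutation(len(tp1_neg_pool))]
    tp2_neg_pool = [tp2_neg_pool[i] for i in rng_alloc.permutation(len(tp2_neg_pool))]

    lineages: dict[int, tuple[AmpliconGraph, Decomposition]] = {}

    def make_ecdna(idx: int, sample_id: str, grade: HistologyGrade | None):
        rng = _rng(config.seed, "ecdna", sample_id)
        amp_id = f"{sample_id}_amp1"
        graph, decomp, truth = simulate_structure(
            b.genome, "ecDNA", rng, amp_id, sample_id,
            cn_median=config.ecdna_cn_median, cn_sigma=config.cn_sigma,
            anchor=b.gene_anchor(idx),
            genes=b.genes,
            n_segments=2,
            rearrangement_steps=_grade_steps(config, grade),
        )
        truth = replace(truth, lineage_id=f"P{idx + 1:03d}_L1")
        b.add_amplicon(sample_id, graph, decomp, truth)
        return graph, decomp

    def make_clone(idx: int, parent, sample_id: str, grade_delta: int):
        rng = _rng(config.seed, "clone", sample_id)
        amp_id = f"{sample_id}_amp1"
        graph, decomp, w = evolve_clone(
            parent, grade_delta, config, rng, amp_id, sample_id
        )
        b.add_amplicon(
            sample_id, graph, decomp,
            TruthRecord(
                sample_id=sample_id,
                amplicon_id=amp_id,
                true_class="ecDNA",
                true_cn=w,
                lineage_id=f"P{idx + 1:03d}_L1",
                genes_planted=_genes_inside(graph.segments, b.genes),
            ),
        )

    tp1_neg_i = 0
    tp2_neg_i = 0
    for idx in range(n_co):
        patient_id = f"P{idx + 1:03d}"
        for tp in ("TP-1", "TP-2"):
            for snum, level in (("S1", 30.0), ("S2", 34.0)):
                sample_id = f"{patient_id}_{tp.replace('-', '')}_{snum}"
                positive = (
                    snum == "S1"
                    and ((tp == "TP-1" and idx in tp1_pos)
                         or (tp == "TP-2" and idx in tp2_pos))
                ) or (
                    snum == "S2" and tp == "TP-2" and idx in within_tp2
                )
                if positive:
                    if tp == "TP-1":
                        if idx in tp1_windowed_only:
                            on_level, windowed = None, H.HGD
                        else:
                            on_level, windowed = H.HGD, None
                    else:  # TP-2 positives
                        if snum == "S2":  # second member of a within-TP-2 pair
                            on_level, windowed = None, H.EAC
                        elif idx in cross_tp_same:
                            on_level, windowed = H.HGD, None
                        else:
                            on_level, windowed = H.EAC, None
                else:
                    pool, i = (
                        (tp1_neg_pool, tp1_neg_i) if tp == "TP-1"
                        else (tp2_neg_pool, tp2_neg_i)
                    )
                    kind, grade = pool[i]
                    if tp == "TP-1":
                        tp1_neg_i += 1
                    else:
                        tp2_neg_i += 1
                    on_level = grade if kind == "on" else None
                    windowed = None
                b.add_sample(sample_id, patient_id, "CO", tp, level,
                             on_level, windowed)
                if positive:
                    grade = on_level if on_level is not None else windowed
                    if tp == "TP-1":
                        lineages[idx] = make_ecdna(idx, sample_id, grade)
                    elif snum == "S1":
                        if idx in (cross_tp_same | cross_tp_adv):
                            delta = 1 if idx in cross_tp_adv else 0
                            make_clone(idx, lineages[idx], sample_id, delta)
                        else:
                            lineages[idx] = make_ecdna(idx, sample_id, grade)
                    else:  # S2 within-TP-2 clone
                        make_clone(idx, lineages[idx], sample_id, 0)
                else:
                    b.add_extra_amplicons(sample_id, patient_id)

    # NCO patients: benign trajectories; exactly one ecDNA-positive patient
    nco_pos_idx = n_co  # first NCO patient
    rng_nco = _rng(config.seed, "nco-grades")
    for j in range(n_nco):
        idx = n_co + j
        patient_id = f"P{idx + 1:03d}"
        base_grade = H.LGD if rng_nco.random() < 0.4 else H.NDBE
        for tp in ("TP-1", "TP-2"):
            for snum, level in (("S1", 30.0), ("S2", 34.0)):
                sample_id = f"{patient_id}_{tp.replace('-', '')}_{snum}"
                on_level = base_grade if rng_nco.random() < 0.7 else None
                b.add_sample(sample_id, patient_id, "NCO", tp, level,
                             on_level, None)
                if idx == nco_pos_idx and tp == "TP-2" and snum == "S1":
                    make_ecdna(idx, sample_id, on_level)
                else:
                    b.add_extra_amplicons(sample_id, patient_id)
    return b


# ---------------------------------------------------------------------------
# loading a simulated cohort back through the pipeline


def load_genome(outdir: str | Path) -> dict[str, int]:
    genome: dict[str, int] = {}
    with open(Path(outdir) / "genome.tsv") as fh:
        next(fh)
        for line in fh:
            chrom, length = line.split("\t")
            genome[chrom] = int(length)
    return genome


def load_gene_models(outdir: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(Path(outdir) / "genes.bed") as fh:
        for line in fh:
            chrom, start, end, name, strand, flags = line.rstrip("\n").split("\t")
            genes.append(
                GeneModel(
                    name=name,
                    interval=GenomicInterval(chrom, int(start) + 1, int(end)),
                    strand=strand,
                    is_oncogene="oncogene" in flags.split(","),
                    is_immunomodulatory="immunomodulatory" in flags.split(","),
                )
            )
    return genes


def load_cohort(
    outdir: str | Path,
    params: ClassifierParams = ClassifierParams(),
    window_cm: float = 1.0,
) -> list[CohortSample]:
    """Read a simulated cohort from disk, classify every amplicon, dedup per
    sample, and pair histology — the classify stage of the pipeline."""
    outdir = Path(outdir)
    samples_dir = outdir / "samples"

    hist: dict[tuple[str, str], list[tuple[float, HistologyGrade]]] = {}
    with open(outdir / "histology.tsv") as fh:
        next(fh)
        for line in fh:
            patient_id, tp, level, grade = line.rstrip("\n").split("\t")
            hist.setdefault((patient_id, tp), []).append(
                (float(level), HistologyGrade.parse(grade))
            )

    samples: list[CohortSample] = []
    with open(outdir / "metadata.tsv") as fh:
        next(fh)
        for line in fh:
            sample_id, patient_id, group, tp, level = line.rstrip("\n").split("\t")
            sample = CohortSample(
                sample_id=sample_id,
                patient_id=patient_id,
                group=group,
                time_point=tp,
                level_cm=float(level),
            )
            amps: list[ClassifiedAmplicon] = []
            for graph_path in sorted(samples_dir.glob(f"{sample_id}_amp*_graph.txt")):
                amp_id = graph_path.name[: -len("_graph.txt")]
                graph = read_graph_file(graph_path, amplicon_id=amp_id,
                                        sample_id=sample_id)
                decomp = read_cycles_file(
                    samples_dir / f"{amp_id}_cycles.txt", amplicon_id=amp_id
                )
                amps.append(classify_amplicon(graph, decomp, params))
            sample.amplicons = deduplicate_amplicons(amps)
            pair_histology(
                sample, hist.get((patient_id, tp), []), window_cm=window_cm
            )
            samples.append(sample)
    return samples


def load_truth(outdir: str | Path) -> list[TruthRecord]:
    out: list[TruthRecord] = []
    with open(Path(outdir) / "truth.tsv") as fh:
        next(fh)
        for line in fh:
            sample_id, amp_id, klass, cn, lineage, genes = line.rstrip("\n").split("\t")
            out.append(
                TruthRecord(
                    sample_id=sample_id,
                    amplicon_id=amp_id,
                    true_class=klass,
                    true_cn=float(cn),
                    lineage_id=lineage,
                    genes_planted=tuple(g for g in genes.split(",") if g),
                )
            )
    return out
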