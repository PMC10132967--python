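"""Amplicon similarity scoring and clonality calling.

To decide whether focal amplifications observed in different biopsies of the
same patient descend from a common origin, each pair is scored on [0, 1] by
combining two Jaccard indices:

* genomic: base-level overlap of the amplified interval sets;
* breakpoint: one-to-one matching of discordant junctions within a coordinate
  tolerance.

The score is the mean of the two when both amplicons carry at least one
discordant edge, and the genomic Jaccard alone otherwise.  Significance is an
empirical upper-tail p-value against a null of cross-patient amplicon pairs
(or uniform random placement of matched-length interval sets when too few
background pairs exist).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import AmpliconClass, ClassifiedAmplicon
from .cohort import CohortSample, HistologyGrade
from .graphio import BreakpointEdge
from .intervals import GenomicInterval, jaccard, intersect_length

DEFAULT_BREAKPOINT_TOL = 100  # bp; junction coordinates jitter by tens of bp


@dataclass
class SimilarityResult:
    amplicon_a: str
    amplicon_b: str
    score: float
    genomic_jaccard: float
    breakpoint_jaccard: float
    p_value: float | None = None
    n_null: int = 0


def _endpoints_match(x, y, tol: int) -> bool:
    return x.chrom == y.chrom and x.side == y.side and abs(x.pos - y.pos) <= tol


def edges_match(a: BreakpointEdge, b: BreakpointEdge, tol: int) -> bool:
    """True when the two junctions coincide within tol bp, sides included.

    Both endpoint assignments are tried (edges are unordered).
    """
    return (
        _endpoints_match(a.left, b.left, tol) and _endpoints_match(a.right, b.right, tol)
    ) or (
        _endpoints_match(a.left, b.right, tol) and _endpoints_match(a.right, b.left, tol)
    )


def _edge_key(e: BreakpointEdge) -> tuple:
    return (e.left.chrom, e.left.pos, e.left.side, e.right.chrom, e.right.pos, e.right.side)


def match_breakpoints(
    edges_a: Sequence[BreakpointEdge],
    edges_b: Sequence[BreakpointEdge],
    tol: int = DEFAULT_BREAKPOINT_TOL,
) -> list[tuple[BreakpointEdge, BreakpointEdge]]:
    """Greedy one-to-one matching of junction edges within tol bp.

    Candidate pairs are considered in ascending coordinate order, so the
    result is deterministic; each edge is used at most once.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    a_sorted = sorted(edges_a, key=_edge_key)
    b_sorted = sorted(edges_b, key=_edge_key)
    used_b: set[int] = set()
    matches: list[tuple[BreakpointEdge, BreakpointEdge]] = []
    for ea in a_sorted:
        for j, eb in enumerate(b_sorted):
            if j in used_b:
                continue
            if edges_match(ea, eb, tol):
                used_b.add(j)
                matches.append((ea, eb))
                break
    return matches


def similarity_score(
    a: ClassifiedAmplicon,
    b: ClassifiedAmplicon,
    tol: int = DEFAULT_BREAKPOINT_TOL,
) -> SimilarityResult:
    """Score two classified amplicons on [0, 1].

    Raises ValueError when either amplicon has no amplified intervals.
    """
    if not a.amplified_intervals or not b.amplified_intervals:
        raise ValueError("similarity undefined for empty amplified intervals")
    gj = jaccard(a.amplified_intervals, b.amplified_intervals)
    ea = a.graph.discordant_edges
    eb = b.graph.discordant_edges
    if ea and eb:
        m = len(match_breakpoints(ea, eb, tol))
        bj = m / (len(ea) + len(eb) - m)
        score = (gj + bj) / 2.0
    else:
        bj = 0.0
        score = gj
    return SimilarityResult(
        amplicon_a=a.amplicon_id,
        amplicon_b=b.amplicon_id,
        score=score,
        genomic_jaccard=gj,
        breakpoint_jaccard=bj,
    )


def _random_placement_score(
    a: ClassifiedAmplicon,
    b: ClassifiedAmplicon,
    genome: dict[str, int],
    rng: np.random.Generator,
) -> float:
    """Null score: both interval sets re-placed uniformly on the genome.

    Junctions are not re-placed (random junction pairs essentially never
    coincide); the combination rule mirrors the observed pair's.
    """
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    def place(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
        placed = []
        for iv in intervals:
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            max_start = max(1, genome[chrom] - iv.length + 1)
            start = int(rng.integers(1, max_start + 1))
            placed.append(GenomicInterval(chrom, start, start + iv.length - 1))
        return placed

    gj = jaccard(place(a.amplified_intervals), place(b.amplified_intervals))
    if a.graph.discordant_edges and b.graph.discordant_edges:
        return gj / 2.0
    return gj


def similarity_p_value(
    result: SimilarityResult,
    a: ClassifiedAmplicon,
    b: ClassifiedAmplicon,
    background: Sequence[tuple[str, ClassifiedAmplicon]],
    n_null: int = 500,
    seed: int = 0,
    genome: dict[str, int] | None = None,
    tol: int = DEFAULT_BREAKPOINT_TOL,
) -> SimilarityResult:
    """Fill the empirical p-value on a similarity result.

    p = (1 + #{null >= observed}) / (n_null + 1), with null scores computed on
    cross-patient pairs sampled (seeded) from the background, a list of
    (patient_id, amplicon).  When fewer than n_null distinct cross-patient
    pairs exist, the remaining replicates use uniform random placement of the
    observed pair's interval-set lengths on the supplied genome model.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    rng = np.random.default_rng(seed)
    pairs = [
        (i, j)
        for i in range(len(background))
        for j in range(i + 1, len(background))
        if background[i][0] != background[j][0]
    ]
    null_scores: list[float] = []
    if pairs:
        idx = rng.integers(0, len(pairs), size=min(n_null, len(pairs)))
        if len(pairs) <= n_null:
            idx = np.arange(len(pairs))  # exhaustively use what exists
        for k in idx:
            i, j = pairs[int(k)]
            try:
                null_scores.append(
                    similarity_score(background[i][1], background[j][1], tol).score
                )
            except ValueError:
                continue
    n_missing = n_null - len(null_scores)
    if n_missing > 0:
        if genome is None:
            if not null_scores:
                raise ValueError(
                    "no background pairs and no genome model for the null"
                )
        else:
            for _ in range(n_missing):
                null_scores.append(_random_placement_score(a, b, genome, rng))
    n = len(null_scores)
    exceed = sum(1 for s in null_scores if s >= result.score - 1e-12)
    result.p_value = (1 + exceed) / (n + 1)
    result.n_null = n
    return result


@dataclass
class ClonalPair:
    """A within-patient ecDNA pair called clonal by similarity."""

    patient_id: str
    sample_a: str
    sample_b: str
    result: SimilarityResult
    cn_first: float
    cn_second: float
    histology_first: HistologyGrade | None
    histology_second: HistologyGrade | None

    @property
    def same_histology(self) -> bool:
        return (
            self.histology_first is not None
            and self.histology_first == self.histology_second
        )

    @property
    def grade_advanced(self) -> bool:
        return (
            self.histology_first is not None
            and self.histology_second is not None
            and self.histology_second > self.histology_first
        )

    @property
    def cn_delta(self) -> float:
        return self.cn_second - self.cn_first


def find_clonal_pairs(
    samples: Sequence[CohortSample],
    alpha: float = 0.05,
    n_null: int = 500,
    seed: int = 0,
    genome: dict[str, int] | None = None,
    tol: int = DEFAULT_BREAKPOINT_TOL,
) -> list[ClonalPair]:
    """Within-patient ecDNA pairs with genomic overlap and significant similarity.

    For every patient, every pair of ecDNA amplicons from *different* samples
    whose amplified intervals share at least one base is scored; pairs with
    empirical p < alpha are returned.  The pair is oriented so that the second
    member has the more severe histology (ties broken by time point then
    sample id), so cn_delta is the copy-number change along disease
    progression.
    """
    by_patient: dict[str, list[CohortSample]] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, []).append(s)

    out: list[ClonalPair] = []
    for patient_id in sorted(by_patient):
        group = sorted(by_patient[patient_id], key=lambda s: (s.time_point, s.sample_id))
        background = [
            (s.patient_id, amp)
            for s in samples
            if s.patient_id != patient_id
            for amp in s.ecdna_amplicons()
        ]
        candidates = [
            (s, amp) for s in group for amp in s.ecdna_amplicons()
        ]
        for i in range(len(candidates)):
            for j in range(i + 1, len(candidates)):
                sa, aa = candidates[i]
                sb, ab = candidates[j]
                if sa.sample_id == sb.sample_id:
                    continue
                if (
                    intersect_length(aa.amplified_intervals, ab.amplified_intervals)
                    == 0
                ):
                    continue
                res = similarity_score(aa, ab, tol)
                pair_seed = (seed + 977 * (hash_label(aa.amplicon_id) ^
                                           hash_label(ab.amplicon_id))) % (2**31)
                res = similarity_p_value(
                    res, aa, ab, background, n_null=n_null, seed=pair_seed,
                    genome=genome, tol=tol,
                )
                if res.p_value is None or res.p_value >= alpha:
                    continue
                first, second = (sa, aa), (sb, ab)
                ga = sa.best_histology()
                gb = sb.best_histology()
                if ga is not None and gb is not None and gb < ga:
                    first, second = second, first
                out.append(
                    ClonalPair(
                        patient_id=patient_id,
                        sample_a=first[0].sample_id,
                        sample_b=second[0].sample_id,
                        result=res,
                        cn_first=first[1].max_copy_number,
                        cn_second=second[1].max_copy_number,
                        histology_first=first[0].best_histology(),
                        histology_second=second[0].best_histology(),
                    )
                )
    return out


def hash_label(label: str) -> int:
    """Stable 32-bit hash of a text label (process-independent)."""
    import zlib

    return zlib.crc32(label.encode())
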