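"""Seed-region detection from copy-number segment tables.

Candidate focal-amplification seeds are copy-number segments passing a
cohort-specific amplitude threshold, merged across small gaps, then filtered on
merged size.  Both thresholds are exclusive ("greater than"): a segment exactly
at cn_min is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .intervals import GenomicInterval, merge_intervals, to_bed_line


@dataclass(frozen=True)
class CnvSegment:
    interval: GenomicInterval
    total_copy_number: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.total_copy_number < 0:
            raise ValueError(f"negative copy number {self.total_copy_number}")


@dataclass(frozen=True)
class SeedParams:
    """Amplitude (cn_min), size (size_min, bp) and merge-gap thresholds.

    cn_min and size_min are exclusive lower bounds; merge_gap is the largest
    same-chromosome gap bridged when joining kept segments before the size
    filter is applied to the merged intervals.
    """

    cn_min: float
    size_min: int
    merge_gap: int = 300_000

    def __post_init__(self) -> None:
        if self.cn_min <= 0 or self.size_min <= 0:
            raise ValueError("cn_min and size_min must be positive")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be non-negative")


#: Cohort presets: amplitude / size thresholds used by each study arm.
PRESETS: dict[str, SeedParams] = {
    "cambridge": SeedParams(cn_min=4.5, size_min=10_000),
    "tcga": SeedParams(cn_min=4.5, size_min=50_000),
    "fhcc_tumour": SeedParams(cn_min=4.3, size_min=50_000),
    "fhcc_normal": SeedParams(cn_min=4.0, size_min=10_000),
}


def call_seeds(
    segments: Iterable[CnvSegment], params: SeedParams
) -> list[GenomicInterval]:
    """Filter, merge and size-select copy-number segments into seed regions.

    Order of operations: amplitude filter (CN > cn_min), same-chromosome merge
    across gaps <= merge_gap, then drop merged intervals with length <=
    size_min.  Output is sorted by (chrom, start).
    """
    kept = [s.interval for s in segments if s.total_copy_number > params.cn_min]
    merged = merge_intervals(kept, gap=params.merge_gap)
    return [iv for iv in merged if iv.length > params.size_min]


def read_cns(
    path: str | Path, sample_id: str = "", log2_ratio: bool = False
) -> list[CnvSegment]:
    """Read a CNVKit-style .cns segment table (TSV).

    Expects columns chromosome, start, end and either an absolute copy-number
    column (``cn`` or ``total_copy_number``) or, with log2_ratio=True, a
    ``log2`` column converted as CN = 2 * 2**log2 (diploid assumption).
    Input start is treated as 0-based half-open (the .cns convention) and
    converted to the package's 1-based inclusive coordinates.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if log2_ratio:
        cn = 2.0 * 2.0 ** df[cols["log2"]]
    else:
        key = "cn" if "cn" in cols else "total_copy_number"
        cn = df[cols[key]].astype(float)
    out = []
    for (_, row), value in zip(df.iterrows(), cn):
        out.append(
            CnvSegment(
                GenomicInterval(
                    str(row[cols["chromosome"]]),
                    int(row[cols["start"]]) + 1,
                    int(row[cols["end"]]),
                ),
                float(value),
                sample_id,
            )
        )
    return out


def write_seeds_bed(seeds: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(seeds, start=1):
            fh.write(to_bed_line(iv, name=f"seed_{i}") + "\n")
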