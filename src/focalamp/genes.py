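"""Gene content of focal amplifications.

A gene is called as carried on an amplification when its length-weighted mean
copy number over the gene body is at least 4.5 and its 5' end is intact —
operationalised as: the 5'-most base lies inside an amplified interval and no
discordant junction endpoint falls strictly inside the first 1 kbp of the gene
measured from the 5' end.  Gene bases not covered by any graph segment are
assumed diploid (CN 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .classify import AmpliconClass, ClassifiedAmplicon
from .intervals import GenomicInterval

GENE_CN_MIN = 4.5          # minimum mean gene copy number for a call
FIVE_PRIME_WINDOW = 1_000  # bp of 5' gene body that must be junction-free
UNCOVERED_CN = 2.0         # diploid assumption for uncovered gene bases


@dataclass(frozen=True)
class GeneModel:
    name: str
    interval: GenomicInterval
    strand: str  # '+' or '-'
    is_oncogene: bool = False
    is_immunomodulatory: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be +/-, got {self.strand!r}")

    @property
    def five_prime_pos(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end


@dataclass(frozen=True)
class GeneCall:
    gene: GeneModel
    amplicon_id: str
    mean_copy_number: float
    five_prime_intact: bool
    on_ecdna: bool

    @property
    def is_oncogene(self) -> bool:
        return self.gene.is_oncogene

    @property
    def is_immunomodulatory(self) -> bool:
        return self.gene.is_immunomodulatory


def _mean_gene_cn(amp: ClassifiedAmplicon, gene: GeneModel) -> float:
    """Length-weighted mean segment copy number over the gene body."""
    g = gene.interval
    covered = 0
    weighted = 0.0
    for seg in amp.graph.segments:
        iv = seg.interval
        if not iv.overlaps(g):
            continue
        n = min(iv.end, g.end) - max(iv.start, g.start) + 1
        covered += n
        weighted += n * seg.copy_count
    uncovered = g.length - covered
    return (weighted + uncovered * UNCOVERED_CN) / g.length


def _five_prime_intact(
    amp: ClassifiedAmplicon, gene: GeneModel, window: int = FIVE_PRIME_WINDOW
) -> bool:
    g = gene.interval
    fp = gene.five_prime_pos
    if not any(iv.contains(g.chrom, fp) for iv in amp.amplified_intervals):
        return False
    if gene.strand == "+":
        lo, hi = g.start, min(g.end, g.start + window)
    else:
        lo, hi = max(g.start, g.end - window), g.end
    for e in amp.graph.discordant_edges:
        for end in (e.left, e.right):
            if end.chrom == g.chrom and lo < end.pos < hi:
                return False
    return True


def genes_on_amplicon(
    amp: ClassifiedAmplicon,
    genes: Sequence[GeneModel],
    cn_min: float = GENE_CN_MIN,
    five_prime_window: int = FIVE_PRIME_WINDOW,
) -> list[GeneCall]:
    """Calls for all genes overlapping the amplicon's amplified intervals.

    Only genes meeting both filters (mean CN >= cn_min, 5' end intact) are
    emitted.
    """
    on_ecdna = amp.amplicon_class is AmpliconClass.ECDNA
    calls: list[GeneCall] = []
    for gene in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start, g.name)):
        if not any(gene.interval.overlaps(iv) for iv in amp.amplified_intervals):
            continue
        mean_cn = _mean_gene_cn(amp, gene)
        intact = _five_prime_intact(amp, gene, five_prime_window)
        if mean_cn >= cn_min and intact:
            calls.append(
                GeneCall(
                    gene=gene,
                    amplicon_id=amp.amplicon_id,
                    mean_copy_number=mean_cn,
                    five_prime_intact=intact,
                    on_ecdna=on_ecdna,
                )
            )
    return calls


def oncogene_summary(
    amplicons: Sequence[ClassifiedAmplicon], calls: Sequence[GeneCall]
) -> pd.DataFrame:
    """Per-class oncogene content summary.

    Rows: each amplicon class present, plus a ``non_ecdna_fsCNA`` aggregate of
    the three non-ecDNA classes.  Columns: n_amplicons, n_unique_oncogenes,
    oncogenes_per_amplicon, frac_multi_oncogene, max_oncogene_cn.
    """
    calls_by_amp: dict[str, list[GeneCall]] = {}
    for c in calls:
        calls_by_amp.setdefault(c.amplicon_id, []).append(c)

    def summarise(label: str, group: list[ClassifiedAmplicon]) -> dict:
        onc_names: set[str] = set()
        n_multi = 0
        max_cn = float("nan")
        cns: list[float] = []
        for amp in group:
            amp_onc = [
                c for c in calls_by_amp.get(amp.amplicon_id, []) if c.is_oncogene
            ]
            onc_names.update(c.gene.name for c in amp_onc)
            if len({c.gene.name for c in amp_onc}) >= 2:
                n_multi += 1
            if amp_onc:
                cns.append(max(c.mean_copy_number for c in amp_onc))
        if cns:
            max_cn = max(cns)
        n = len(group)
        return {
            "class": label,
            "n_amplicons": n,
            "n_unique_oncogenes": len(onc_names),
            "oncogenes_per_amplicon": len(onc_names) / n if n else float("nan"),
            "frac_multi_oncogene": n_multi / n if n else float("nan"),
            "max_oncogene_cn": max_cn,
        }

    rows = []
    for klass in AmpliconClass:
        group = [a for a in amplicons if a.amplicon_class is klass]
        if group:
            rows.append(summarise(klass.label, group))
    non_ecdna = [
        a for a in amplicons if a.amplicon_class is not AmpliconClass.ECDNA
    ]
    if non_ecdna:
        rows.append(summarise("non_ecdna_fsCNA", non_ecdna))
    return pd.DataFrame(
        rows,
        columns=[
            "class",
            "n_amplicons",
            "n_unique_oncogenes",
            "oncogenes_per_amplicon",
            "frac_multi_oncogene",
            "max_oncogene_cn",
        ],
    )


def read_gene_bed(
    path: str | Path,
    oncogenes: Iterable[str] = (),
    immunomodulatory: Iterable[str] = (),
) -> list[GeneModel]:
    """Read gene models from a BED-like TSV (chrom, start, end, name, strand).

    start is 0-based half-open (BED) and converted to 1-based inclusive.
    Membership in the oncogene / immunomodulatory symbol sets is annotated on
    the models.
    """
    onc = set(oncogenes)
    imm = set(immunomodulatory)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[4] if len(fields) > 4 else "+"
            genes.append(
                GeneModel(
                    name=name,
                    interval=GenomicInterval(chrom, start + 1, end),
                    strand=strand,
                    is_oncogene=name in onc,
                    is_immunomodulatory=name in imm,
                )
            )
    return genes


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                out.add(token)
    return out
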