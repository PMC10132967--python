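"""Cohort sample metadata: patients, time points, biopsy levels, histology."""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from enum import Enum

from .classify import AmpliconClass, ClassifiedAmplicon


@functools.total_ordering
class HistologyGrade(Enum):
    """Histological disease grade, totally ordered by severity.

    NDBE (non-dysplastic Barrett's oesophagus) < LGD (low-grade dysplasia)
    < HGD (high-grade dysplasia) < EAC (oesophageal adenocarcinoma).
    """

    NDBE = 0
    LGD = 1
    HGD = 2
    EAC = 3

    def __lt__(self, other: "HistologyGrade") -> bool:
        if not isinstance(other, HistologyGrade):
            return NotImplemented
        return self.value < other.value

    @classmethod
    def parse(cls, token: str) -> "HistologyGrade":
        return cls[token.strip().upper()]


@dataclass
class CohortSample:
    """One sequencing biopsy with its metadata and classified amplicons."""

    sample_id: str
    patient_id: str
    group: str                     # cohort arm, e.g. CO | NCO | early EAC
    time_point: str = ""
    level_cm: float = 0.0          # biopsy height above the gastro-oesophageal junction
    amplicons: list[ClassifiedAmplicon] = field(default_factory=list)
    histology_on_level: HistologyGrade | None = None
    histology_windowed: HistologyGrade | None = None

    def __post_init__(self) -> None:
        if self.level_cm < 0:
            raise ValueError(f"level_cm must be >= 0, got {self.level_cm}")

    @property
    def ecdna_positive(self) -> bool:
        return any(
            a.amplicon_class is AmpliconClass.ECDNA for a in self.amplicons
        )

    def ecdna_amplicons(self) -> list[ClassifiedAmplicon]:
        return [
            a for a in self.amplicons if a.amplicon_class is AmpliconClass.ECDNA
        ]

    def best_histology(self) -> HistologyGrade | None:
        """Windowed histology when available, else on-level."""
        return self.histology_windowed or self.histology_on_level
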