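"""Histology pairing and cohort association statistics.

All two-by-two analyses use one-sided Fisher's exact tests (enrichment in cell
``a``) and Haldane-corrected odds ratios with Woolf (log-normal) confidence
intervals: when any cell of the table is zero, 0.5 is added to every cell
before computing the odds ratio and its interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .cohort import CohortSample, HistologyGrade


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of counts; rows = exposure, columns = outcome.

    Convention throughout: row 1 = the more-advanced / exposed group,
    column 1 = event present (e.g. ecDNA-positive), so enrichment tests are
    one-sided on cell ``a``.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


def fisher_one_sided(t: ContingencyTable) -> float:
    """Exact one-sided (greater) Fisher p-value for enrichment in cell a."""
    if t.total == 0:
        raise ValueError("all-zero contingency table")
    return float(sps.fisher_exact(t.as_array(), alternative="greater")[1])


def odds_ratio_ci(
    t: ContingencyTable, alpha: float = 0.05
) -> tuple[float, float, float, bool]:
    """Odds ratio with Woolf (1-alpha) CI, Haldane-corrected when needed.

    Returns (odds_ratio, ci_low, ci_high, haldane_applied).  The Haldane
    correction adds 0.5 to every cell if and only if any cell is zero; both
    the odds ratio and the standard error use the corrected cells.
    """
    haldane = t.has_zero_cell
    shift = 0.5 if haldane else 0.0
    a, b, c, d = (x + shift for x in (t.a, t.b, t.c, t.d))
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    log_or = math.log(orr)
    return orr, math.exp(log_or - z * se), math.exp(log_or + z * se), haldane


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> float:
    """Mann-Whitney U p-value.

    Exact enumeration when the pooled sample is small (n_x + n_y <= 12,
    tie-free); otherwise the tie-corrected normal approximation with
    continuity correction.  ``alternative`` follows scipy ('less', 'greater',
    'two-sided'), stated for x relative to y.
    """
    x = list(x)
    y = list(y)
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    pooled = x + y
    small = len(pooled) <= 12 and len(set(pooled)) == len(pooled)
    method = "exact" if small else "asymptotic"
    return float(
        sps.mannwhitneyu(x, y, alternative=alternative, method=method)[1]
    )


def levene(x: Sequence[float], y: Sequence[float]) -> float:
    """Levene's test on absolute deviations from the group means."""
    x = list(x)
    y = list(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need length >= 2")
    dev_x = [abs(v - sum(x) / len(x)) for v in x]
    dev_y = [abs(v - sum(y) / len(y)) for v in y]
    if max(dev_x) == 0 and max(dev_y) == 0:
        raise ValueError("degenerate samples: no within-group deviation")
    return float(sps.levene(x, y, center="mean")[1])


# ---------------------------------------------------------------------------
# histology pairing


def pair_histology(
    sample: CohortSample,
    records: Sequence[tuple[float, HistologyGrade]],
    window_cm: float = 1.0,
) -> CohortSample:
    """Assign on-level and windowed histology to a sequencing biopsy.

    On-level: most severe grade among histology records at exactly the same
    oesophageal level; windowed: most severe among records within +/-
    window_cm (inclusive).  Either is left absent when no record qualifies.
    Returns the sample (mutated in place) for chaining.
    """
    if window_cm < 0:
        raise ValueError("window_cm must be non-negative")
    on_level = [g for level, g in records if level == sample.level_cm]
    windowed = [
        g for level, g in records if abs(level - sample.level_cm) <= window_cm
    ]
    sample.histology_on_level = max(on_level) if on_level else None
    sample.histology_windowed = max(windowed) if windowed else None
    return sample


# ---------------------------------------------------------------------------
# study contingency tables


def _patient_positive(samples: Sequence[CohortSample]) -> dict[str, bool]:
    """Patient-level ecDNA positivity: any positive sample."""
    status: dict[str, bool] = {}
    for s in samples:
        status[s.patient_id] = status.get(s.patient_id, False) or s.ecdna_positive
    return status


def _patient_table(
    samples: Sequence[CohortSample], exposed_group: str, reference_group: str
) -> ContingencyTable:
    by_group: dict[str, dict[str, bool]] = {}
    for s in samples:
        by_group.setdefault(s.group, {})
    for group, members in by_group.items():
        members.update(_patient_positive([s for s in samples if s.group == group]))
    exp = by_group.get(exposed_group, {})
    ref = by_group.get(reference_group, {})
    return ContingencyTable(
        a=sum(exp.values()),
        b=sum(not v for v in exp.values()),
        c=sum(ref.values()),
        d=sum(not v for v in ref.values()),
    )


def build_association_tables(
    samples: Sequence[CohortSample],
) -> dict[str, ContingencyTable]:
    """Regenerate the study's headline contingency tables from cohort samples.

    Emits each table whose groups are present in the input:

    * ``early_eac_vs_ndbe_lgd`` — patient-level ecDNA, early-stage EAC vs
      NDBE/LGD surveillance patients;
    * ``late_vs_early_eac`` — patient-level ecDNA, late- vs early-stage EAC;
    * ``co_vs_nco`` — patient-level ecDNA (any sample, any time point),
      cancer-outcome vs non-cancer-outcome patients;
    * ``tp1_hgd_vs_ecdna`` — sample-level, cancer-outcome TP-1 biopsies with
      on-level histology: rows ecDNA+/-, columns on-level HGD-or-worse vs not;
    * ``tp2_eac_vs_ecdna`` — sample-level, cancer-outcome TP-2 biopsies with
      on-level histology: rows ecDNA+/-, columns on-level EAC vs not.
    """
    groups = {s.group for s in samples}
    tables: dict[str, ContingencyTable] = {}

    if {"early EAC", "NDBE/LGD"} <= groups:
        tables["early_eac_vs_ndbe_lgd"] = _patient_table(
            samples, "early EAC", "NDBE/LGD"
        )
    if {"late EAC", "early EAC"} <= groups:
        tables["late_vs_early_eac"] = _patient_table(samples, "late EAC", "early EAC")
    if {"CO", "NCO"} <= groups:
        tables["co_vs_nco"] = _patient_table(samples, "CO", "NCO")

    co = [s for s in samples if s.group == "CO"]
    tp1 = [
        s for s in co if s.time_point == "TP-1" and s.histology_on_level is not None
    ]
    if tp1:
        pos = [s for s in tp1 if s.ecdna_positive]
        neg = [s for s in tp1 if not s.ecdna_positive]
        tables["tp1_hgd_vs_ecdna"] = ContingencyTable(
            a=sum(s.histology_on_level >= HistologyGrade.HGD for s in pos),
            b=sum(s.histology_on_level < HistologyGrade.HGD for s in pos),
            c=sum(s.histology_on_level >= HistologyGrade.HGD for s in neg),
            d=sum(s.histology_on_level < HistologyGrade.HGD for s in neg),
        )
    tp2 = [
        s for s in co if s.time_point == "TP-2" and s.histology_on_level is not None
    ]
    if tp2:
        pos = [s for s in tp2 if s.ecdna_positive]
        neg = [s for s in tp2 if not s.ecdna_positive]
        tables["tp2_eac_vs_ecdna"] = ContingencyTable(
            a=sum(s.histology_on_level is HistologyGrade.EAC for s in pos),
            b=sum(s.histology_on_level is not HistologyGrade.EAC for s in pos),
            c=sum(s.histology_on_level is HistologyGrade.EAC for s in neg),
            d=sum(s.histology_on_level is not HistologyGrade.EAC for s in neg),
        )
    return tables


def table_report(tables: dict[str, ContingencyTable]) -> list[dict]:
    """Fisher p, odds ratio and CI for each named table (report rows)."""
    rows = []
    for name in sorted(tables):
        t = tables[name]
        orr, lo, hi, haldane = odds_ratio_ci(t)
        rows.append(
            {
                "table": name,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "fisher_p_one_sided": fisher_one_sided(t),
                "odds_ratio": orr,
                "ci_low": lo,
                "ci_high": hi,
                "haldane_applied": haldane,
            }
        )
    return rows
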