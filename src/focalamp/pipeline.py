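"""End-to-end pipeline: simulate -> seed -> classify -> similarity -> genes ->
stats -> report.

Every stage is a pure function of (inputs, config, seed); re-running with the
same seed reproduces the output tree byte for byte.  Stage outputs live under
one run directory with fixed names:

    cohort/            simulated input files (.cns, graph/cycles, metadata)
    seeds/             per-sample seed BED files
    classification.tsv per-amplicon class, species count, CN, complexity
    classified_bed/    per-amplicon amplified-region BED files
    clonal_pairs.tsv   within-patient clonal ecDNA pairs
    gene_calls.tsv     genes carried on amplifications
    oncogene_summary.tsv
    stats.tsv / stats.json
    report.txt
    manifest.json
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .classify import ClassifierParams
from .cohort import CohortSample
from .complexity import complexity_score
from .genes import genes_on_amplicon, oncogene_summary
from .intervals import to_bed_line
from .seeds import PRESETS, call_seeds, read_cns, write_seeds_bed
from .similarity import find_clonal_pairs
from .simulate import (
    SimConfig,
    cambridge_config,
    fhcc_config,
    load_cohort,
    load_gene_models,
    load_genome,
    simulate_cohort,
)
from .stats import build_association_tables, table_report

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    version: str
    seed: int
    design: str
    config: dict
    input_checksums: dict[str, str]
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _grade_name(grade) -> str:
    return grade.name if grade is not None else "NA"


def make_config(design: str, seed: int) -> SimConfig:
    if design == "fhcc":
        return fhcc_config(seed)
    if design == "cambridge":
        return cambridge_config(seed)
    raise ValueError(f"unknown design {design!r}; use 'fhcc' or 'cambridge'")


def run_pipeline(
    config: SimConfig,
    outdir: str | Path,
    classifier_params: ClassifierParams = ClassifierParams(),
    seed_preset: str | None = None,
    n_null: int = 200,
) -> RunManifest:
    """Execute all stages into outdir and return the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = config.design if config.design != "generic" else "cambridge"
    if seed_preset is None:
        seed_preset = "fhcc_tumour" if design == "fhcc" else "cambridge"

    t0 = time.monotonic()
    cohort_dir = outdir / "cohort"
    simulate_cohort(config, cohort_dir)
    logger.info("simulate: %.1fs", time.monotonic() - t0)

    # -- seed detection over the .cns tables --------------------------------
    t0 = time.monotonic()
    seeds_dir = outdir / "seeds"
    seeds_dir.mkdir(exist_ok=True)
    params = PRESETS[seed_preset]
    for cns_path in sorted((cohort_dir / "samples").glob("*.cns")):
        sample_id = cns_path.stem
        segs = read_cns(cns_path, sample_id=sample_id)
        write_seeds_bed(call_seeds(segs, params), seeds_dir / f"{sample_id}.bed")
    logger.info("seed: %.1fs", time.monotonic() - t0)

    # -- classification ------------------------------------------------------
    t0 = time.monotonic()
    samples = load_cohort(cohort_dir, classifier_params)
    bed_dir = outdir / "classified_bed"
    bed_dir.mkdir(exist_ok=True)
    with open(outdir / "classification.tsv", "w") as fh:
        fh.write(
            "sample_id\tamplicon_id\tclass\tn_ecdna_species\tmax_copy_number"
            "\tcomplexity_bits\tamplified_bed_path\n"
        )
        for sample in samples:
            for amp in sample.amplicons:
                amp.complexity_bits = complexity_score(amp.decomposition)
                bed_path = bed_dir / f"{amp.amplicon_id}.bed"
                with open(bed_path, "w") as bed:
                    for iv in amp.amplified_intervals:
                        bed.write(to_bed_line(iv, name=amp.amplicon_id) + "\n")
                fh.write(
                    f"{sample.sample_id}\t{amp.amplicon_id}"
                    f"\t{amp.amplicon_class.label}\t{amp.n_ecdna_species}"
                    f"\t{amp.max_copy_number:g}\t{amp.complexity_bits:.4f}"
                    f"\t{bed_path.name}\n"
                )
    logger.info("classify: %.1fs", time.monotonic() - t0)

    # -- similarity / clonal pairs -------------------------------------------
    t0 = time.monotonic()
    genome = load_genome(cohort_dir)
    pairs = find_clonal_pairs(
        samples, n_null=n_null, seed=config.seed, genome=genome
    )
    with open(outdir / "clonal_pairs.tsv", "w") as fh:
        fh.write(
            "patient_id\tsample_a\tsample_b\tamplicon_a\tamplicon_b"
            "\tgenomic_jaccard\tbreakpoint_jaccard\tscore\tp_value"
            "\tcn_a\tcn_b\thistology_a\thistology_b\tsame_histology\n"
        )
        for p in pairs:
            r = p.result
            fh.write(
                f"{p.patient_id}\t{p.sample_a}\t{p.sample_b}"
                f"\t{r.amplicon_a}\t{r.amplicon_b}"
                f"\t{r.genomic_jaccard:.4f}\t{r.breakpoint_jaccard:.4f}"
                f"\t{r.score:.4f}\t{r.p_value:.6g}"
                f"\t{p.cn_first:g}\t{p.cn_second:g}"
                f"\t{_grade_name(p.histology_first)}"
                f"\t{_grade_name(p.histology_second)}"
                f"\t{p.same_histology}\n"
            )
    logger.info("similarity: %.1fs", time.monotonic() - t0)

    # -- gene calls ----------------------------------------------------------
    t0 = time.monotonic()
    gene_models = load_gene_models(cohort_dir)
    all_amps = [amp for s in samples for amp in s.amplicons]
    calls = []
    for amp in all_amps:
        calls.extend(genes_on_amplicon(amp, gene_models))
    with open(outdir / "gene_calls.tsv", "w") as fh:
        fh.write(
            "amplicon_id\tgene\tmean_copy_number\ton_ecdna"
            "\tis_oncogene\tis_immunomodulatory\n"
        )
        for c in calls:
            fh.write(
                f"{c.amplicon_id}\t{c.gene.name}\t{c.mean_copy_number:.3f}"
                f"\t{c.on_ecdna}\t{c.is_oncogene}\t{c.is_immunomodulatory}\n"
            )
    summary = oncogene_summary(all_amps, calls)
    summary.to_csv(outdir / "oncogene_summary.tsv", sep="\t", index=False,
                   float_format="%.4f")
    logger.info("genes: %.1fs", time.monotonic() - t0)

    # -- cohort statistics ----------------------------------------------------
    t0 = time.monotonic()
    tables = build_association_tables(samples)
    rows = table_report(tables)
    with open(outdir / "stats.tsv", "w") as fh:
        fh.write(
            "table\ta\tb\tc\td\tfisher_p_one_sided\todds_ratio\tci_low"
            "\tci_high\thaldane_applied\n"
        )
        for r in rows:
            fh.write(
                f"{r['table']}\t{r['a']}\t{r['b']}\t{r['c']}\t{r['d']}"
                f"\t{r['fisher_p_one_sided']:.6g}\t{r['odds_ratio']:.4f}"
                f"\t{r['ci_low']:.4f}\t{r['ci_high']:.4f}"
                f"\t{r['haldane_applied']}\n"
            )
    with open(outdir / "stats.json", "w") as fh:
        json.dump(rows, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("stats: %.1fs", time.monotonic() - t0)

    _write_report(outdir, samples, rows, pairs)

    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        design=design,
        config={
            "design": config.design,
            "seed": config.seed,
            "ecdna_cn_median": config.ecdna_cn_median,
            "other_cn_median": config.other_cn_median,
            "cn_escalation_factor": config.cn_escalation_factor,
            "seed_preset": seed_preset,
            "n_null": n_null,
        },
        input_checksums={
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(cohort_dir.rglob("*"))
            if p.is_file()
        },
        outputs=sorted(
            str(p.relative_to(outdir))
            for p in outdir.rglob("*")
            if p.is_file() and p.name != "manifest.json"
        ),
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def _write_report(
    outdir: Path,
    samples: list[CohortSample],
    stat_rows: list[dict],
    pairs,
) -> None:
    """Human-readable run summary (rounding follows the report convention:
    odds ratios and CI bounds to 1 d.p., p-values to 2 s.f.)."""
    n_pos = sum(s.ecdna_positive for s in samples)
    patients = {s.patient_id for s in samples}
    pos_patients = {s.patient_id for s in samples if s.ecdna_positive}
    lines = [
        "focalamp run report",
        "===================",
        f"samples: {len(samples)} ({n_pos} ecDNA-positive)",
        f"patients: {len(patients)} ({len(pos_patients)} ecDNA-positive)",
        "",
        "Association tables (one-sided Fisher, Haldane-corrected OR):",
    ]
    for r in stat_rows:
        lines.append(
            f"  {r['table']}: [[{r['a']},{r['b']}],[{r['c']},{r['d']}]]"
            f"  P = {r['fisher_p_one_sided']:.2g}"
            f"  OR = {r['odds_ratio']:.1f}"
            f" (95% CI {r['ci_low']:.1f}-{r['ci_high']:.1f})"
        )
    lines.append("")
    lines.append(f"clonal ecDNA pairs: {len(pairs)}")
    for p in pairs:
        lines.append(
            f"  {p.patient_id}: {p.sample_a} -> {p.sample_b}"
            f"  score {p.result.score:.2f} (P = {p.result.p_value:.2g})"
            f"  CN {p.cn_first:g} -> {p.cn_second:g}"
            f"  histology {_grade_name(p.histology_first)}"
            f" -> {_grade_name(p.histology_second)}"
        )
    lines.append("")
    lines.append("note: per-test p-values are reported without multiple-testing"
                 " correction")
    with open(outdir / "report.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")
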