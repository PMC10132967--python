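"""Synthetic-cohort generator: determinism, truth consistency, clone model."""

import filecmp
import math

import numpy as np
import pytest

from focalamp.classify import classify_amplicon
from focalamp.graphio import read_cycles_file, read_graph_file
from focalamp.similarity import similarity_score
from focalamp.simulate import (
    GroupSpec,
    SimConfig,
    cambridge_config,
    evolve_clone,
    fhcc_config,
    load_cohort,
    load_truth,
    simulate_cohort,
    simulate_structure,
)
from focalamp.cohort import HistologyGrade


def _tree_identical(a, b):
    cmp = filecmp.dircmp(a, b)

    def walk(c):
        if c.left_only or c.right_only or c.diff_files or c.funny_files:
            return False
        return all(walk(sub) for sub in c.subdirs.values())

    return walk(cmp)


class TestDeterminism:
    def test_same_seed_byte_identical_trees(self, tmp_path):
        simulate_cohort(fhcc_config(9), tmp_path / "a")
        simulate_cohort(fhcc_config(9), tmp_path / "b")
        assert _tree_identical(tmp_path / "a", tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        simulate_cohort(fhcc_config(9), tmp_path / "a")
        simulate_cohort(fhcc_config(10), tmp_path / "c")
        assert not _tree_identical(tmp_path / "a", tmp_path / "c")


class TestEvolveClone:
    def _parent(self, genome, rng):
        g, d, _ = simulate_structure(genome, "ecDNA", rng, "parent", "s0",
                                     n_segments=2)
        return g, d

    def test_identity_limit(self, genome, rng):
        g, d = self._parent(genome, rng)
        cfg = fhcc_config(0)
        cg, cd, w = evolve_clone((g, d), 0, cfg, rng, "child", "s1", noise=False)
        parent_w = d.cyclic_walks()[0].weight
        assert w == parent_w
        pa = classify_amplicon(g, d)
        ca = classify_amplicon(cg, cd)
        assert similarity_score(pa, ca).score > 0.8

    def test_escalation_formula(self, genome, rng):
        g, d = self._parent(genome, rng)
        cfg = fhcc_config(0)
        _, _, w = evolve_clone((g, d), 1, cfg, rng, "child", "s1", noise=False)
        parent_w = d.cyclic_walks()[0].weight
        # weights are reported to 2 d.p.
        assert w == pytest.approx(parent_w * cfg.cn_escalation_factor, abs=0.006)

    def test_child_shares_bases_and_junctions(self, genome, rng):
        g, d = self._parent(genome, rng)
        cfg = fhcc_config(0)
        cg, cd, _ = evolve_clone((g, d), 1, cfg, rng, "child", "s1")
        parent_bases = sum(s.interval.length for s in g.segments)
        shared = sum(
            s.interval.length for s in cg.segments
            if s.interval in {x.interval for x in g.segments}
        )
        assert shared / parent_bases >= 0.8
        shared_edges = set(g.edges) & set(cg.edges)
        assert len(shared_edges) >= len(g.edges) / 2

    def test_non_ecdna_parent_error(self, genome, rng):
        g, d, _ = simulate_structure(genome, "linear", rng, "lin", "s0")
        with pytest.raises(ValueError, match="cyclic"):
            evolve_clone((g, d), 1, fhcc_config(0), rng, "child", "s1")


class TestCohortTruth:
    def test_generated_files_parse_without_warnings(self, fhcc_run, caplog):
        outdir, _ = fhcc_run
        samples_dir = outdir / "cohort" / "samples"
        graph_files = sorted(samples_dir.glob("*_graph.txt"))
        assert graph_files
        with caplog.at_level("WARNING"):
            for gp in graph_files[:40]:
                amp_id = gp.name[: -len("_graph.txt")]
                read_graph_file(gp, amplicon_id=amp_id)
                read_cycles_file(samples_dir / f"{amp_id}_cycles.txt",
                                 amplicon_id=amp_id)
        assert caplog.text == ""

    def test_truth_labels_match_reclassification(self, fhcc_run):
        outdir, _ = fhcc_run
        samples = load_cohort(outdir / "cohort")
        truth = load_truth(outdir / "cohort")
        pred = {
            a.amplicon_id: a.amplicon_class.label
            for s in samples for a in s.amplicons
        }
        assert pred  # non-empty cohort
        mismatches = [t for t in truth if pred.get(t.amplicon_id) != t.true_class]
        assert mismatches == []

    def test_lineage_members_share_segments(self, fhcc_run):
        outdir, _ = fhcc_run
        truth = load_truth(outdir / "cohort")
        by_lineage = {}
        for t in truth:
            if t.lineage_id:
                by_lineage.setdefault(t.lineage_id, []).append(t)
        multi = {k: v for k, v in by_lineage.items() if len(v) > 1}
        assert len(multi) == 8  # the planted clonal lineages
        samples_dir = outdir / "cohort" / "samples"
        for members in multi.values():
            base_sets = []
            for t in members:
                g = read_graph_file(samples_dir / f"{t.amplicon_id}_graph.txt",
                                    amplicon_id=t.amplicon_id)
                base_sets.append(
                    {(s.interval.chrom, s.interval.start) for s in g.segments}
                )
            assert base_sets[0] & base_sets[1]


class TestPrevalenceRecovery:
    def test_planted_group_positivity_within_binomial_ci(self, tmp_path):
        """Patient-level positivity of each arm must sit inside the exact
        binomial 95% CI of the design prevalence (CO 13/40, NCO 1/40)."""
        from scipy.stats import binom

        simulate_cohort(fhcc_config(4), tmp_path)
        samples = load_cohort(tmp_path)
        for group, prev, n in (("CO", 13 / 40, 40), ("NCO", 1 / 40, 40)):
            pos_patients = {
                s.patient_id for s in samples
                if s.group == group and s.ecdna_positive
            }
            n_patients = len({s.patient_id for s in samples if s.group == group})
            assert n_patients == n
            lo, hi = binom.ppf([0.025, 0.975], n, prev)
            assert lo <= len(pos_patients) <= hi

    def test_zero_prevalence_cohort_has_no_ecdna(self, tmp_path):
        cfg = SimConfig(
            seed=2,
            design="generic",
            group_specs={
                "A": GroupSpec(6, 0, HistologyGrade.LGD),
                "B": GroupSpec(6, 0, HistologyGrade.EAC),
            },
        )
        simulate_cohort(cfg, tmp_path)
        samples = load_cohort(tmp_path)
        assert not any(s.ecdna_positive for s in samples)


class TestGenePlanting:
    def test_planted_genes_are_called_and_unplanted_are_not(self, fhcc_run):
        """Genes placed wholly inside amplified ecDNA segments must be called;
        genes outside amplified intervals never are."""
        from focalamp.genes import genes_on_amplicon
        from focalamp.simulate import load_gene_models

        outdir, _ = fhcc_run
        samples = load_cohort(outdir / "cohort")
        truth = {t.amplicon_id: t for t in load_truth(outdir / "cohort")}
        gene_models = load_gene_models(outdir / "cohort")
        by_name = {g.name: g for g in gene_models}
        checked = 0
        for s in samples:
            for amp in s.amplicons:
                calls = {c.gene.name for c in genes_on_amplicon(amp, gene_models)}
                planted = set(truth[amp.amplicon_id].genes_planted)
                # completeness: planted genes sit at amplicon CN >= 4.5 with
                # intact 5' ends by construction
                assert planted <= calls
                # soundness: no call for a gene that never touches the amplicon
                for name in calls:
                    g = by_name[name]
                    assert any(
                        g.interval.overlaps(iv) for iv in amp.amplified_intervals
                    )
                checked += len(planted)
        assert checked > 0
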