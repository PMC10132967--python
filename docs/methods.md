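# Methods

This note documents the models and procedures implemented in `focalamp`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic cohorts do and do not demonstrate.

## Coordinates and file dialects

All internal coordinates are 1-based and inclusive at both ends, matching the
breakpoint-graph and cycles file dialects; BED output converts to 0-based
half-open at the writer boundary only. Graph files are tab-delimited records
(`sequence`, `concordant`, `discordant`); junction endpoint direction `+`
attaches to the head (right end) of the incoming sequence, `-` to the tail.
Cycles files define a segment table and weighted walks; segment id `0` is the
sentinel marking the open ends of a linear walk. Unknown record types are
skipped with a warning rather than rejected, because these dialects have
drifted across tool versions; malformed coordinates, negative copy counts,
undefined segment references and duplicate segment ids are hard errors that
name the offending line. Writers emit deterministic ordering (segments by
coordinate, walks by descending weight), so write∘read is a fixed point.

Discordant-edge endpoints must coincide with a segment boundary within 1 bp:
these files come from a graph builder, not raw variant calls, so larger
disagreement indicates a corrupt file rather than measurement jitter.

## Seed detection

Copy-number segments with total CN strictly greater than `cn_min` are merged
across same-chromosome gaps of at most `merge_gap` (default 300 kbp), and
merged intervals with length strictly greater than `size_min` become seeds —
filter, merge, then size-select, in that order, with the size filter applied
to the *merged* interval. Both thresholds are exclusive. Cohort presets:
`cambridge` 4.5 / 10 kbp, `tcga` 4.5 / 50 kbp, `fhcc_tumour` 4.3 / 50 kbp,
`fhcc_normal` 4.0 / 10 kbp. The merge gap is not dictated by any of the
presets; 300 kbp joins fragmented segment calls over one amplicon without
fusing independent events, and it is configurable.

## Classification cascade

The published upstream classifier's exact heuristics are not reproduced here;
the cascade below is this package's own operationalisation of the four
classes, validated against synthetic ground truth (≥ 95 % label recovery is a
tested contract):

1. **ecDNA** — there is a cyclic walk with weight ≥ `cn_min` (default 4.5)
   whose footprint covers ≥ `ecdna_cycle_weight_min` (default 0.5) of the
   amplified bases, *or* the summed weight of cyclic walks overlapping the
   amplified region reaches `cn_min`. A circular structure at amplified copy
   number is the operative signature of ecDNA.
2. **BFB** — otherwise, if at least 2 foldback junctions (intra-chromosomal,
   same-side endpoints within `foldback_dist_max` = 25 kbp) carry
   ≥ `foldback_frac_min` (default 0.25) of the discordant copy-count weight.
   Foldback inversions with a stepwise copy-number ladder are the
   breakage–fusion–bridge signature.
3. **complex non-cyclic** — otherwise, if ≥ `complex_edge_min` (default 3)
   discordant edges touch the amplified intervals.
4. **linear** — everything else that passed seeding.

`n_ecdna_species` counts overlap-connected clusters of qualifying cyclic
walks whose footprints are disjoint between clusters — two genomically
disjoint circles in one amplicon are two ecDNA species. Deduplication keeps,
per overlap-connected component of amplified regions, the amplicon with the
best class rank (ecDNA > BFB > complex > linear), ties broken by largest
amplified length, then lexicographic id; it is idempotent and order-free.

## Similarity and clonality

The similarity score of two classified amplicons is the mean of a genomic
Jaccard (base-level overlap of amplified interval sets) and a breakpoint
Jaccard (one-to-one matching of discordant junctions with both endpoint
positions within `tol` = 100 bp and matching sides, allowing whole-edge
swap); when either amplicon has no discordant edge the score is the genomic
Jaccard alone. Equal weighting of the two components is this package's
choice — the components are isolated behind one function so alternative
combinations can be swapped, and scores should not be compared against other
implementations' values. Junction matching is greedy in coordinate order;
on unambiguous instances this attains the maximum bipartite matching (a
tested property).

Significance is empirical: the observed score is compared against scores of
amplicon pairs drawn from *different* patients, p = (1 + #{null ≥ obs}) /
(n_null + 1). When fewer cross-patient pairs exist than requested
replicates, the null is topped up by placing interval sets of matched
lengths uniformly on the genome. Cross-patient pairs are preferred because
they inherit the realistic size and location distribution of amplicons in
the cohort. Pair p-values are reported raw (no multiple-testing
correction), matching the per-pair reporting convention of this analysis
family; a Benjamini–Hochberg flag can be layered on the output table.

A clonal pair is a within-patient pair of ecDNA amplicons from different
samples with genomic overlap > 0 and p < 0.05. Pairs are oriented so the
second member carries the more severe histology (windowed histology
preferred, then on-level), making the copy-number delta interpretable as
change along disease progression.

## Complexity

Amplicon complexity is the Shannon entropy (base 2) of the normalised
positive decomposition weights: 0 bits for a single structure, log₂ k for k
equal-weight structures. It is scale- and permutation-invariant. The
published score additionally involves decomposition residuals, which this
package omits; values are in bits and comparable only within this package.

## Gene calls

A gene is called on an amplification when (i) the length-weighted mean copy
number over the gene body is ≥ 4.5, counting uncovered bases as diploid
(CN 2, a conservative default for partial overlap), and (ii) the 5′ end is
intact: the 5′-most base lies in an amplified interval and no discordant
junction endpoint falls strictly inside the first 1 kbp of the gene from the
5′ end. The 1-kbp window operationalises "5′ end intact" — the criterion is
stated in the field without an operational window — and is configurable.
Length weighting (rather than segment-mean averaging) is used because it
equals the per-base average, which is the tested oracle.

## Cohort statistics

Two-by-two tables follow a fixed orientation: row 1 = more-advanced/exposed
group, column 1 = event present, so one-sided Fisher tests are upper-tailed
in cell *a*. Odds ratios use the Haldane correction (add 0.5 to every cell
if and only if some cell is zero) and Woolf confidence intervals (normal
approximation on log OR with SE = √(1/a + 1/b + 1/c + 1/d) over the possibly
corrected cells); the Woolf interval is used because it is the standard
closed-form interval for corrected tables, with the exact conditional
interval available as an alternative. Mann–Whitney uses exact enumeration
for tie-free pooled samples of ≤ 12 and the tie-corrected normal
approximation otherwise; Levene's test uses absolute deviations from group
means. Fisher p-values are verified in the tests against an independent
exact-rational enumeration over all tables with fixed margins.

Histology pairing: a sequencing biopsy gets on-level histology from records
at exactly its oesophageal level and windowed histology from records within
±1 cm (inclusive); in either case the most severe grade is assigned, and the
attribute is absent when no record qualifies.

## Synthetic cohorts

The generator emulates the two study designs on a toy genome of 4
chromosomes × 10 Mb carrying 60 planted 20-kb genes (12 oncogenes, 6
immunomodulatory) — small enough that every derived quantity can be checked
against per-base brute force.

Structure archetypes: ecDNA = 1–6 segments joined into a closed cycle at
log-normal copy number (median 15); BFB = a three-segment ladder with two
terminal foldback junctions and stepwise CN; complex = three segments with
three non-foldback rearrangement junctions and only linear walks; linear =
one amplified run with no discordant edges. Non-ecDNA amplifications draw
copy number around a lower median (8), so copy-number contrasts between
ecDNA and other amplifications hold stochastically at cohort scale.
Rearrangement steps per histology grade (HGD 1, EAC 2) add low-weight
decomposition variants, raising entropy with disease stage.

Clonal evolution: a child ecDNA keeps all parental segments and junctions,
multiplies its weight by `cn_escalation_factor`^grade_delta (default 1.5)
with small multiplicative noise (σ = 0.05 on the log scale), and, when the
grade advanced, splices one small extra segment into a secondary
decomposition variant.

Cohort allocation is deterministic: each arm receives exactly its designed
number of ecDNA-positive patients (e.g. 13/40 case vs 1/40 control in the
longitudinal design; 0/42, 1/25, 13/51, 38/88 across the cross-sectional
groups), and sample-level histology pairings are planted so the association
tables are reproduced exactly rather than in expectation. Deterministic
allocation keeps the planted counts inside the exact binomial intervals of
the corresponding prevalences while making end-to-end table reproduction a
sharp, testable contract. All stochastic choices flow from one master seed
through per-entity sub-seeds derived by stable label hashing (CRC32), so a
fixed seed yields byte-identical output trees.

What the synthetic cohorts do **not** emulate: read-level data, sequence
content, purity/ploidy variation, germline CNV background, segmentation
noise in the `.cns` tables, and upstream graph-inference errors. Passing
recovery tests therefore demonstrates the internal consistency of the
pipeline and the sharpness of its contracts on clean inputs, not classifier
performance on real sequencing data.

## Problem sizes

Default runs use the full designed cohorts (80 patients × 4 samples
longitudinal; 206 patients cross-sectional), 100–300 structures for recovery
checks, and 100–500 null replicates for similarity p-values; a complete
pipeline run takes about a second on one core, so no analysis in this
package required scaling down.

## Known limitations

* The classification cascade and the similarity-score combination rule are
  this package's conventions; numeric agreement with other implementations'
  scores is not expected.
* Concordant edges are parsed and preserved but unused by the classifier.
* The complexity score ignores decomposition residuals.
* No purity dilution knob in the generator: copy numbers are clonal.
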