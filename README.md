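# spliceburden

Quantifying the transcriptome-wide splicing burden that appears when the
spliceosome is impaired — for example when a splicing factor is depleted by
shRNA and cells are simultaneously stressed with cisplatin. The package is
aimed at RNA-seq analysts who want gene-level intron-retention estimates and
event-level inclusion quantification with explicit, testable semantics, plus
a spliced-read simulator that provides ground truth for every statistic it
reports.

## What it computes

**Gene-level intron retention.** For each protein-coding gene (level 1–2
annotations, *gene* and *exon* features only), fragments are counted under
intersection-strict containment on two layers: *exonic* (every aligned block
inside the flattened union of all annotated exons of exactly one gene) and
*genic* (every block inside exactly one gene's extent). The difference

&nbsp;&nbsp;&nbsp;&nbsp;intronic(g, s) = genic(g, s) − exonic(g, s)

is a conservative count of fragments touching intronic sequence. Genes with
genic < exonic in any sample (extent overlaps with neighbours) or with a
zero exonic count in any sample are discarded; per-gene ratios
intronic/exonic, averaged over replicates within a condition, are compared
between conditions with a paired Wilcoxon signed-rank test, and per-sample
intronic/exonic totals with a Welch t-test. An expression-stratified variant
localizes the shift across the expression range.

**Event-level inclusion (ψ).** Skipped-exon (SE), retained-intron (RI),
alternative 5′/3′ splice-site (A5SS/A3SS) and mutually-exclusive-exon (MXE)
events are enumerated from pairwise transcript comparisons. Inclusion (I)
and skipping (S) support comes from fragments whose junctions match the
defining junctions exactly, plus fragments unique to the inclusion form
("junctions + reads on target"); the inclusion level is the
length-normalized fraction

&nbsp;&nbsp;&nbsp;&nbsp;ψ = (I/lI) / (I/lI + S/lS),

with effective lengths lI, lS computed by exact enumeration of supporting
fragment placements (or by a fixed junction-count convention). Two-condition
comparisons report ΔΨ (difference of replicate-mean ψ), a pooled two-sided
Fisher exact p, Benjamini–Hochberg q, and the significance rule
q < 5% ∧ |ΔΨ| ≥ 20%.

**Normalization and candidate-gene folds.** Median-of-ratios size factors,
fold changes as ratios of mean normalized counts, and the 2×2 interaction
ratio (depleted+drug/depleted) / (control+drug/control), which is 1 when
depletion and drug act without interaction.

**Simulation.** `spliceburden.simulate` generates non-overlapping gene
models on a synthetic chromosome plus N-gapped paired-end SAM alignments
(73-nt mates) under the 4-condition × 3-replicate design (C, Ccis, D, Dcis),
with per-gene NB expression, per-condition intron-retention fractions and
per-event ψ — all recorded in a truth table. Named presets reproduce
candidate-gene topologies: `sat1` (7 exons, skippable exon 4), `nupr1`
(2 exons, retainable intron 1), `noxa1` (11 exons, retainable introns
9 and 10).

## Worked example

Candidate-gene fold recovery — simulate NB counts for the full 2×2×3 design
in which cisplatin induces the target 5.6-fold in control cells but only
1.5-fold in depleted cells, then re-estimate both folds from the counts:

```python
from spliceburden import simulate_nupr1_counts, size_factors, fold_change

counts, design = simulate_nupr1_counts(seed=1)   # 1 target + 1000 background genes
f = size_factors(counts)
print(round(fold_change(counts, f, "NUPR1SIM", "C", "Ccis", design).fold, 2))
print(round(fold_change(counts, f, "NUPR1SIM", "D", "Dcis", design).fold, 2))
```

prints (seed 1)

```
5.38
1.28
```

— single-seed estimates of the 5.6 and 1.5 presets; the median over 100
seeds lands at 5.70 and 1.52 (see below). A full pipeline run on simulated
reads:

```sh
spliceburden all --outdir demo --seed 1
```

simulates 200 genes × 12 samples (~200,000 fragments each), counts,
filters and tests. `demo/retention_tests.tsv` then contains

```
comparison     stratum  n_genes  statistic  p_value       median_difference  method
Dcis_vs_Ccis   all      199      0.0        2.1e-34       0.0496             approx
```

the depletion-under-cisplatin retention shift: the default simulation adds
Δr = 0.10 to every gene's retention fraction in Dcis, and the per-gene
median ratio difference recovers ~0.05 of extra intronic coverage per
exonic read, overwhelmingly significant across 199 genes.
`demo/retention_totals.tsv` shows per-sample intronic fractions rising from
~0.026 (C) to ~0.079 (Dcis).

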