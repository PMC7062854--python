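# Methods

## Scope and model

The package quantifies the splicing burden of a transcriptome from spliced
paired-end alignments in three complementary ways: (1) a gene-level,
annotation-anchored intron-retention estimate built from strict feature
counting; (2) event-level inclusion quantification for the five classical
alternative-splicing categories; (3) library-size normalization and
candidate-gene fold-change point estimates. A read simulator with complete
ground truth ties the three together so that every downstream statistic can
be validated by parameter recovery.

All coordinates are 0-based half-open internally; GTF's 1-based inclusive
convention is converted at the boundary.

## Gene models

Annotation is restricted to a configurable biotype set (default
`protein_coding`) and a maximum annotation confidence level (default 2,
i.e. verified or manually annotated loci); genes whose `level` attribute is
missing are excluded when a maximum level is in force, because their
confidence cannot be verified. Only *gene* and *exon* features are read.

The exonic region of a gene is the flattened union of **all** exons of
**all** its transcripts — deliberately the most comprehensive exonic
definition, which makes the intronic estimate conservative. Introns are the
complement of this union within the gene extent, which is taken from the
annotated *gene* feature when present (configurable to the exon span;
where the two disagree the extent is their union so that exons are never
outside the extent). Exon union and introns tile the extent exactly; this
invariant is property-tested.

## Strict fragment counting

The counting unit is the fragment (read pair); mates' aligned M-blocks are
unioned before any containment test, and junctions are taken from N
operations in the CIGAR. Secondary, supplementary and unmapped records are
skipped; duplicates are kept; unpaired leftovers are counted from the
available mate and tallied as singletons.

A fragment is assigned to a gene on a layer (exon union or extent) only if
every block lies entirely within that gene's feature set and the gene is
the *unique* such candidate after strand filtering — the intersection-strict
rule. Unassigned fragments carry a reason code (`no_feature`, `ambiguous`,
`not_contained`). The default library protocol is `reverse` (dUTP-stranded:
read 2 carries the transcript strand), overridable to `forward` or
`unstranded`.

`intronic = genic − exonic` per gene and sample. Where gene extents overlap
(e.g. a gene nested in another's intron), extent-level assignment is
ambiguous while exon-level assignment may remain unique, so genic can fall
below exonic; such entries are preserved and flagged, never clamped,
because the retention-stage filter acts on the flags. Counting mates
independently rather than as fragments was considered and rejected: the
fragment is the sampling unit of the library, and mate-level counting
double-counts fragments whose mates both touch the same feature.

## Retention analysis

Two gene filters precede any ratio: (a) genes flagged genic < exonic in any
sample are discarded; (b) genes with zero reads in any sample are
discarded. Filter (b) is applied on the exonic layer by default because the
exonic count is the denominator of the retention ratio; a genic-layer
variant with a pseudocount is exposed for sensitivity analysis.

Per-gene ratios intronic/exonic are averaged arithmetically over the
replicates of a condition. The between-condition test is a paired
(per-gene) Wilcoxon signed-rank test on condition-mean ratio differences:
zero differences are dropped, the exact null distribution is used for
n ≤ 25 tie-free pairs, and the normal approximation with tie and continuity
correction otherwise. Two-sided by default; a one-sided alternative is a
flag. Global burden is summarized per sample as
total_intronic/(total_intronic + total_exonic) over retained genes and
compared between conditions with a Welch two-sided t-test on the fractions
(raw totals are reported alongside, since a totals-based test is an equally
defensible reading). The expression-stratified variant ranks genes by mean
exonic count over all samples, splits them into equal-size strata and runs
the paired test per stratum; strata with fewer than two genes are skipped
with a warning.

## Events and ψ

Events are enumerated from ordered pairs of transcripts within a gene:

- **SE** — an internal exon flanked by two junctions in one transcript and
  bridged by the single junction joining its neighbours in the other.
- **RI** — a junction of one transcript contiguously covered by an exon of
  the other; the intron is the inclusion body.
- **A5SS/A3SS** — two junctions sharing one end; the inclusion form is the
  longer exon, and the extension must be contiguously exonic in the
  inclusion transcript and absent from the skipping one (this guard stops
  SE transcript pairs from masquerading as alternative splice sites).
  Categories follow the gene strand.
- **MXE** — two mutually non-overlapping exons, each bridged by the other
  form, sharing the flanking donor and acceptor; the leftmost exon defines
  the inclusion form.

Duplicates (same category and junction sets) are reported once.

Support counting is "junctions + reads on target": a fragment supports
inclusion if any of its junctions equals an inclusion junction exactly or
any block lies entirely within an inclusion-body interval; it supports
skipping if any junction equals a skipping junction. For RI, skipping
requires the exact spliced junction, and a contiguous read fully inside the
intron is inclusion-body support (a boundary-straddling read is not
counted, since flanking-exon sequence is shared between forms under
gene-level retention). Fragments supporting both forms — possible with
discordant mates — are discarded and tallied.

ψ = (I/lI) / (I/lI + S/lS). Effective lengths come in two modes:

- `placement` (default): exact enumeration of every fragment placement on a
  representative transcript of each form at the nominal read and fragment
  length, counting placements that the support rules above would call for
  that form, expressed in units of 2·(read_length − 1) (one junction's
  worth of placements for a pair). For SE with long flanking exons this
  reduces to the 2:1 junction convention; for RI it calibrates the body
  term that a fixed convention can only approximate. Under the simulator's
  sampling model (isoform weight ∝ inclusion level × placement count, start
  uniform) this estimator is unbiased, which is what the ψ-recovery tests
  exercise.
- `junction-count`: the fixed convention (SE 2:1, A5SS/A3SS 1:1, MXE 2:2,
  RI (1 + body/read_length):1), for comparability with junction-based
  pipelines.

Comparisons pool I and S per condition into a 2×2 table, use a two-sided
Fisher exact test and Benjamini–Hochberg correction across evaluated
events, and flag significance at q < 0.05 ∧ |ΔΨ| ≥ 0.20 where ΔΨ is the
difference of replicate-mean ψ. This pooled exact test is a deliberate,
documented substitute for the hierarchical replicate-aware likelihood model
of dedicated event tools, which is out of scope; it treats replicates as
exchangeable and will be anti-conservative under strong between-replicate
overdispersion. The per-category summary reports total evaluated events and
counts of significantly lower/higher inclusion.

## Normalization and folds

Size factors follow the median-of-ratios definition: using only genes with
positive counts in every sample, factor(s) = median_g count(g,s)/geomean(g).
No pseudocount is applied by default. Fold changes are ratios of mean
normalized counts between conditions; the interaction ratio is
(Dcis/D)/(Ccis/C). These are raw point estimates: no dispersion estimation,
Wald testing or shrinkage, so folds for weakly expressed genes are noisier
than shrunk estimates from a full differential-expression fit. A filter
utility applies the q < 0.05 and ≥ twofold rule to externally supplied
q-values.

## Simulator

The simulator emulates the study design — four conditions (C, Ccis, D,
Dcis) × three replicates, paired-end 73-nt mates — at desk scale, with
defaults: 200 genes, 200,000 fragments per sample, NB dispersion 0.05,
fragment length ~ Normal(250, 30) truncated to [read_length, isoform
length] (typical short-insert library values; drawn lengths beyond an
isoform are truncated rather than resampled, which preserves the uniform
start law the ψ estimator assumes), lognormal relative gene abundances
(σ = 1), baseline retention r = 0.05, and an additive depletion effect on
retention of Δr = 0.05 without drug and Δr = 0.10 under cisplatin. The
effect sizes are design choices of the generator, exposed in the config —
not claims about any real dataset.

Per sample, per-gene fragment counts use the Poisson–Gamma construction
(rate ~ Gamma(1/α, μα), count ~ Poisson), giving exact NB marginals while
keeping per-sample totals Poisson-consistent with the configured library
size. Per fragment, with probability r the gene's pre-mRNA-like copy
retaining one uniformly chosen annotated intron is used; otherwise an
annotated isoform is chosen with probability ∝ inclusion level × placement
count. Reads are alignment records only (SEQ is poly-A, QUAL constant):
downstream stages consume coordinates and CIGARs. One RNG stream per sample
is derived from (seed, CRC32(sample_id)), so samples are independent and
reruns are byte-identical.

A structural point: the gene-level intronic estimate is defined relative to
the flattened exon union, so a gene whose retained-intron isoform is
*annotated* has no flattened intron there and contributes nothing to
gene-level retention. The simulator therefore annotates variant isoforms
only for genes that carry events (the presets, and background genes given a
skipped exon), while background-gene retention is modeled as incomplete
splicing of annotated introns. This mirrors real annotation, where most
incomplete splicing is unannotated while curated retained-intron
transcripts exist for some loci.

What the simulator does not emulate: sequence content and sequencing error,
mappability artifacts, positional (5′/3′) coverage bias, correlated
expression between genes, and annotation errors. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
sampling model, not robustness to alignment or annotation pathologies.

## Numerical and design choices

- Interval indexing uses an interval tree over gene extents; containment
  tests use binary search over the sorted disjoint feature arrays.
  Equivalence with a brute-force scan is property-tested.
- Wilcoxon: SciPy's implementation, with the exact/approx switch described
  above; exact enumeration of sign assignments is kept as an independent
  test oracle for n ≤ 12.
- BH: statsmodels' `multipletests`, checked against a direct step-up
  computation in tests.
- Size factors are implemented directly (the definition is six lines) and
  cross-checked against the reference median-ratio implementation in a
  test.
- SAM records are written as text by the simulator (they are constructed,
  not parsed) and always read back through pysam.
- Desk-scale problem sizes used by the test suite: the transcriptome-wide
  retention check runs 10,000 genes × 12 samples × 200,000 fragments;
  ψ recovery uses ~50,000 fragments per event; fold recovery uses 100 seeds
  of a 1,001-gene count matrix. These sizes keep full runs in the minutes
  range on a single CPU while leaving Monte-Carlo error well inside the
  stated tolerances.
- Config-level overrides for per-gene expression folds, per-event ψ and
  per-gene retention are API-level dictionaries keyed by (id, condition);
  the YAML pipeline config does not expose them.

## Known limitations

- The pooled event test ignores replicate structure (see above).
- ψ effective lengths in `placement` mode assume the nominal fragment
  length; strong insert-size dispersion shifts lI/lS slightly (second-order
  at the defaults).
- Gene-level retention cannot localize which intron is retained; that is
  the role of RI events.
- Fold estimates are unshrunk ratios; for genes with very low counts they
  are unstable, and the candidate-gene recovery targets use a
  well-expressed target (mean 500) for that reason.
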