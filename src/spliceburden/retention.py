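"""Gene-level intron-retention analysis.

Applies the two gene filters (genic < exonic in any sample; zero reads in
any sample), computes per-gene intronic/exonic ratios and their
condition-averaged means, tests for a transcriptome-wide retention shift
between conditions with a paired Wilcoxon signed-rank test, and summarizes
global intronic vs exonic read totals with a Welch t-test. An
expression-stratified variant of the paired test localizes where in the
expression range a shift is detectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counting import CountMatrix
from .design import SampleDesign, condition_label, samples_of

log = logging.getLogger(__name__)


@dataclass
class DiscardReport:
    n_input: int
    n_flagged: int  # genic < exonic in any sample
    n_zero: int  # zero reads on the filter layer in any sample
    n_retained: int

    @property
    def fraction_flagged(self) -> float:
        return self.n_flagged / self.n_input if self.n_input else 0.0

    @property
    def fraction_zero(self) -> float:
        return self.n_zero / self.n_input if self.n_input else 0.0


def filter_genes(
    matrix: CountMatrix, layer: str = "exonic"
) -> tuple[CountMatrix, DiscardReport]:
    """Drop genes flagged genic<exonic in any sample, then genes with a zero
    on the filter layer (default exonic — the ratio's denominator) in any
    sample."""
    if not matrix.samples:
        raise ValueError("count matrix has no samples")
    if layer not in ("exonic", "genic"):
        raise ValueError("filter layer must be 'exonic' or 'genic'")
    flagged = matrix.flagged.any(axis=1)
    counts = getattr(matrix, layer)
    zero = (counts == 0).any(axis=1) & ~flagged
    keep = ~flagged & ~zero
    report = DiscardReport(
        n_input=len(matrix.genes),
        n_flagged=int(flagged.sum()),
        n_zero=int(zero.sum()),
        n_retained=int(keep.sum()),
    )
    return matrix.subset(keep), report


def gene_ratio_table(
    matrix: CountMatrix,
    design: Sequence[SampleDesign] | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-gene per-sample intronic/exonic ratios (tidy frame).

    The filter contract guarantees exonic ≥ 1 for every retained gene; a
    pseudocount is only needed for the genic-layer filter variant.
    """
    design = list(design) if design is not None else list(matrix.design)
    exonic = matrix.exonic.astype(float) + pseudocount
    if pseudocount == 0.0 and (exonic == 0).any():
        raise RuntimeError(
            "exonic count of 0 encountered; run filter_genes first or use a pseudocount"
        )
    ratios = (matrix.intronic + pseudocount) / exonic
    df = pd.DataFrame(ratios, index=matrix.genes, columns=matrix.samples)
    df.index.name = "gene_id"
    return df


def condition_means(
    ratio_table: pd.DataFrame, design: Sequence[SampleDesign]
) -> pd.DataFrame:
    """Arithmetic mean of per-replicate ratios within each condition."""
    out = {}
    for d in design:
        out.setdefault(condition_label(d), []).append(d.sample_id)
    return pd.DataFrame(
        {cond: ratio_table[cols].mean(axis=1) for cond, cols in out.items()}
    )


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    median_difference: float
    n_pairs: int
    method: str


def paired_retention_test(
    cond_means: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    alternative: str = "two-sided",
) -> PairedTestResult:
    """Paired Wilcoxon signed-rank test on per-gene ratio differences B − A.

    Zero differences are dropped (Wilcoxon convention). The exact null
    distribution is used for n ≤ 25 without ties; otherwise the normal
    approximation with tie and continuity correction.
    """
    for c in (condition_a, condition_b):
        if c not in cond_means.columns:
            raise ValueError(f"condition {c!r} absent from the ratio table")
    diff = (cond_means[condition_b] - cond_means[condition_a]).to_numpy(float)
    diff = diff[~np.isnan(diff)]
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        raise ValueError(
            "all paired differences are zero; the signed-rank test is undefined"
        )
    use_exact = nonzero.size <= 25 and np.unique(np.abs(nonzero)).size == nonzero.size
    method = "exact" if use_exact else "approx"
    res = stats.wilcoxon(
        nonzero,
        zero_method="wilcox",
        correction=True,
        alternative=alternative,
        method=method,
    )
    return PairedTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_difference=float(np.median(diff)),
        n_pairs=int(nonzero.size),
        method=method,
    )


@dataclass
class GlobalTotals:
    per_sample: pd.DataFrame  # sample_id, condition, total_intronic, total_exonic, fraction
    t_statistic: float
    p_value: float


def global_totals(
    matrix: CountMatrix,
    design: Sequence[SampleDesign],
    condition_a: str,
    condition_b: str,
) -> GlobalTotals:
    """Per-sample intronic/exonic totals over retained genes and a Welch
    two-sided t-test on the per-replicate intronic fraction."""
    rows = []
    for d in design:
        j = matrix.samples.index(d.sample_id)
        ti = int(matrix.intronic[:, j].sum())
        te = int(matrix.exonic[:, j].sum())
        rows.append(
            {
                "sample_id": d.sample_id,
                "condition": condition_label(d),
                "total_intronic": ti,
                "total_exonic": te,
                "intronic_fraction": ti / (ti + te) if ti + te else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    fa = df.loc[df["condition"] == condition_a, "intronic_fraction"].to_numpy()
    fb = df.loc[df["condition"] == condition_b, "intronic_fraction"].to_numpy()
    if fa.size < 2 or fb.size < 2:
        raise ValueError("each compared condition needs >= 2 replicates")
    if np.ptp(np.concatenate([fa, fb])) == 0:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(fb, fa, equal_var=False)
    return GlobalTotals(per_sample=df, t_statistic=float(t), p_value=float(p))


@dataclass
class StratumResult:
    stratum: int
    n_genes: int
    result: PairedTestResult | None


def stratify_by_expression(
    ratio_table: pd.DataFrame,
    matrix: CountMatrix,
    design: Sequence[SampleDesign],
    condition_a: str,
    condition_b: str,
    n_strata: int = 4,
) -> list[StratumResult]:
    """Paired tests within equal-size strata of mean exonic expression.

    Stratum 0 holds the lowest-expressed genes. Strata with fewer than two
    genes are skipped with a warning.
    """
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    mean_expr = pd.Series(
        matrix.exonic.mean(axis=1), index=matrix.genes
    ).loc[ratio_table.index]
    order = mean_expr.sort_values(kind="mergesort").index
    cm = condition_means(ratio_table, design)
    results = []
    for k, idx in enumerate(np.array_split(np.asarray(order), n_strata)):
        if idx.size < 2:
            log.warning("stratum %d has %d genes; skipped", k, idx.size)
            results.append(StratumResult(k, int(idx.size), None))
            continue
        res = paired_retention_test(cm.loc[idx], condition_a, condition_b)
        results.append(StratumResult(k, int(idx.size), res))
    return results


def retention_scatter(
    cond_means: pd.DataFrame, condition_a: str, condition_b: str, path: str
) -> None:
    """Log-log per-gene scatter of condition-mean ratios with identity axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = cond_means[condition_a].to_numpy() + 1e-3
    y = cond_means[condition_b].to_numpy() + 1e-3
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.loglog(x, y, ".", markersize=2, alpha=0.4)
    lim = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax.plot(lim, lim, "r-", linewidth=0.8)
    ax.set_xlabel(f"intronic/exonic ratio, {condition_a}")
    ax.set_ylabel(f"intronic/exonic ratio, {condition_b}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
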