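"""Library-size normalization and candidate-gene fold-change estimates.

Size factors use the median-of-ratios method: for genes with positive
counts in every sample, each sample's factor is the median ratio of its
counts to the per-gene geometric means. Fold changes are ratios of mean
normalized counts between conditions; the interaction ratio is the fold of
folds across the 2×2 depletion × drug design,
(depleted+drug / depleted) / (control+drug / control), equal to 1 when the
two factors act purely multiplicatively with no interaction.

Only point estimates live here — dispersion estimation, Wald tests and
shrinkage belong to dedicated differential-expression packages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import SampleDesign, samples_of


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    Raises when no gene is positive in every sample; filter low-count genes
    or add a pseudocount upstream in that case.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; "
            "filter genes or add a pseudocount before computing size factors"
        )
    log_counts = np.log(mat[positive])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_counts - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


@dataclass
class FoldChangeEstimate:
    gene_id: str
    condition_a: str
    condition_b: str
    mean_a: float
    mean_b: float
    fold: float | None  # None when the denominator mean is zero


def fold_change(
    counts: pd.DataFrame,
    factors: pd.Series,
    gene: str,
    condition_a: str,
    condition_b: str,
    design: Sequence[SampleDesign],
) -> FoldChangeEstimate:
    """Ratio of mean normalized counts, condition B over condition A."""
    normed = normalize(counts, factors)
    a_cols = samples_of(design, condition_a)
    b_cols = samples_of(design, condition_b)
    if not a_cols or not b_cols:
        raise ValueError("both conditions need at least one replicate")
    mean_a = float(normed.loc[gene, a_cols].mean())
    mean_b = float(normed.loc[gene, b_cols].mean())
    fold = mean_b / mean_a if mean_a > 0 else None
    return FoldChangeEstimate(gene, condition_a, condition_b, mean_a, mean_b, fold)


def interaction_ratio(
    counts: pd.DataFrame,
    factors: pd.Series,
    gene: str,
    design: Sequence[SampleDesign],
) -> float | None:
    """(Dcis/D) / (Ccis/C): drug response in depleted over control cells."""
    depleted = fold_change(counts, factors, gene, "D", "Dcis", design)
    control = fold_change(counts, factors, gene, "C", "Ccis", design)
    if depleted.fold is None or control.fold is None or control.fold == 0:
        return None
    return depleted.fold / control.fold


def significant_changes(
    table: pd.DataFrame,
    q_column: str = "q",
    fold_column: str = "fold",
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Filter an externally tested table to q < alpha and ≥ min_fold change
    in either direction (the magnitude filter applied to |log fold|)."""
    q = table[q_column]
    fold = table[fold_column]
    keep = (q < alpha) & ((fold >= min_fold) | (fold <= 1.0 / min_fold))
    return table[keep]
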