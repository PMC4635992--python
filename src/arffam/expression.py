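"""qRT-PCR expression analysis: 2^-ddCt fold changes, reference-scaled
profiles, log2 heatmap matrices, 2x significance calls, and abundance /
tissue-specificity summaries.

All computations start from a long-format :class:`~arffam.io.CtTable`. The
delta-Ct of a target gene in a condition is ct_target - ct_reference; by
default replicates are paired by replicate index and the delta-Ct is averaged
across replicates afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CtTable

__all__ = [
    "ExpressionValue",
    "relative_expression",
    "expression_matrix",
    "ddct_fold_change",
    "significance_flag",
    "replicate_ttest",
    "heatmap_matrix",
    "abundance_share",
    "tissue_specificity",
]


@dataclass
class ExpressionValue:
    gene: str
    condition: str
    rel_expr: float
    n_reps: int
    sd: float


def _delta_ct(ct: CtTable, gene: str, condition: str, paired: bool = True) -> np.ndarray:
    target = ct.ct_values(gene, condition)
    ref = ct.ct_values(ct.reference_gene, condition)
    if paired:
        shared = target.index.intersection(ref.index)
        if len(shared) == 0:
            raise ValueError(
                f"{gene}/{condition}: no shared replicate indices with reference"
            )
        return (target.loc[shared] - ref.loc[shared]).to_numpy(float)
    return target.to_numpy(float) - ref.to_numpy(float).mean()


def relative_expression(
    ct: CtTable,
    gene: str,
    condition: str,
    scale: float = 1000.0,
    paired: bool = True,
) -> ExpressionValue:
    """Reference-scaled expression: per replicate, scale * 2^-(dCt);
    mean and sd over replicates.

    With scale = 1000 a target as abundant as the reference reads 1000.
    """
    dct = _delta_ct(ct, gene, condition, paired)
    values = scale * np.exp2(-dct)
    return ExpressionValue(
        gene=gene,
        condition=condition,
        rel_expr=float(values.mean()),
        n_reps=len(values),
        sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
    )


def expression_matrix(
    ct: CtTable,
    scale: float = 1000.0,
    paired: bool = True,
) -> pd.DataFrame:
    """Gene x condition matrix of mean reference-scaled expression."""
    data = {
        cond: {
            gene: relative_expression(ct, gene, cond, scale, paired).rel_expr
            for gene in ct.genes
        }
        for cond in ct.conditions
    }
    return pd.DataFrame(data, index=ct.genes, columns=ct.conditions)


def ddct_fold_change(
    ct: CtTable,
    gene: str,
    condition_test: str,
    condition_control: str,
    paired: bool = True,
) -> float:
    """Comparative 2^-ddCt fold change of test over control.

    ddCt = mean dCt(test) - mean dCt(control); the result equals the ratio of
    the reference-scaled expressions up to floating error.
    """
    ddct = _delta_ct(ct, gene, condition_test, paired).mean() - _delta_ct(
        ct, gene, condition_control, paired
    ).mean()
    return float(2.0 ** (-ddct))


def significance_flag(fold: float, cutoff: float = 2.0) -> str:
    """Fixed fold-change rule: up iff fold >= cutoff, down iff fold <= 1/cutoff
    (boundary inclusive), else unchanged."""
    if fold <= 0 or not math.isfinite(fold):
        raise ValueError(f"fold change must be positive and finite, got {fold}")
    if fold >= cutoff:
        return "up"
    if fold <= 1.0 / cutoff:
        return "down"
    return "unchanged"


def replicate_ttest(
    ct: CtTable,
    gene: str,
    condition_test: str,
    condition_control: str,
) -> float:
    """Secondary significance evidence: Welch t-test p-value comparing
    replicate-level delta-Ct between the two conditions."""
    a = _delta_ct(ct, gene, condition_test, paired=True)
    b = _delta_ct(ct, gene, condition_control, paired=True)
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def heatmap_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Row-wise log2 ratios to the row maximum: each row's maximum is 0 and
    every entry is <= 0 ("highest to lowest expression of each gene").

    Zeros are replaced by a pseudocount of 1e-3 x the smallest positive value
    in the row; an all-zero row is an error naming the gene.
    """
    mat = expr.astype(float).copy()
    if (mat < 0).any().any():
        raise ValueError("expression values must be non-negative")
    for gene, row in mat.iterrows():
        positive = row[row > 0]
        if positive.empty:
            raise ValueError(f"all-zero expression row for gene {gene!r}")
        if (row == 0).any():
            mat.loc[gene] = row.replace(0.0, positive.min() * 1e-3)
    return np.log2(mat.div(mat.max(axis=1), axis=0))


def abundance_share(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene fractional abundance across categories (rows sum to 1), with
    the arg-max category and whether its share exceeds 0.5.

    Returns the share matrix plus ``top_category`` and ``dominant`` columns.
    """
    mat = expr.astype(float)
    if (mat < 0).any().any():
        raise ValueError("abundance values must be non-negative")
    totals = mat.sum(axis=1)
    zero = totals[totals == 0]
    if not zero.empty:
        raise ValueError(f"zero total abundance for gene {zero.index[0]!r}")
    shares = mat.div(totals, axis=0)
    out = shares.copy()
    out["top_category"] = shares.idxmax(axis=1)
    out["dominant"] = shares.max(axis=1) > 0.5
    return out


def tissue_specificity(expr: pd.DataFrame, threshold: float = 0.5) -> dict[str, str | None]:
    """Label each gene "<tissue>-specific" when one tissue holds at least
    ``threshold`` of its total expression; None otherwise."""
    mat = expr.astype(float)
    totals = mat.sum(axis=1)
    zero = totals[totals == 0]
    if not zero.empty:
        raise ValueError(f"zero total expression for gene {zero.index[0]!r}")
    shares = mat.div(totals, axis=0)
    labels: dict[str, str | None] = {}
    for gene, row in shares.iterrows():
        top = row.idxmax()
        labels[gene] = f"{top}-specific" if row[top] >= threshold else None
    return labels
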