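"""Matrix-level preprocessing: log2, quantile normalization, batch centering,
and two-group ANOVA differential expression with Benjamini-Hochberg FDR.

These are matrix-level stand-ins for the chip-level chain real microarray
studies run (RMA summarization, vendor batch tools): the discriminatory
analysis downstream consumes a normalized log2 genes-x-samples matrix, so
the pipeline provides the corresponding operations at that level —
quantile normalization (the across-array step of RMA), per-gene batch-mean
centering (the exact fixed-effect ANOVA correction for a one-factor batch
model), and per-gene one-way two-group ANOVA with FDR control at q < 0.05.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "log2_transform",
    "quantile_normalize",
    "remove_batch_effects",
    "differential_expression",
]


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Base-2 logarithm of a strictly positive linear-scale matrix."""
    values = matrix.to_numpy(float)
    if np.any(values <= 0) or np.any(~np.isfinite(values)):
        bad = np.argwhere(~(values > 0) | ~np.isfinite(values))[0]
        raise DataError(
            f"non-positive value at gene '{matrix.index[bad[0]]}', "
            f"sample '{matrix.columns[bad[1]]}'"
        )
    return pd.DataFrame(np.log2(values), index=matrix.index, columns=matrix.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common mean quantile profile.

    The reference distribution is the row-wise mean of the per-column sorted
    values; each column's values are replaced by the reference value at
    their average rank (ties share the mean of the tied reference values).
    Idempotent up to floating tolerance.
    """
    if matrix.shape[1] < 2:
        logger.warning("quantile_normalize on a single sample is a no-op")
        return matrix.copy()
    values = matrix.to_numpy(float)
    reference = np.sort(values, axis=0).mean(axis=1)
    positions = np.arange(1, len(reference) + 1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = scipy.stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def remove_batch_effects(matrix: pd.DataFrame, batch_assignment: pd.Series) -> pd.DataFrame:
    """Per-gene batch-mean centering with the grand mean added back.

    For each gene, every sample's value loses its batch mean (for that gene)
    and regains the gene's grand mean, so per-gene grand means are exactly
    preserved.  This is the fixed-effect ANOVA correction for a one-factor
    batch model with no covariates; a single batch is the identity.
    """
    unknown = batch_assignment.index.difference(matrix.columns)
    if len(unknown) > 0:
        raise DataError(f"batch map references unknown samples: {list(unknown[:5])}")
    missing = matrix.columns.difference(batch_assignment.index)
    if len(missing) > 0:
        raise DataError(f"samples without batch assignment: {list(missing[:5])}")
    grand = matrix.mean(axis=1)
    out = matrix.copy()
    for _, cols in matrix.columns.to_series().groupby(batch_assignment):
        cols = list(cols)
        batch_mean = matrix[cols].mean(axis=1)
        out[cols] = matrix[cols].sub(batch_mean, axis=0).add(grand, axis=0)
    return out


def differential_expression(
    matrix: pd.DataFrame, labels: pd.Series, *, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene two-group one-way ANOVA with Benjamini-Hochberg q-values.

    For two groups the one-way ANOVA F-test on 1 and n-2 degrees of freedom
    is the square of the equal-variance two-sample t-test, which is how the
    p-values are computed (vectorized over genes).  Degenerate genes with
    zero within-group variance get p = 1 when the group means agree (no
    evidence) and the smallest positive float when they differ (perfect
    separation), with a logged warning.  ``significant`` is ``fdr_q < alpha``.
    """
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise DataError(f"expected exactly 2 classes, got {list(classes)}")
    class1 = "fatigued" if "fatigued" in set(classes) else sorted(classes)[0]
    cols1 = labels.index[labels == class1]
    cols2 = labels.index[labels != class1]
    if len(cols1) < 2 or len(cols2) < 2:
        raise DataError("each class needs >= 2 samples")
    x1 = matrix[cols1].to_numpy(float)
    x2 = matrix[cols2].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = scipy.stats.ttest_ind(x1, x2, axis=1, equal_var=True)
        p = np.asarray(res.pvalue, dtype=float)
    mean1 = x1.mean(axis=1)
    mean2 = x2.mean(axis=1)
    degenerate = ~np.isfinite(p) | (p == 0.0)
    if degenerate.any():
        logger.warning("%d degenerate zero-variance genes", int(degenerate.sum()))
        equal = np.isclose(mean1, mean2)
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = np.nextafter(0.0, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "mean_class1": mean1,
            "mean_class2": mean2,
            "p_value": p,
            "fdr_q": q,
            "significant": q < alpha,
        },
        index=matrix.index.rename("gene_id"),
    )
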