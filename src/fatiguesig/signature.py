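"""LOOCV nearest-neighbor classification and minimal-signature discovery.

Leave-one-out cross-validation (LOOCV) holds each sample out in turn and
predicts its class from the remaining samples with a nearest-neighbor rule
in the space spanned by the currently selected gene subset ("the reduced
base").  The minimal signature is found by recursive elimination: starting
from the full ranked gene list, the lowest-ranked gene is peeled off one at
a time, the LOOCV accuracy of every prefix is recorded, and the smallest
prefix attaining the maximum observed accuracy is returned.  The rationale
is that highly discriminatory genes span the main features of the
classification while low-ranked genes only account for details.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["Signature", "loocv_accuracy", "minimal_signature"]


@dataclass
class Signature:
    """An ordered gene subset with its LOOCV accuracy and elimination trace."""

    gene_ids: list
    loocv_accuracy: float
    #: (prefix size k, LOOCV accuracy of the top-k genes), k = n .. 1.
    accuracy_curve: list = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def _validate_subset(matrix: pd.DataFrame, gene_subset) -> list:
    genes = list(gene_subset)
    if not genes:
        raise DataError("gene subset must be non-empty")
    for g in genes:
        if g not in matrix.index:
            raise DataError(f"gene '{g}' not present in the expression matrix")
    return genes


def _reduced_base(matrix: pd.DataFrame, labels: pd.Series, genes) -> tuple[np.ndarray, np.ndarray]:
    unknown = labels.index.difference(matrix.columns)
    if len(unknown) > 0:
        raise DataError(f"labels reference unknown samples: {list(unknown[:5])}")
    X = matrix.loc[genes, labels.index].to_numpy(float).T  # samples x genes
    y = labels.to_numpy()
    return X, y


def _distance_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        return np.einsum("ijk,ijk->ij", diff, diff)  # squared distances
    if metric == "correlation":
        if X.shape[1] < 2:
            raise DataError("correlation distance needs >= 2 genes")
        return 1.0 - np.corrcoef(X)
    raise DataError(f"unknown metric '{metric}'")


def loocv_accuracy(
    matrix: pd.DataFrame,
    labels: pd.Series,
    gene_subset,
    *,
    k: int = 1,
    metric: str = "euclidean",
    zscore: bool = False,
) -> float:
    """Leave-one-out accuracy of a k-NN classifier on a gene subset.

    Each sample in turn is the validation sample; its class is predicted
    from the ``k`` nearest training samples (Euclidean distance on the
    selected genes' log2 values by default; distance ties go to the lower
    sample index, which ``argmin``/stable ``argsort`` implement).  With
    ``zscore=True`` each gene is standardized using training-fold statistics
    only.  The result is always an integer multiple of ``1/n_samples``.
    """
    genes = _validate_subset(matrix, gene_subset)
    if k < 1 or k % 2 == 0:
        raise DataError(f"k must be a positive odd integer, got {k}")
    X, y = _reduced_base(matrix, labels, genes)
    n = len(y)
    if n < 3:
        raise DataError("LOOCV needs >= 3 samples")

    if not zscore:
        D = _distance_matrix(X, metric)
        np.fill_diagonal(D, np.inf)
        if k == 1:
            pred = y[np.argmin(D, axis=1)]
        else:
            kk = min(k, n - 1)
            order = np.argsort(D, axis=1, kind="stable")[:, :kk]
            pred = np.array([_vote(y[row]) for row in order])
        return float(np.mean(pred == y))

    correct = 0
    for i in range(n):
        train = np.delete(np.arange(n), i)
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xt = (X[train] - mu) / sd
        xi = (X[i] - mu) / sd
        if metric == "euclidean":
            d = np.einsum("ij,ij->i", Xt - xi, Xt - xi)
        else:
            d = np.array([1.0 - np.corrcoef(xi, row)[0, 1] for row in Xt])
        order = np.argsort(d, kind="stable")[: min(k, n - 1)]
        if _vote(y[train][order]) == y[i]:
            correct += 1
    return correct / n


def _vote(neighbor_labels: np.ndarray):
    counts = Counter(neighbor_labels)
    best = max(counts.values())
    winners = [c for c, v in counts.items() if v == best]
    if len(winners) == 1:
        return winners[0]
    # vote tie (only possible for even effective k): nearest neighbor decides
    for lab in neighbor_labels:
        if lab in winners:
            return lab
    return winners[0]


def _prefix_accuracies_euclidean(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LOOCV 1-NN accuracy of every ranked-gene prefix in one sweep.

    Squared Euclidean distances are additive over genes, so the distance
    matrix of prefix k is the cumulative sum of per-gene contributions —
    an O(g n^2) evaluation of all g prefixes instead of O(g^2 n^2).
    """
    n, g = X.shape
    contrib = (X.T[:, :, None] - X.T[:, None, :]) ** 2  # g x n x n
    d2 = np.cumsum(contrib, axis=0)
    idx = np.arange(n)
    d2[:, idx, idx] = np.inf
    nn = np.argmin(d2, axis=2)  # g x n; ties -> lower sample index
    return (y[nn] == y[None, :]).mean(axis=1)


def minimal_signature(
    matrix: pd.DataFrame,
    labels: pd.Series,
    ranked_genes,
    *,
    k: int = 1,
    metric: str = "euclidean",
    zscore: bool = False,
) -> Signature:
    """Minimum-size signature by recursive elimination of low-ranked genes.

    ``ranked_genes`` must be in descending discriminatory order (the output
    order of :func:`fatiguesig.fisher.score_genes`, optionally after band
    selection).  The LOOCV accuracy of the top-k prefix is evaluated for
    k = n, n-1, ..., 1; the returned signature is the smallest prefix whose
    accuracy equals the maximum over the whole curve (minimum size wins
    ties).  Deterministic for fixed inputs.
    """
    genes = _validate_subset(matrix, ranked_genes)
    if k == 1 and metric == "euclidean" and not zscore:
        X, y = _reduced_base(matrix, labels, genes)
        acc = _prefix_accuracies_euclidean(X, y)
    else:
        acc = np.array(
            [
                loocv_accuracy(matrix, labels, genes[:kk], k=k, metric=metric, zscore=zscore)
                for kk in range(1, len(genes) + 1)
            ]
        )
    best = float(acc.max())
    best_k = int(np.flatnonzero(acc == best)[0]) + 1
    curve = [(kk, float(acc[kk - 1])) for kk in range(len(genes), 0, -1)]
    return Signature(gene_ids=genes[:best_k], loocv_accuracy=best, accuracy_curve=curve)
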