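"""Per-gene Fisher's-ratio and fold-change scoring, and band selection.

For gene *j* in a two-class problem the Fisher's ratio is

    FR_j = (mu_j1 - mu_j2)^2 / (sigma_j1^2 + sigma_j2^2)

where mu and sigma^2 are the class means and variances of that gene's log2
intensities.  Large FR_j means the classes are far apart relative to their
internal spread; it is a per-feature separability score, not a test
statistic.  Fold change here is the difference of class mean log2
intensities (class 1 minus class 2), so its sign gives direction.

Feature reduction proceeds by ranking genes in decreasing FR order and,
optionally, keeping only the genes whose (FR, fold change) pair falls inside
a rectangular band filter.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "BandFilter",
    "DEFAULT_BAND_FILTER",
    "fisher_ratio",
    "fold_change",
    "score_genes",
    "select_band",
]

SCORE_COLUMNS = ["fisher_ratio", "fold_change", "mu1", "mu2", "var1", "var2", "rank"]


@dataclass(frozen=True)
class BandFilter:
    """Closed Fisher's-ratio window plus one or more closed fold-change bands."""

    fr_min: float
    fr_max: float
    fc_bands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.fr_min > self.fr_max:
            raise ConfigError(f"fr_min = {self.fr_min} > fr_max = {self.fr_max}")
        for lo, hi in self.fc_bands:
            if lo > hi:
                raise ConfigError(f"fold-change band [{lo}, {hi}] has lower > upper")

    @classmethod
    def from_string(cls, fr_min: float, fr_max: float, fc_bands: str) -> "BandFilter":
        """Parse bands from a ``"lo:hi,lo:hi"`` CLI string."""
        bands = []
        for part in fc_bands.split(","):
            try:
                lo, hi = (float(x) for x in part.split(":"))
            except ValueError as exc:
                raise ConfigError(f"cannot parse fold-change band '{part}'") from exc
            bands.append((lo, hi))
        return cls(float(fr_min), float(fr_max), tuple(bands))


#: Band filter used by the default pipeline: Fisher's ratio in [0.70, 1.72],
#: fold change in [-0.92, -0.15] or [0.09, 1.13].
DEFAULT_BAND_FILTER = BandFilter(0.70, 1.72, ((-0.92, -0.15), (0.09, 1.13)))


def _moments(values: np.ndarray, ddof: int) -> tuple[float, float]:
    return float(np.mean(values)), float(np.var(values, ddof=ddof))


def fisher_ratio(values_class1, values_class2, ddof: int = 1) -> float:
    """Fisher's ratio of one gene from its two class-wise value vectors.

    Uses unbiased (n-1) class variances by default (``ddof=0`` switches to
    the maximum-likelihood estimator).  Degenerate inputs: if both class
    variances are zero the ratio is 0 when the means agree and ``inf``
    (perfect separability, sorted above every finite ratio) when they
    differ.
    """
    x1 = np.asarray(values_class1, dtype=float)
    x2 = np.asarray(values_class2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise DataError("fisher_ratio requires >= 2 values per class")
    m1, v1 = _moments(x1, ddof)
    m2, v2 = _moments(x2, ddof)
    denom = v1 + v2
    if denom == 0.0:
        return 0.0 if m1 == m2 else float("inf")
    return (m1 - m2) ** 2 / denom


def fold_change(values_class1, values_class2) -> float:
    """Difference of class mean log2 intensities, class 1 minus class 2."""
    x1 = np.asarray(values_class1, dtype=float)
    x2 = np.asarray(values_class2, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise DataError("fold_change requires non-empty classes")
    return float(np.mean(x1) - np.mean(x2))


def _split_classes(matrix: pd.DataFrame, labels: pd.Series, class1: str | None):
    unknown = labels.index.difference(matrix.columns)
    if len(unknown) > 0:
        raise DataError(f"labels reference unknown samples: {list(unknown[:5])}")
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise DataError(f"expected exactly 2 classes, got {list(classes)}")
    if class1 is None:
        # 'fatigued' is class 1 when present; otherwise lexicographic order.
        class1 = "fatigued" if "fatigued" in set(classes) else sorted(classes)[0]
    if class1 not in set(classes):
        raise DataError(f"class1 = '{class1}' not among labels {list(classes)}")
    cols1 = labels.index[labels == class1]
    cols2 = labels.index[labels != class1]
    if len(cols1) < 2 or len(cols2) < 2:
        raise DataError("each class needs >= 2 samples")
    return matrix[cols1].to_numpy(float), matrix[cols2].to_numpy(float)


def score_genes(
    matrix: pd.DataFrame,
    labels: pd.Series,
    *,
    class1: str | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Score every gene and rank by decreasing discriminatory power.

    Returns a DataFrame indexed by gene id, ordered rank 1 (most
    discriminatory) first, with columns ``fisher_ratio``, ``fold_change``,
    ``mu1``, ``mu2``, ``var1``, ``var2``, ``rank``.  Rank ties are broken by
    gene-id lexicographic order so the ranking is deterministic.
    """
    x1, x2 = _split_classes(matrix, labels, class1)
    mu1 = x1.mean(axis=1)
    mu2 = x2.mean(axis=1)
    var1 = x1.var(axis=1, ddof=ddof)
    var2 = x2.var(axis=1, ddof=ddof)
    denom = var1 + var2
    num = (mu1 - mu2) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        fr = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.where(num > 0, np.inf, 0.0))
    scores = pd.DataFrame(
        {
            "fisher_ratio": fr,
            "fold_change": mu1 - mu2,
            "mu1": mu1,
            "mu2": mu2,
            "var1": var1,
            "var2": var2,
        },
        index=matrix.index.rename("gene_id"),
    )
    # mergesort is stable, so pre-sorting by gene id implements the tie rule
    scores = (
        scores.sort_index(kind="mergesort")
        .sort_values(by="fisher_ratio", ascending=False, kind="mergesort")
    )
    scores["rank"] = np.arange(1, len(scores) + 1)
    return scores


def select_band(scores: pd.DataFrame, band: BandFilter) -> pd.DataFrame:
    """Keep the scores inside the band filter, preserving rank order.

    A score passes when ``fr_min <= fisher_ratio <= fr_max`` and its fold
    change lies in at least one fold-change band (all intervals closed).
    An empty selection is a valid result, not an error.
    """
    if len(scores) == 0:
        raise DataError("select_band requires non-empty scores")
    fr = scores["fisher_ratio"]
    fc = scores["fold_change"]
    in_fr = (fr >= band.fr_min) & (fr <= band.fr_max)
    in_fc = pd.Series(False, index=scores.index)
    for lo, hi in band.fc_bands:
        in_fc |= (fc >= lo) & (fc <= hi)
    return scores[in_fr & in_fc]
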