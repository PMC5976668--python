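"""Random gene-network sampling with posterior gene frequencies.

An uncertainty analysis around the single minimal signature: small gene
subsets ("networks") are drawn at random from the high-discriminatory pool,
each is scored by LOOCV nearest-neighbor accuracy, networks at or above a
retention threshold are kept, and each pool gene's posterior sampling
frequency — the fraction of retained networks containing it — measures how
consistently it participates in accurate classifiers.

A single RNG stream is consumed draw by draw and network scoring uses no
random state, so results are reproducible for a given seed regardless of
how scoring is executed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .signature import _distance_matrix, _reduced_base

import logging

logger = logging.getLogger(__name__)

__all__ = ["SamplerConfig", "SamplerResult", "sample_networks", "frequency_report"]


@dataclass(frozen=True)
class SamplerConfig:
    """Sampling plan over a high-Fisher's-ratio gene pool."""

    pool: tuple
    n_draws: int = 10_000
    size_min: int = 2
    size_max: int = 20
    retention_accuracy: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pool) == 0:
            raise ConfigError("sampler pool must be non-empty")
        if len(set(self.pool)) != len(self.pool):
            raise ConfigError("sampler pool contains duplicate gene ids")
        if self.n_draws < 1:
            raise ConfigError(f"n_draws must be >= 1, got {self.n_draws}")
        if not (1 <= self.size_min <= self.size_max):
            raise ConfigError(
                f"need 1 <= size_min <= size_max, got [{self.size_min}, {self.size_max}]"
            )
        if self.size_max > len(self.pool):
            raise ConfigError(
                f"size_max = {self.size_max} exceeds pool size {len(self.pool)}"
            )


@dataclass
class SamplerResult:
    """Retained networks, their accuracies, and per-gene frequencies."""

    networks: list  # list of (tuple of gene ids, loocv accuracy), retained only
    posterior_frequency: pd.Series  # indexed by pool gene id, in [0, 1]
    membership_counts: pd.Series  # integer retained-network memberships per gene
    n_retained: int
    n_draws: int
    config: SamplerConfig = field(repr=False, default=None)


def sample_networks(
    matrix: pd.DataFrame, labels: pd.Series, config: SamplerConfig
) -> SamplerResult:
    """Draw, score, and retain random gene networks from the pool.

    Each draw picks a network size uniformly on [size_min, size_max] and
    that many distinct pool genes uniformly at random; the network's LOOCV
    1-NN accuracy is computed on the selected genes and networks with
    accuracy >= ``retention_accuracy`` are retained.  Zero retained
    networks is a valid outcome (all frequencies 0).
    """
    pool = list(config.pool)
    missing = [g for g in pool if g not in matrix.index]
    if missing:
        raise DataError(f"pool genes absent from matrix: {missing[:5]}")

    X, y = _reduced_base(matrix, labels, pool)  # samples x pool genes
    n = len(y)
    # per-gene squared-difference contributions; reused by every draw
    contrib = (X.T[:, :, None] - X.T[:, None, :]) ** 2
    diag = np.arange(n)

    rng = np.random.default_rng(config.seed)
    retained: list[tuple[tuple, float]] = []
    counts = np.zeros(len(pool))
    for _ in range(config.n_draws):
        size = int(rng.integers(config.size_min, config.size_max + 1))
        idx = rng.choice(len(pool), size=size, replace=False)
        d2 = contrib[idx].sum(axis=0)
        d2[diag, diag] = np.inf
        pred = y[np.argmin(d2, axis=1)]
        acc = float(np.mean(pred == y))
        if acc >= config.retention_accuracy:
            retained.append((tuple(pool[i] for i in idx), acc))
            counts[idx] += 1

    n_retained = len(retained)
    if n_retained == 0:
        logger.info("sampler retained no networks at threshold %.3f", config.retention_accuracy)
        freq = np.zeros(len(pool))
    else:
        freq = counts / n_retained
    gene_index = pd.Index(pool, name="gene_id")
    return SamplerResult(
        networks=retained,
        posterior_frequency=pd.Series(freq, index=gene_index, name="posterior_frequency"),
        membership_counts=pd.Series(counts.astype(int), index=gene_index, name="membership_count"),
        n_retained=n_retained,
        n_draws=config.n_draws,
        config=config,
    )


def frequency_report(result: SamplerResult) -> pd.DataFrame:
    """Pool genes ranked by descending posterior frequency, ties by gene id."""
    freq = result.posterior_frequency
    table = (
        freq.to_frame()
        .sort_index(kind="mergesort")
        .sort_values("posterior_frequency", ascending=False, kind="mergesort")
    )
    table["n_retained"] = result.n_retained
    return table


def verify_frequency_identity(result: SamplerResult) -> bool:
    """Check sum(frequency * n_retained) == total size of retained networks.

    Evaluated on the exact integer membership counts (of which the
    posterior frequencies are counts / n_retained), so the identity is
    checked without floating-point slack.
    """
    lhs = int(result.membership_counts.sum())
    rhs = sum(len(genes) for genes, _ in result.networks)
    return lhs == rhs
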