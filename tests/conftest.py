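import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fatiguesig import SimConfig, generate_dataset

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_matrix(values, gene_ids=None, sample_ids=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(1, values.shape[0] + 1)]
    samples = sample_ids or [f"s{j}" for j in range(1, values.shape[1] + 1)]
    return pd.DataFrame(
        values,
        index=pd.Index(genes, name="gene_id"),
        columns=pd.Index(samples, name="sample_id"),
    )


def make_labels(classes, sample_ids=None) -> pd.Series:
    samples = sample_ids or [f"s{j}" for j in range(1, len(classes) + 1)]
    return pd.Series(list(classes), index=pd.Index(samples, name="sample_id"), name="class")


@pytest.fixture(scope="session")
def small_dataset():
    """A modest two-class dataset with planted genes and batch structure."""
    return generate_dataset(
        SimConfig(
            n_genes=300,
            n_planted=10,
            effect_size=1.5,
            sigma_within=1.0,
            n_batches=2,
            batch_sd=0.3,
            seed=11,
        )
    )
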