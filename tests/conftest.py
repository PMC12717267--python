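import numpy as np
import pandas as pd
import pytest

from aerodiv.compositional import CompositionMatrix, CountMatrix
from aerodiv.synthetic import SyntheticConfig, make_community, sample_reads


def make_count_matrix(counts: np.ndarray, genera=None, weeks=None, **meta) -> CountMatrix:
    """Hand-built CountMatrix with minimal metadata for unit tests."""
    d, w = counts.shape
    genera = genera or [f"g{i}" for i in range(d)]
    weeks = weeks or [f"1974-W{j + 1:02d}" for j in range(w)]
    metadata = pd.DataFrame(
        {
            "year": meta.get("year", np.full(w, 1974)),
            "calendar_week": meta.get("calendar_week", np.arange(1, w + 1)),
            "mean_read_length": meta.get("mean_read_length", np.full(w, 120.0)),
            "filter_type": meta.get("filter_type", ["CS5.0"] * w),
            "human_read_fraction": meta.get("human_read_fraction", np.full(w, 0.3)),
            "total_reads": counts.sum(axis=0),
        },
        index=pd.Index(weeks, name="week"),
    )
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genera, columns=weeks), metadata=metadata
    )


def random_composition(d: int, w: int, seed: int = 0) -> CompositionMatrix:
    rng = np.random.default_rng(seed)
    x = rng.dirichlet(np.ones(d) * 2, size=w).T
    return CompositionMatrix(
        proportions=pd.DataFrame(
            x,
            index=[f"g{i}" for i in range(d)],
            columns=[f"1974-W{j + 1:02d}" for j in range(w)],
        )
    )


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_genera=40, n_weeks=120, n_clusters=4, n_spurious_genera=6, seed=123
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return make_community(small_config)


@pytest.fixture(scope="session")
def small_counts(small_truth, small_config):
    return sample_reads(small_truth, small_config)
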