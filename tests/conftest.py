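import numpy as np
import pandas as pd
import pytest

from avigut.io import CountMatrix, RelAbundanceMatrix, SampleMetadata, TaxonomyTable
from avigut.simulate import GeneratorConfig, default_template, generate_dataset


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return CountMatrix(pd.DataFrame(
        {"s1": [5, 3, 0], "s2": [1, 0, 4]},
        index=["t1", "t2", "t3"],
    ))


@pytest.fixture
def tiny_taxonomy() -> TaxonomyTable:
    cols = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]
    return TaxonomyTable(pd.DataFrame(
        [
            ["Bacteria", "Firmicutes", "c", "o", "f", "Lactobacillus", "L. x"],
            ["Bacteria", "Firmicutes", "c", "o", "f", "Lactobacillus", None],
            ["Bacteria", "Bacteroidetes", "c", "o", "f", None, None],
        ],
        index=["t1", "t2", "t3"], columns=cols,
    ))


@pytest.fixture
def tiny_metadata() -> SampleMetadata:
    return SampleMetadata(pd.DataFrame(
        {"segment": ["duodenum", "caecum"], "age_days": [11, 11], "pen": [1, 1]},
        index=["s1", "s2"],
    ))


def random_count_matrix(rng: np.random.Generator, n_taxa=8, n_samples=5,
                        max_count=50) -> CountMatrix:
    counts = rng.integers(0, max_count, size=(n_taxa, n_samples))
    counts[rng.integers(0, n_taxa), :] += 1  # no all-zero samples
    return CountMatrix(pd.DataFrame(
        counts,
        index=[f"t{i}" for i in range(n_taxa)],
        columns=[f"s{j}" for j in range(n_samples)],
    ))


def random_rel_matrix(rng: np.random.Generator, n_taxa=8, n_samples=6,
                      zero_fraction=0.3) -> RelAbundanceMatrix:
    values = rng.random((n_taxa, n_samples))
    values[rng.random((n_taxa, n_samples)) < zero_fraction] = 0.0
    values[rng.integers(0, n_taxa), :] += 0.1  # keep columns positive
    values /= values.sum(axis=0)
    return RelAbundanceMatrix(pd.DataFrame(
        values,
        index=[f"t{i}" for i in range(n_taxa)],
        columns=[f"s{j}" for j in range(n_samples)],
    ))


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One default-condition dataset shared across tests (seed fixed)."""
    return generate_dataset(default_template(), GeneratorConfig(seed=11))
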