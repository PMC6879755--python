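"""Shared fixtures: one default synthetic study reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ovorigin.datatypes import CountMatrix, SampleAnnotation
from ovorigin.model import CellOfOriginModel
from ovorigin.simulate import (
    SimulationConfig,
    generate_orthology_table,
    simulate_cohort,
    simulate_mouse_experiment,
)


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def mouse_data(default_cfg):
    return simulate_mouse_experiment(default_cfg)


@pytest.fixture(scope="session")
def orthology(default_cfg, mouse_data):
    _, truth = mouse_data
    return generate_orthology_table(default_cfg, truth)


@pytest.fixture(scope="session")
def cohort_data(default_cfg, mouse_data, orthology):
    _, truth = mouse_data
    return simulate_cohort(default_cfg, truth, orthology)


@pytest.fixture(scope="session")
def fitted(mouse_data, orthology):
    matrix, _ = mouse_data
    return CellOfOriginModel(matrix, orthology=orthology).fit()


def make_count_matrix(
    counts: np.ndarray | list, groups: list[str], gene_prefix: str = "g"
) -> CountMatrix:
    """Tiny hand-built CountMatrix helper for unit tests."""
    arr = np.asarray(counts)
    genes = [f"{gene_prefix}{i}" for i in range(arr.shape[0])]
    samples = [f"s{i}" for i in range(arr.shape[1])]
    ann = SampleAnnotation(
        pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample_id"))
    )
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples), ann)
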