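import numpy as np
import pandas as pd
import pytest

from fppid import granulation, materials, pipeline, synthetic


@pytest.fixture(scope="session")
def library30():
    """Default 30-material synthetic library."""
    return synthetic.generate_library(synthetic.GeneratorSpec(seed=42))


@pytest.fixture(scope="session")
def working10(library30):
    rep = materials.select_representatives(library30)
    ids = rep["boundary"] + rep["center"] + rep["fill"]
    return pipeline.subset_library(library30, ids)


@pytest.fixture(scope="session")
def design180(working10):
    return granulation.build_design(working10, seed=7)


@pytest.fixture(scope="session")
def observations720(working10, design180):
    table, truth = synthetic.generate_hswgt_observations(
        working10, design180, seed=11)
    return table, truth


@pytest.fixture(scope="session")
def pipeline_report():
    """One full seeded pipeline run shared across tests."""
    return pipeline.run_pipeline({"seed": 1})


def tiny_library(n: int = 4, scores=None) -> materials.MaterialLibrary:
    """A minimal hand-built valid library (n rows); helper for unit tests."""
    base = synthetic.generate_library(synthetic.GeneratorSpec(seed=5, n_materials=max(n, 4)))
    return materials.MaterialLibrary(base.table.iloc[:n].reset_index(drop=True))
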