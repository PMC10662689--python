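import numpy as np
import pytest

import redoxquant as rq


@pytest.fixture(scope="session")
def default_dataset():
    """A small but fully featured simulated experiment (noise + missingness)."""
    cfg = rq.SimConfig(n_proteins=20, seed=11, missing_rate=0.2)
    return rq.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_database(default_dataset):
    return rq.fasta_to_dict(default_dataset.entries)


@pytest.fixture(scope="session")
def default_run(default_dataset, default_database):
    """analyze() output on the default dataset (protein df, site df, info)."""
    return rq.analyze(
        default_dataset.table,
        default_database,
        default_dataset.design,
        rq.PipelineConfig(),
    )


@pytest.fixture
def toy_database():
    return {"P1": "MKACRLLCK", "P2": "ACRMM"}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
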