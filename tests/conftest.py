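import numpy as np
import pandas as pd
import pytest

from factorbn import bcfa, genomics, simdata


@pytest.fixture(scope="session")
def small_config():
    """Panel-shaped config scaled down for fast fits."""
    return simdata.SimulationConfig.default(seed=7, n_accessions=200, n_markers=400)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simdata.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def measurement_model(small_config):
    cfg = small_config
    return bcfa.MeasurementModel.from_factor_lists(
        {f: [t for t in cfg.trait_names if t.startswith(f)] for f in cfg.factor_names}
    )


@pytest.fixture()
def toy_genotypes():
    """3 accessions x 2 markers with known allele frequencies."""
    return genomics.GenotypeMatrix(
        ["a1", "a2", "a3"], ["m1", "m2"], np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 1.0]])
    )
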