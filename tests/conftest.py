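import numpy as np
import pytest

from ovotox import atlas as atlas_mod
from ovotox import preprocess, simdata


@pytest.fixture(scope="session")
def atlas_data():
    """A default synthetic atlas: (counts cells x genes, metadata, truth)."""
    return simdata.generate_atlas(seed=1)


@pytest.fixture(scope="session")
def qc_atlas(atlas_data):
    sc, meta, truth = atlas_data
    counts, metadata, report = preprocess.qc_cells(sc, meta)
    return counts, metadata, report, truth


@pytest.fixture(scope="session")
def reference(qc_atlas):
    counts, metadata, _, _ = qc_atlas
    return atlas_mod.build_reference(counts, metadata)


@pytest.fixture(scope="session")
def cohort(atlas_data):
    _, _, truth = atlas_data
    bulk, meta, ctruth = simdata.generate_bulk_cohort(truth, seed=3)
    return bulk, meta, ctruth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
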