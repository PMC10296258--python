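import numpy as np
import pandas as pd
import pytest

from metabotype import (
    PipelineConfig, PrognosticSubtypeModel, SimulationConfig, generate_cohort,
)
from metabotype.containers import RawFeatureTable


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study (209 patients, 186 metabolites), seed 0."""
    return generate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def fitted_results(default_cohort):
    c = default_cohort
    model = PrognosticSubtypeModel(c.raw, c.clinical, c.library,
                                   c.pathway_map, PipelineConfig(seed=0))
    return model.fit()


def build_raw(values, mode="C18-", batches=None, mz=None, rt=None):
    """RawFeatureTable from an array shaped (features, samples, 3)."""
    arr = np.asarray(values, float)
    n_feat, n_samp, _ = arr.shape
    fids = [f"F{i + 1}" for i in range(n_feat)]
    sids = [f"S{i + 1}" for i in range(n_samp)]
    features = pd.DataFrame({
        "mz": mz if mz is not None else np.linspace(100, 200, n_feat),
        "rt": rt if rt is not None else np.linspace(20, 120, n_feat),
        "mode": mode,
    }, index=pd.Index(fids, name="feature_id"))
    cols = pd.MultiIndex.from_product([sids, [1, 2, 3]],
                                      names=["sample", "replicate"])
    inten = pd.DataFrame(arr.reshape(n_feat, n_samp * 3), index=features.index,
                         columns=cols)
    if batches is None:
        batches = pd.Series("B1", index=sids, name="batch")
    else:
        batches = pd.Series(batches, index=sids, name="batch")
    return RawFeatureTable(features, inten, batches)


@pytest.fixture
def make_raw():
    return build_raw
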