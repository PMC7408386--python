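import numpy as np
import pandas as pd
import pytest

from glynorm.dataio import GlycomicsDataset
from glynorm.glycan_model import build_igg_fc_pathway, default_igg_panel
from glynorm.simulate import SimulationConfig, sample_abundances


@pytest.fixture(scope="session")
def igg1_panel():
    """20 biantennary glycoform compositions of a single IgG subclass."""
    return [(l, s, c) for l, s, c in default_igg_panel() if s == "IgG1"]


@pytest.fixture(scope="session")
def igg1_pathway(igg1_panel):
    return build_igg_fc_pathway(igg1_panel)


@pytest.fixture(scope="session")
def clean_dataset(igg1_pathway):
    """Clean pathway-structured log-normal data, n=1000, rho=0.3."""
    cfg = SimulationConfig(pathway=igg1_pathway, n=1000, rho=0.3, seed=11)
    dataset, truth = sample_abundances(cfg)
    return dataset, truth


def make_dataset(values, sample_meta=None, glycan_meta=None, platform="generic"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    index = [f"s{i}" for i in range(n)]
    columns = [f"g{j}" for j in range(p)]
    df = pd.DataFrame(values, index=index, columns=columns)
    sm = pd.DataFrame(sample_meta, index=index) if sample_meta is not None else pd.DataFrame()
    gm = pd.DataFrame(glycan_meta, index=columns) if glycan_meta is not None else pd.DataFrame()
    return GlycomicsDataset(df, sm, gm, platform)


@pytest.fixture
def dataset_factory():
    return make_dataset
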