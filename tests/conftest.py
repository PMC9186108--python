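import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rnalof import SimulationConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from rnalof.simulate import sample_names


@pytest.fixture
def small_config():
    return SimulationConfig(seed=11, n_genes=60, n_background_junctions=12)


@pytest.fixture
def two_group_map():
    return {"wt_1": "wt", "wt_2": "wt", "wt_3": "wt", "mut_1": "mut", "mut_2": "mut", "mut_3": "mut"}


@pytest.fixture
def quant_table():
    """Three genes: multi-PAS, a filtered-down gene, and a single-PAS gene."""
    index = pd.MultiIndex.from_tuples(
        [("GA", 1), ("GA", 2), ("GA", 3), ("GB", 1), ("GB", 2), ("GC", 1)],
        names=["gene_id", "pas_index"],
    )
    return pd.DataFrame(
        {
            "wt_1": [10.0, 4.0, 8.0, 20.0, 6.0, 30.0],
            "wt_2": [10.0, 4.0, 8.0, 20.0, 6.0, 30.0],
        },
        index=index,
    )


def group_map(config: SimulationConfig, conditions=("wt", "mut")):
    return sample_names(config, conditions)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
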