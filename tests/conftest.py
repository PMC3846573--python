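import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tagdge.simulate import SimulationConfig, simulate_dataset
from tagdge.tagproc import filter_tags


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=40,
        length_range=(100, 400),
        n_tags_per_library=30_000,
        frac_de=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_dataset(small_config, return_gene_draws=True)


@pytest.fixture(scope="session")
def small_tables(small_sim):
    return {
        "CO": filter_tags(small_sim.reads_co, library_id="CO"),
        "DS": filter_tags(small_sim.reads_ds, library_id="DS"),
    }
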