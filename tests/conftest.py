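import pandas as pd
import pytest

from regdiv.simulate import (
    SimConfig,
    simulate_dataset,
    simulate_genome_layout,
    write_fixture_bundle,
    write_layout_files,
)


@pytest.fixture(scope="session")
def small_dataset():
    """60 genes across all six architectures at moderate depth."""
    return simulate_dataset(SimConfig(n_genes=60, seed=3))


@pytest.fixture(scope="session")
def bundle(tmp_path_factory, small_dataset):
    d = tmp_path_factory.mktemp("bundle")
    return write_fixture_bundle(small_dataset, str(d))


@pytest.fixture(scope="session")
def layout():
    """150-gene planted genome layout with all five duplication modes."""
    return simulate_genome_layout(150, seed=7)


@pytest.fixture(scope="session")
def layout_files(tmp_path_factory, layout):
    d = tmp_path_factory.mktemp("layout")
    return write_layout_files(layout, str(d))
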