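import numpy as np
import pytest

import demesim as d


@pytest.fixture
def constant_model():
    return d.generic_piecewise_constant([1000.0])


@pytest.fixture
def two_epoch_model():
    return d.generic_piecewise_constant([10000.0, 1000.0], [1000.0])


@pytest.fixture
def im_model():
    return d.generic_im(7300.0, 10000.0, 10000.0, 4000.0, 1e-4, 1e-4)


@pytest.fixture
def small_contig():
    return d.Contig(length=1e5, recombination_map=d.flat_map(1e5, 1e-8), mutation_rate=1e-8)


@pytest.fixture
def simulated_tables(constant_model, small_contig):
    samples = d.SampleSpec.simple([6])
    tables = d.simulate_ancestry(constant_model, samples, small_contig, seed=11)
    d.drop_mutations(tables, 1e-8, seed=12)
    return tables
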