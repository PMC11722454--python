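import numpy as np
import pytest

import repeatlens as rl


@pytest.fixture(scope="session")
def small_cfg():
    return rl.SimConfig(seed=11, n_samples=120, reads_per_sample=300)


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return rl.gen_population(small_cfg)


@pytest.fixture(scope="session")
def small_panel(small_truth):
    return rl.gen_tag_panel(small_truth)


@pytest.fixture(scope="session")
def gene_model():
    return rl.default_gene_model()


@pytest.fixture(scope="session")
def chrom_classes(small_truth):
    return np.where(small_truth.is_long, "LONG", "SHORT")
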