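import numpy as np
import pytest

from isomir_gaselect import SyntheticConfig, generate_matrix, emit_quantification_files


@pytest.fixture(scope="session")
def tiny_dataset():
    """Default desk-scale synthetic dataset: matrix plus planted ground truth."""
    config = SyntheticConfig(seed=11)
    matrix, truth = generate_matrix(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def emitted_dataset(tmp_path_factory):
    """Per-sample quantification files plus manifest for the default config."""
    config = SyntheticConfig(seed=11)
    out_dir = tmp_path_factory.mktemp("quantification")
    manifest = emit_quantification_files(config, out_dir)
    return config, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
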