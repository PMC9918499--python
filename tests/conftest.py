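import numpy as np
import pytest

import nucdyn as nd


@pytest.fixture(scope="session")
def clean_sim():
    """Small noise-free synthetic trajectory with exact labels."""
    params = nd.SyntheticParams(n_frames=400, seed=17, noise_sigma=0.0)
    system, ens, truth = nd.simulate_trajectory(params)
    return params, system, ens, truth


@pytest.fixture(scope="session")
def noisy_sim():
    params = nd.SyntheticParams(n_frames=400, seed=23, noise_sigma=0.5)
    system, ens, truth = nd.simulate_trajectory(params)
    return params, system, ens, truth


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, clean_sim):
    """The clean simulation written to disk as PDB + XTC + TSV."""
    _, system, ens, truth = clean_sim
    d = tmp_path_factory.mktemp("fixture")
    return nd.write_fixture(system, ens, d, ground_truth=truth)


@pytest.fixture(scope="session")
def packaged_seqs():
    return nd.load_packaged("H2A"), nd.load_packaged("H2A.Z")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
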