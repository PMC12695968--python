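import pytest

from rockroi.simulate import SimConfig, run_simulation


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small zero-error simulation shared across test modules."""
    cfg = SimConfig(seed=7, n_cells=30, n_empty=120, wta_mean=10.0,
                    ambient_mean=5.0, error_rate=0.0)
    out_dir = tmp_path_factory.mktemp("small_sim")
    return run_simulation(cfg, out_dir)


@pytest.fixture(scope="session")
def small_truth(small_sim):
    return small_sim.truth
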