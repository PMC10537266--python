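import numpy as np
import pytest

import drosvir as dv


@pytest.fixture(scope="session")
def small_experiment():
    """A compact two-project experiment with duplicates and marker leakage."""
    cfg = dv.SimConfig(
        n_projects=2,
        libraries_per_project=60,
        n_genes=500,
        viruses={"nora_virus": 0.35, "DAV": 0.15},
        duplicate_pairs_per_project=3,
        marker_leakage=True,
        seed=5,
    )
    meta, vc, gc, truth = dv.simulate_experiment(cfg)
    return cfg, meta, vc, gc, truth


@pytest.fixture(scope="session")
def small_de_results(small_experiment):
    """Fitted DE results for both viruses of the small experiment."""
    _, meta, vc, gc, _ = small_experiment
    calls = dv.call_infections(vc, projects=meta["project"]).present
    out = {}
    for virus in ("nora_virus", "DAV"):
        model = dv.VirusDEModel(gc, meta, calls, virus)
        out[virus] = model.fit()
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
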