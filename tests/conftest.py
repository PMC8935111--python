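import numpy as np
import pytest

import scinsight as si


@pytest.fixture
def tiny_study():
    """Two samples, two conditions, 3 cells x 4 genes each."""
    genes = ["g1", "g2", "g3", "g4"]
    rng = np.random.default_rng(42)
    samples = [
        si.SampleMatrix("A", "ctrl", ["A:c1", "A:c2", "A:c3"], genes,
                        rng.integers(0, 20, (3, 4)).astype(float)),
        si.SampleMatrix("B", "treat", ["B:c1", "B:c2", "B:c3"], genes,
                        rng.integers(0, 20, (3, 4)).astype(float)),
    ]
    return si.StudyData(samples)


@pytest.fixture(scope="session")
def small_sim():
    """A reduced synthetic study: 6 samples, 3 conditions, 300 genes."""
    cfg = si.SimulationConfig(seed=0, cells_per_type=30, n_genes=300,
                              markers_per_type=30, markers_per_condition=20)
    study, truth = si.simulate_study(cfg)
    return cfg, study, truth


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A factorization fit on the reduced synthetic study."""
    _, study, truth = small_sim
    proc = si.preprocess(study, n_hvgs=300)
    model, report = si.fit(proc, K=8, K_j=2, lambda1=0.01, lambda2=0.01,
                           seed=0, max_iter=60)
    return proc, model, report, truth
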