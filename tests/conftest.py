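import numpy as np
import pytest

import poolcline as pc


@pytest.fixture(scope="session")
def gradient_dataset():
    """Moderate two-cluster cline dataset shared across test modules."""
    cfg = pc.SimulationConfig(seed=123, n_snps=6000, n_scaffolds=50)
    return pc.simulate_gradient_experiment(cfg)


@pytest.fixture(scope="session")
def neutral_dataset():
    """Two-cluster dataset without selected loci (structure-only tests)."""
    cfg = pc.SimulationConfig(seed=321, n_snps=6000, n_scaffolds=50,
                              selected_fraction=0.0)
    return pc.simulate_gradient_experiment(cfg)


def make_table(rows, n_pools):
    """Build a SiteCountsTable from (scaffold, pos, ref, [sextet, ...]) rows."""
    scaf = np.array([r[0] for r in rows], dtype=object)
    pos = np.array([r[1] for r in rows], dtype=np.int64)
    ref = np.array([r[2] for r in rows], dtype=object)
    counts = np.array([r[3] for r in rows], dtype=np.int64).reshape(
        len(rows), n_pools, 6
    )
    return pc.SiteCountsTable(scaf, pos, ref, counts)


@pytest.fixture
def two_pool_site():
    """Single biallelic site observed in two pools."""
    def _build(c1, c2):
        sext1 = list(c1) + [0] * (6 - len(c1))
        sext2 = list(c2) + [0] * (6 - len(c2))
        return make_table([("sc1", 10, "A", [sext1, sext2])], 2)

    return _build
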