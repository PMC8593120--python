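import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import memstalk as ms


@pytest.fixture(scope="session")
def small_system():
    """A relaxed, briefly equilibrated 16-lipids-per-leaflet double bilayer."""
    spec = ms.SystemBuildSpec(lipids_per_leaflet=16)
    system = ms.build_double_bilayer(spec, seed=3)
    ms.relax(system, 100)
    ms.langevin_run(system, ms.IntegratorParams(dt=0.02, seed=4), 500)
    return system


@pytest.fixture()
def random_config():
    """Apolar beads scattered around a cylinder region in a cubic box."""
    rng = np.random.default_rng(12)
    n = 60
    box = np.array([8.0, 8.0, 8.0])
    pos = rng.uniform(2.0, 6.0, (n, 3))
    return ms.Configuration(pos, box, np.zeros(n, dtype=int),
                            np.array(["LIP"] * n))


@pytest.fixture()
def std_cylinder():
    return ms.CylinderSpec(np.array([4.0, 4.0]), 3.0, 5.0, radius=1.2,
                           n_slices=20)


@pytest.fixture()
def std_params():
    return ms.ChainCoordParams()
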