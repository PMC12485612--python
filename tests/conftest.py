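import numpy as np
import pytest

from urbwell.natural_city import GradientZones
from urbwell.synthetic import SimulationConfig


@pytest.fixture
def small_cfg() -> SimulationConfig:
    return SimulationConfig(grid_shape=(60, 60), n_years=5, seed=7,
                            posts_per_zone=50)


@pytest.fixture
def disk_zones() -> GradientZones:
    """Three concentric rings from nested disks of radius 5, 10, 15."""
    rr, cc = np.ogrid[:40, :40]
    d2 = (rr - 20) ** 2 + (cc - 20) ** 2
    label = np.zeros((40, 40), dtype=np.int32)
    label[d2 <= 15 ** 2] = 3
    label[d2 <= 10 ** 2] = 2
    label[d2 <= 5 ** 2] = 1
    return GradientZones(label=label, n_rings=3)
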