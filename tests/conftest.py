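import numpy as np
import pytest

from ilmix.trajectory import Topology


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def point_topology():
    """Topology factory for configs of single-site 'water' pseudo-atoms."""

    def make(n: int, species: str = "water") -> Topology:
        role = {"water": "water_center", "cation": "cation_center"}[species]
        return Topology(
            molecule_id=np.arange(n),
            species=np.array([species] * n, dtype=object),
            role=np.array([role] * n, dtype=object),
        )

    return make
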