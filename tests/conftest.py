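import numpy as np
import pytest

from mpva.demography import VitalRates, build_matrix
from mpva.metapopulation import ColonyGeometry


@pytest.fixture
def typical_vitals() -> VitalRates:
    """A mid-sized colonial seabird with slightly positive baseline growth."""
    return VitalRates(s0=0.6, s1=0.8, s2=0.9, s3=0.9, b=0.9, e=1.5, h=0.75, f=0.7, afr=4)


@pytest.fixture
def typical_matrix(typical_vitals):
    return build_matrix(typical_vitals)


@pytest.fixture
def triangle_geometry() -> ColonyGeometry:
    return ColonyGeometry(
        np.array([[0.0, 100.0, 200.0], [100.0, 0.0, 150.0], [200.0, 150.0, 0.0]])
    )


def random_geometry(rng: np.random.Generator, k: int, lo=20.0, hi=800.0) -> ColonyGeometry:
    d = rng.uniform(lo, hi, (k, k))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return ColonyGeometry(d)
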