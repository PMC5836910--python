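import pytest

from qmtkit.io import packaged_protocol
from qmtkit.model import AcquisitionTiming
from qmtkit.params import whole_cord_tissue
from qmtkit.pulses import MTPulseSpec, TrainSpec


@pytest.fixture(scope="session")
def cord_tissue():
    return whole_cord_tissue()


@pytest.fixture(scope="session")
def optimized_protocol():
    return packaged_protocol("table_optimized")


@pytest.fixture(scope="session")
def uniform_protocol():
    return packaged_protocol("table_uniform")


@pytest.fixture(scope="session")
def timing():
    return AcquisitionTiming()


@pytest.fixture(scope="session")
def train25():
    return TrainSpec(25, 15e-3, MTPulseSpec(b1_peak=0.0, duration=15e-3, offset=0.0))


def random_tissue(rng):
    """One random valid tissue draw spanning the fit bounds interior."""
    from qmtkit.params import tissue_from_t1obs
    bpf = rng.uniform(0.03, 0.3)
    t2f = rng.uniform(20e-3, 90e-3)
    t2b = rng.uniform(5e-6, 20e-6)
    kfb = rng.uniform(0.5, 5.0)
    t1obs = rng.uniform(0.8, 1.6)
    return tissue_from_t1obs(bpf=bpf, t2f=t2f, t2b=t2b, kfb=kfb, t1obs=t1obs)
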