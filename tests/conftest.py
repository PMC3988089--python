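import numpy as np
import pytest

from ria15n.chem import Template
from ria15n.config import RunConfig
from ria15n.spectra_io import PeptideTarget, Scan


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240415)


def make_scan(mz, intensity, rt=10.0):
    order = np.argsort(mz)
    return Scan(rt, np.asarray(mz, dtype=float)[order], np.asarray(intensity, dtype=float)[order])


def make_template(mz_values, slots=None):
    """A bare template at arbitrary positions, for constructed-spectrum tests."""
    mz_values = np.asarray(mz_values, dtype=float)
    if slots is None:
        slots = np.arange(mz_values.size)
    return Template("TESTPEPK", 1, mz_values, np.asarray(slots))


@pytest.fixture
def simple_target():
    return PeptideTarget("AVANQPIAVAVEGGGR", 2, 42.7, "G7JAR7")
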