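import numpy as np
import pytest

from sexbias.sfs_engine import SpectrumData


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_pair():
    """A tiny constant-size-like autosome/X spectrum pair."""
    sA = SpectrumData([40.0, 20.0, 13.0, 10.0], 5, L=1e4, mu=1e-8, chrom_class="A")
    sX = SpectrumData([30.0, 15.0, 10.0, 7.0], 5, L=1e4, mu=1e-8, chrom_class="X")
    return sA, sX
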