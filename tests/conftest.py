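import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_signatures():
    """A CpG-deamination-like C>T signature and a flat C>A signature."""
    from clonerate.spectra import CHANNELS_96

    deam = np.zeros(96)
    for i, label in enumerate(CHANNELS_96):
        if "[C>T]" in label:
            deam[i] = 10.0 if label.endswith("G") else 1.0
    c_to_a = np.array([1.0 if "[C>A]" in c else 0.0 for c in CHANNELS_96])
    return np.vstack([deam / deam.sum(), c_to_a / c_to_a.sum()])
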