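import numpy as np
import pytest

from ac4cpred.seqdata import SynthSpec, generate_synthetic


@pytest.fixture(scope="session")
def tiny_ds():
    """60 benchmark-style records, 201 nt, motifs implanted at 20-60."""
    return generate_synthetic(SynthSpec(n_positive=30, n_negative=30, seed=42))


@pytest.fixture(scope="session")
def short_ds():
    """Quick-to-train dataset: 61-nt windows, zone 10-50, strong signal."""
    spec = SynthSpec(n_positive=60, n_negative=60, window_length=61,
                     enrich_start=10, enrich_end=50, seed=7)
    return generate_synthetic(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
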