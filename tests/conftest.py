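import numpy as np
import pytest

from thiohelix.fiber import A_FORM, B_FORM, SequenceSpec, build_duplex, duplex_pairing


@pytest.fixture(scope="session")
def gc_spec():
    return SequenceSpec("GCGCGCGC")


@pytest.fixture(scope="session")
def gc_duplex(gc_spec):
    """8-bp poly(GC) B-form DNA duplex."""
    return build_duplex(gc_spec, B_FORM)


@pytest.fixture(scope="session")
def hybrid_spec():
    return SequenceSpec("GTACGTACGT", strand1_type="DNA", strand2_type="RNA")


@pytest.fixture(scope="session")
def hybrid_duplex(hybrid_spec):
    """10-bp mixed-sequence DNA:RNA hybrid, ideal A form."""
    return build_duplex(hybrid_spec, A_FORM)


@pytest.fixture
def rng():
    return np.random.default_rng(20240525)
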