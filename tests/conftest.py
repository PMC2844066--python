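import pytest

from mtepitope.sequences import ProteinSequence, load_bundled


@pytest.fixture(scope="session")
def pig():
    """Bundled synthetic stand-in for porcine brain β-tubulin (445 aa)."""
    return load_bundled("btub_pig")


@pytest.fixture(scope="session")
def tbb1():
    """Bundled synthetic stand-in for A. thaliana β-tubulin 1 (447 aa)."""
    return load_bundled("tbb1_arath")


@pytest.fixture
def tiny_seq():
    return ProteinSequence("tiny", "MREILHVQGG")
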