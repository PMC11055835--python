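import pytest

from phlipkit import STUDY_PEPTIDES, load_scale


@pytest.fixture(scope="session")
def peptides():
    """The five printed study peptides keyed by label."""
    return STUDY_PEPTIDES


@pytest.fixture(scope="session")
def kd_scale():
    return load_scale("kyte_doolittle")


@pytest.fixture(scope="session")
def fp_scale():
    return load_scale("fauchere_pliska")


@pytest.fixture(scope="session")
def diwv_scale():
    return load_scale("guruprasad_diwv")
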