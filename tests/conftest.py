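import pytest

from spliceprobe.simulate import (
    default_bait_panel,
    default_study_profiles,
    make_background,
    make_gene,
)


@pytest.fixture(scope="session")
def gene():
    return make_gene(1)


@pytest.fixture(scope="session")
def panel(gene):
    return default_bait_panel(gene)


@pytest.fixture(scope="session")
def background(panel):
    return make_background(7, 20, 1500, baits=panel)


@pytest.fixture(scope="session")
def profiles():
    return default_study_profiles()
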