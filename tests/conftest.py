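import pytest

import recurvar as rv


@pytest.fixture(scope="session")
def ref38():
    return rv.context_contig("hg38")


@pytest.fixture(scope="session")
def ref19():
    return rv.context_contig("hg19")


@pytest.fixture(scope="session")
def anchors():
    return rv.load_fixture("build_anchors")


@pytest.fixture(scope="session")
def table2():
    return rv.load_fixture("table2")


@pytest.fixture(scope="session")
def table3():
    return rv.load_fixture("table3")


@pytest.fixture(scope="session")
def cdna_map():
    return rv.cdna_key_map()


@pytest.fixture(scope="session")
def standin_cds():
    return rv.make_shank3_like_cds()


@pytest.fixture(scope="session")
def transcript_models():
    return rv.make_transcript_models()
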