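import pytest

from prepsim import builtin_protocol, table_params


@pytest.fixture(params=["mechanical", "enzymatic"])
def assay(request):
    return request.param


@pytest.fixture
def protocol(assay):
    return builtin_protocol(assay)


@pytest.fixture
def params(assay):
    return table_params(assay)


@pytest.fixture
def mech_params():
    return table_params("mechanical")
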