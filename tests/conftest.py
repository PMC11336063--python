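import pytest

from gcn2triage import load_catalog


@pytest.fixture(scope="session")
def catalog():
    """The packaged catalog: 34 natural missense variants + K619R control."""
    return load_catalog()


@pytest.fixture(scope="session")
def tested_panels(catalog):
    """Assay panels of the 17 experimentally characterised rows."""
    return {e.name: e.panel for e in catalog.assayed}
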