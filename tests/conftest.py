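import pytest

import tsmr


@pytest.fixture(scope="session")
def study():
    """Packaged exposure instruments, five outcome datasets, proxy map."""
    return tsmr.load_study()


@pytest.fixture(scope="session")
def exposure(study):
    return study[0]


@pytest.fixture(scope="session")
def outcomes(study):
    return study[1]


@pytest.fixture(scope="session")
def proxy_map(study):
    return study[2]


@pytest.fixture(scope="session")
def harmonized(study):
    """Harmonized sets for all five outcomes (proxy_required policy)."""
    exp, outs, pm = study
    return {name: tsmr.harmonize_dataset(exp, out, proxies=pm)
            for name, out in outs.items()}
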