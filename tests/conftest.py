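import numpy as np
import pytest

from tcskit.signatures import DomainCall, load_signature_defs


@pytest.fixture(scope="session")
def sig_defs():
    return load_signature_defs()


@pytest.fixture(scope="session")
def sig_by_name(sig_defs):
    return {d.name: d for d in sig_defs}


def make_call(pid, name, start, length=12, key_status="n/a", observed=None, source="scan"):
    return DomainCall(pid, name, start, start + length,
                      key_status=key_status, observed_key=observed, source=source)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
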