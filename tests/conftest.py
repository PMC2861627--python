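import numpy as np
import pytest

import nbcascade as nb


@pytest.fixture(scope="session")
def dros():
    """Reference network with hb-|cas and the x regulations."""
    return nb.drosophila_network(include_hb_to_cas=True, include_x=True)


@pytest.fixture(scope="session")
def dros_no_x():
    return nb.drosophila_network(include_hb_to_cas=True, include_x=False)


@pytest.fixture(scope="session")
def functional_scan():
    """The full 3^15 screen (ON->OFF); shared by the acceptance tests."""
    report, records = nb.scan_with_x("on_off", t_end=10)
    return report, records


@pytest.fixture()
def rng():
    return np.random.default_rng(20201)


def random_network(rng, include_x=True):
    slots = 15 if include_x else 12
    code = int(rng.integers(0, 3 ** slots))
    return nb.SignNetwork.from_code(code, include_x=include_x)
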