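import numpy as np
import pytest

import blafear as bf


@pytest.fixture(scope="session")
def cell_db():
    return bf.load_cell_params()


@pytest.fixture(scope="session")
def short_full_run():
    """A 4 s full single-cell-network conditioning run, shared across tests."""
    net = bf.assemble(bf.NetworkConfig())
    res = bf.run(net, [bf.PhaseSpec(0.0, 4000.0, cs_on=True, us_on=True)], seed=17)
    return net, res
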