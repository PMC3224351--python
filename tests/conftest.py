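import numpy as np
import pytest

import fluxlogic as fl


@pytest.fixture
def proto():
    """The 10-reaction worked-example network."""
    return fl.fixtures.build_prototypic_network()


@pytest.fixture
def proto_coupled(proto):
    return fl.couple(proto)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def toy_gated_model():
    """One metabolite passing through an essential gene-gated reaction."""
    return fl.MetabolicModel(
        mets=["M"],
        rxns=["Rin", "Rout"],
        S=np.array([[1.0, -1.0]]),
        vmin=[0.0, 0.0],
        vmax=[10.0, 10.0],
        objective=[0.0, 1.0],
        genes=["g"],
        gpr=["", "g"],
    )
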