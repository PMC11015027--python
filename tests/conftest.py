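import numpy as np
import pytest

from snnl2l import AdaptationParams, NeuronParams, WeightSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_toy_network(seed=42, n=3, n_in=2, v_th=1.0, delays=True,
                     beta=(0.0, 0.5, 0.5)):
    """Small spiking network in a regime with both spikes and near-threshold
    excursions, heterogeneous delays and mixed SFA."""
    g = np.random.default_rng(seed)
    neuron = NeuronParams(tau_m=20.0, v_th=v_th, tau_ref=2.0)
    adapt = AdaptationParams(beta=np.resize(np.asarray(beta, dtype=float), n),
                             tau_a=np.linspace(20.0, 200.0, n))
    weights = WeightSet(
        w_in=g.uniform(0.5, 3.0, (n, n_in)),
        w_rec=g.normal(0.0, 0.6, (n, n)),
        w_out=g.normal(0.0, 1.0, (1, n)),
        w0=1.0,
        d_in=g.integers(1, 3, (n, n_in)) if delays else None,
        d_rec=g.integers(1, 4, (n, n)) if delays else None,
    )
    return weights, neuron, adapt


@pytest.fixture
def toy_network():
    return make_toy_network()
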