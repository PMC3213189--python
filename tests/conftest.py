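import numpy as np
import pytest

from sporedyn.models import default_parameters, make_topology

ALL_MODELS = ("irreversible_only", "reversible_only", "hybrid")


@pytest.fixture(params=ALL_MODELS)
def model(request):
    """Topology + default parameters for each of the three schemes."""
    topo = make_topology(request.param)
    return topo, default_parameters(topo)


def random_valid_parameters(topology, rng: np.random.Generator):
    """Random rate set respecting the stress-coupling invariants."""
    f_high = rng.uniform(0.2, 2.0)
    f_low = rng.uniform(0.0, f_high)
    b_low = rng.uniform(0.2, 2.0)
    b_high = rng.uniform(0.0, b_low)
    return default_parameters(
        topology,
        forward_high=f_high,
        forward_low=f_low,
        backward_low=b_low,
        backward_high=b_high,
        commitment_high=rng.uniform(0.1, 2.0),
        commitment_low=rng.uniform(0.0, 0.1),
        spore_rate=rng.uniform(0.2, 2.0),
        growth_low=rng.uniform(0.0, 1.0),
        growth_high=-rng.uniform(0.05, 1.0),
    )
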