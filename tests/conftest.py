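import numpy as np
import pytest

from cocomo2 import ChainSpec, SystemState, build_topology, load_parameter_set
from cocomo2.fixtures import make_folded_fixture, make_idp_sequence


@pytest.fixture(scope="session")
def cocomo2_params():
    return load_parameter_set("COCOMO2")


@pytest.fixture(scope="session")
def cocomo_params():
    return load_parameter_set("COCOMO")


@pytest.fixture(scope="session")
def folded_bundle():
    """49-residue helix-bundle chain with burial labels."""
    return make_folded_fixture(49, seed=3)


def random_system(n_chains=6, chain_length=12, seed=0, box=10.0,
                  params=None, folded=False, spread=None):
    """Random multi-chain configuration for oracle comparisons."""
    if params is None:
        params = load_parameter_set("COCOMO2")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_chains):
        if folded and i == 0:
            spec, _ = make_folded_fixture(max(12, chain_length), seed=seed + 50)
        else:
            spec = ChainSpec(chain_id=f"c{i}",
                             sequence=make_idp_sequence(chain_length, None,
                                                        seed * 100 + i))
        specs.append(spec)
    top = build_topology(specs, params)
    box_arr = np.full(3, float(box))
    # chains as compact random blobs so bonded terms stay sane and plenty
    # of pairs fall inside the cutoff
    coords = np.empty((top.n_beads, 3))
    for sl in top.chain_slices():
        n = sl.stop - sl.start
        center = rng.random(3) * box
        blob = rng.normal(scale=(spread or 0.5), size=(n, 3))
        coords[sl] = center + blob
    state = SystemState(coordinates=coords, box=box_arr, topology=top,
                        params=params)
    return state
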