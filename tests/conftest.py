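import numpy as np
import pytest

from lefsim import LatticeConfig, LEFParams, init_simulation


@pytest.fixture
def small_state():
    """Empty 100-site lattice with 5 unbound LEFs."""
    config = LatticeConfig(n_sites=100)
    params = LEFParams(n_lefs=5, k_bind=1.0, k_unbind=0.1)
    return init_simulation(config, params, seed=1)


@pytest.fixture
def fixtures():
    from lefsim.io import make_fixtures

    return make_fixtures(seed=0)


def place_lef(state, lef, left, right, active="right", two_sided=False):
    """Deterministically put a LEF at given sites (test helper)."""
    state.left[lef] = left
    state.right[lef] = right
    state.bound[lef] = 1
    state.two_s[lef] = 1 if two_sided else 0
    if two_sided:
        state.act_l[lef] = 1
        state.act_r[lef] = 1
    else:
        state.act_l[lef] = 1 if active == "left" else 0
        state.act_r[lef] = 1 if active == "right" else 0
    if not state.params.traversal:
        state.occ[left] = lef + 1
        state.occ_side[left] = 0
        state.occ[right] = lef + 1
        state.occ_side[right] = 1
    return state
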