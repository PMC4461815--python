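import numpy as np
import pytest

from ordertex.texture_model import TextureSetSpec, builtin_specs, get_builtin


@pytest.fixture(scope="session")
def builtins():
    return builtin_specs()


@pytest.fixture(scope="session")
def potts():
    return get_builtin("potts")


@pytest.fixture(scope="session")
def potts4():
    """Ferromagnetic Potts set on a tiny 4x4 lattice."""
    return get_builtin("potts").with_shape((4, 4))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def nn_spec(potentials, name="test", shape=(4, 4), tile=None, n_states=3):
    """Helper: nearest-neighbour spec with given potentials."""
    return TextureSetSpec(
        name=name,
        n_states=n_states,
        offsets=((0, 1), (1, 0)),
        potentials=potentials,
        lattice_shape=shape,
        beta_grid=(0.0, 0.5, 1.0),
        ground_state_tile=tile,
    )
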