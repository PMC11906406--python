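import numpy as np
import pytest

from icodwi.equivariant_layers import build_orbit, star_layout
from icodwi.icosa_group import build_icosahedron, build_rotation_group
from icodwi.synthetic_data import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def ico():
    return build_icosahedron()


@pytest.fixture(scope="session")
def group(ico):
    return build_rotation_group(ico)


@pytest.fixture(scope="session")
def layout(ico):
    return star_layout(ico)


@pytest.fixture(scope="session")
def orbit(group, layout):
    return build_orbit(group, layout)


@pytest.fixture(scope="session")
def orbit_perms(group, orbit):
    """orbit_perms[h][i] = orbit index of elements[h]^-1 @ points[i].

    Used to rotate orbit-sampled spherical signals exactly:
    rotated[i] = original[perm[i]].
    """
    perms = np.empty((group.order, len(orbit.points)), dtype=np.intp)
    for h in range(group.order):
        rotated = orbit.points @ group.elements[group.inverse[h]].T
        d = np.linalg.norm(rotated[:, None, :] - orbit.points[None], axis=2)
        perms[h] = d.argmin(axis=1)
        assert d[np.arange(len(orbit.points)), perms[h]].max() < 1e-9
    return perms


@pytest.fixture(scope="session")
def phantom_pair():
    """Two small phantoms sharing one gradient table (train / held-out)."""
    vol_a, lab_a, mask_a = generate_phantom(PhantomConfig(seed=11))
    vol_b, lab_b, mask_b = generate_phantom(PhantomConfig(seed=12))
    return (vol_a, lab_a, mask_a), (vol_b, lab_b, mask_b)


@pytest.fixture(scope="session")
def noise_free_phantom():
    vol, lab, mask = generate_phantom(PhantomConfig(seed=7, noise="none"))
    return vol, lab, mask
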